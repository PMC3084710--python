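Property Sequence(txt);
Property Neg35StartEnd(txt);
Property Neg10StartEnd(txt);
Property OperatorSites(txt[]);
Property OperatorSiteLocations(txt[]);
Property CorrespondingProtein(txt);
Property ProteinBindingInfo(txt);
Part Promoter(Sequence, Neg35StartEnd, Neg10StartEnd, OperatorSites, OperatorSiteLocations);
Part RBS(Sequence);
Part CodingDNA(Sequence, CorrespondingProtein, ProteinBindingInfo);
Part Terminator(Sequence);
Promoter araP(.Sequence("AAGCCCAATAAACCACTCTGACTGGCCGAATAGGGATATAGGCAACGACATGTGCGGCGA"));
Promoter lacP(.Sequence("CCCTTGCGACAGTGACGCTTTCGCCGTTGCCTAAACCTATTTGAAGGAGTCTAGCAGC"));
Promoter tetP(.Sequence("GCAGTAAGGCACAATACCTCGTCCGTGTT"));
RBS rbs1(.Sequence("CCAGACCAAACAAGACGTCCTCTTCAA"));
RBS rbs2(.Sequence("GTTTAAATGACCCTCTCGTCATAAAACCTTTCTACTATGTGTTCCGC"));
RBS rbs3(.Sequence("AGAATCAACAACTACAATGGCGC"));
CodingDNA DNAlac(.Sequence("TCGTGAATAACGCGACGGCTGAGACGAACGGCGCGT"), .CorrespondingProtein("LacI"));
CodingDNA DNAtet(.Sequence("AATGAAGCGCTTAAACAGCTCAGGAGCCAGTCCCCT"), .CorrespondingProtein("TetR"));
CodingDNA DNAara(.Sequence("CGTCGCATATCCTGGCCACTG"), .CorrespondingProtein("AraC"));
Terminator term1(.Sequence("AGGTGAAGCGAATGGTATCGATACGTAGGAGGTGTGC"));
Terminator term2(.Sequence("TTCGTAGGCTGTTTCTCAGGACGCCCAACTAT"));
Terminator term3(.Sequence("CTTTCCAATCCTACATCTGTTTCTTGCGTCGTAGCGGGACCCTCCA"));
Rule promoterToCoding1(araP BEFORE DNAlac);
Rule promoterToCoding2(lacP BEFORE DNAtet);
Rule promoterToCoding3(tetP BEFORE DNAara);
Assert(promoterToCoding1 AND promoterToCoding2 AND promoterToCoding3);
Device Repressilator(araP, rbs1, DNAlac, term1, lacP, rbs2, DNAtet, term2, tetP, rbs3, DNAara, term3);
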