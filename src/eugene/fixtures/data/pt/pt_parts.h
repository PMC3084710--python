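Property ID(txt);
Property Sequence(txt);
Part Promoter(ID, Sequence);
Part NTag(ID, Sequence);
Part CTag(ID, Sequence);
Part CS(ID, Sequence);
Part OS(ID, Sequence);
Part RSO(ID, Sequence);
Part Terminator(ID, Sequence);
Promoter P1(.ID("P1"), .Sequence("AAGCCCAATAAACCACTCTGACTGGCCGAATAGGGATATAGGCAACGACATGTGCGGCGA"));
NTag ntag01(.ID("Ab01"), .Sequence("CCCTTGCGACAGTGACGCTTTCGCCGTTGCCTAAACCTATTTGAAGGAGTCTAGCAGC"));
NTag ntag02(.ID("Ab02"), .Sequence("GCAGTAAGGCACAATACCTCGTCCGTGTT"));
NTag ntag03(.ID("Ab03"), .Sequence("CCAGACCAAACAAGACGTCCTCTTCAA"));
NTag ntag04(.ID("Ab04"), .Sequence("GTTTAAATGACCCTCTCGTCATAAAACCTTTCTACTATGTGTTCCGC"));
NTag ntag05(.ID("Ab05"), .Sequence("AGAATCAACAACTACAATGGCGC"));
NTag ntag06(.ID("Ab06"), .Sequence("TCGTGAATAACGCGACGGCTGAGACGAACGGCGCGT"));
NTag ntag07(.ID("Ab07"), .Sequence("AATGAAGCGCTTAAACAGCTCAGGAGCCAGTCCCCT"));
NTag ntag08(.ID("Ab08"), .Sequence("CGTCGCATATCCTGGCCACTG"));
NTag ntag09(.ID("Ab09"), .Sequence("AGGTGAAGCGAATGGTATCGATACGTAGGAGGTGTGC"));
NTag ntag10(.ID("Ab10"), .Sequence("TTCGTAGGCTGTTTCTCAGGACGCCCAACTAT"));
NTag ntag11(.ID("Ab11"), .Sequence("CTTTCCAATCCTACATCTGTTTCTTGCGTCGTAGCGGGACCCTCCA"));
NTag ntag12(.ID("Ab12"), .Sequence("TGTTACTTATTAGGTTCTCGTTATGTCTCATAATCTCAGTGCTGGT"));
CTag ctag01(.ID("Ab01"), .Sequence("TGATAAGCAAACCACCCTACTGGCACGAAGTTCACAG"));
CTag ctag02(.ID("Ab02"), .Sequence("AAGTGAGATTATGTCTCGTTTGGCAGTCTTGATGCTCGGGGGACACTTCTTTAAGCTC"));
CTag ctag03(.ID("Ab03"), .Sequence("GTGTGGTGGGCACGACCCTGGACGCGCGACGAAGCTAAG"));
CTag ctag04(.ID("Ab04"), .Sequence("TTGCAGTAATTAACCGACATCTTTGTGAACCGACCCACATTTGACGGTAC"));
CTag ctag05(.ID("Ab05"), .Sequence("CTACCGCAACGGTATGTGTTAATGGAACAGACTTGC"));
CTag ctag06(.ID("Ab06"), .Sequence("TTATGTGGACGTTGTATAGGGATATTACGTTACGCGTTAACCGATACATACTGGTTT"));
CTag ctag07(.ID("Ab07"), .Sequence("TCTCCAGTGGAGGTCTTGGTTGCCTCTAGTTTCTA"));
CTag ctag08(.ID("Ab08"), .Sequence("GATATACTCATGGTAGTGTAACGCATAA"));
CTag ctag09(.ID("Ab09"), .Sequence("CGAAGAGGGTCCTCCCATCTCCTGTGATGCATGGTGTGCTTACTGGGA"));
CTag ctag10(.ID("Ab10"), .Sequence("GAATGCGCCGCAAGTAGCAGGTCCCGGCGTGGATACCTGATAGAT"));
CTag ctag11(.ID("Ab11"), .Sequence("GTGACTAGCATGTACAAGTAACCTTGTCTATTGAGCTTCGAGG"));
CTag ctag12(.ID("Ab12"), .Sequence("TGCATACAAGCCCACCCGCAGCC"));
CS cs1(.ID("cs1"), .Sequence("GCAACAGCGACGACTAATTGATCAGTAATTTATTAAGCACGGTGTTAACTTCTG"));
OS osORF1(.ID("ORF1"), .Sequence("TTAGTGGGCTAAAATAGCAGATGTAGGGACCTCAGGAGCTAGACGGGGA"));
OS osORF2(.ID("ORF2"), .Sequence("CTACAACTTTGCGGGAACCAAGTTTTTGCAG"));
RSO rsoORF1(.ID("ORF1"), .Sequence("AGTGACTAACGCCGGGAATTCCTCGATATATAGTTTGATAGCTGATA"));
RSO rsoORF2(.ID("ORF2"), .Sequence("TTATGGCGCAACGGCCACGCCCACTTTGGCTATTG"));
Terminator T1(.ID("T1"), .Sequence("AGAGTTAAGGAATTATCGTCATAGACACTTCGGGTTG"));
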