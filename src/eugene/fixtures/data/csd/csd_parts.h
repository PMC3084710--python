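Property ID(txt);
Property Sequence(txt);
Property Orientation(txt);
Part Passenger(ID, Sequence, Orientation);
Part Spacer(ID, Sequence, Orientation);
Part Displayer(ID, Sequence, Orientation);
Part Terminator(ID, Sequence, Orientation);
Passenger PassAg4(.ID("PassAg4"), .Sequence("AAGCCCAATAAACCACTCTGACTGGCCGAATAGGGATATAGGCAACGACATGTGCGGCGA"));
Passenger PassLeu(.ID("PassLeu"), .Sequence("CCCTTGCGACAGTGACGCTTTCGCCGTTGCCTAAACCTATTTGAAGGAGTCTAGCAGC"));
Passenger PassCell(.ID("PassCell"), .Sequence("GCAGTAAGGCACAATACCTCGTCCGTGTT"));
Passenger PassNeedle(.ID("PassNeedle"), .Sequence("CCAGACCAAACAAGACGTCCTCTTCAA"));
Passenger PassStrep(.ID("PassStrep"), .Sequence("GTTTAAATGACCCTCTCGTCATAAAACCTTTCTACTATGTGTTCCGC"));
Passenger PassMgfp(.ID("PassMgfp"), .Sequence("AGAATCAACAACTACAATGGCGC"));
Spacer SpacerINP(.ID("SpacerINP"), .Sequence("TCGTGAATAACGCGACGGCTGAGACGAACGGCGCGT"));
Spacer SpacerGly_Ser(.ID("SpacerGly_Ser"), .Sequence("AATGAAGCGCTTAAACAGCTCAGGAGCCAGTCCCCT"));
Spacer SpacerGfp_Iva(.ID("SpacerGfp_Iva"), .Sequence("CGTCGCATATCCTGGCCACTG"));
Spacer SpacerBeta_Roll(.ID("SpacerBeta_Roll"), .Sequence("AGGTGAAGCGAATGGTATCGATACGTAGGAGGTGTGC"));
Spacer SpacerBeta_Helix(.ID("SpacerBeta_Helix"), .Sequence("TTCGTAGGCTGTTTCTCAGGACGCCCAACTAT"));
Displayer Disp_upaG(.ID("Disp_upaG"), .Sequence("CTTTCCAATCCTACATCTGTTTCTTGCGTCGTAGCGGGACCCTCCA"));
Displayer Disp_Vta(.ID("Disp_Vta"), .Sequence("TGTTACTTATTAGGTTCTCGTTATGTCTCATAATCTCAGTGCTGGT"));
Displayer Disp_ehaB(.ID("Disp_ehaB"), .Sequence("TGATAAGCAAACCACCCTACTGGCACGAAGTTCACAG"));
Displayer Disp_CPG6(.ID("Disp_CPG6"), .Sequence("AAGTGAGATTATGTCTCGTTTGGCAGTCTTGATGCTCGGGGGACACTTCTTTAAGCTC"));
Displayer Disp_AIDA(.ID("Disp_AIDA"), .Sequence("GTGTGGTGGGCACGACCCTGGACGCGCGACGAAGCTAAG"));
Displayer Disp_cl(.ID("Disp_cl"), .Sequence("TTGCAGTAATTAACCGACATCTTTGTGAACCGACCCACATTTGACGGTAC"));
Displayer Disp_Pcryo(.ID("Disp_Pcryo"), .Sequence("CTACCGCAACGGTATGTGTTAATGGAACAGACTTGC"));
Displayer Disp_s08(.ID("Disp_s08"), .Sequence("TTATGTGGACGTTGTATAGGGATATTACGTTACGCGTTAACCGATACATACTGGTTT"));
Displayer Disp_s09(.ID("Disp_s09"), .Sequence("TCTCCAGTGGAGGTCTTGGTTGCCTCTAGTTTCTA"));
Displayer Disp_s10(.ID("Disp_s10"), .Sequence("GATATACTCATGGTAGTGTAACGCATAA"));
Displayer Disp_s11(.ID("Disp_s11"), .Sequence("CGAAGAGGGTCCTCCCATCTCCTGTGATGCATGGTGTGCTTACTGGGA"));
Displayer Disp_s12(.ID("Disp_s12"), .Sequence("GAATGCGCCGCAAGTAGCAGGTCCCGGCGTGGATACCTGATAGAT"));
Displayer Disp_s13(.ID("Disp_s13"), .Sequence("GTGACTAGCATGTACAAGTAACCTTGTCTATTGAGCTTCGAGG"));
Displayer Disp_s14(.ID("Disp_s14"), .Sequence("TGCATACAAGCCCACCCGCAGCC"));
Displayer Disp_s15(.ID("Disp_s15"), .Sequence("GCAACAGCGACGACTAATTGATCAGTAATTTATTAAGCACGGTGTTAACTTCTG"));
Terminator T01(.ID("T01"), .Sequence("TTAGTGGGCTAAAATAGCAGATGTAGGGACCTCAGGAGCTAGACGGGGA"));
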