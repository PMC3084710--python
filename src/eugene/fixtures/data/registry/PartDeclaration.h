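Promoter BBa_I0500(.ID("BBa_I0500"), .Sequence("AAGCCCAATAAACCACTCTGACTGGCCGAATAGGGATATAGGCAACGACATGTGCGGCGA"), .Orientation("Forward"), .Inducible(true));
ORF BBa_K112805(.ID("BBa_K112805"), .Sequence("CCCTTGCGACAGTGACGCTTTCGCCGTTGCCTAAACCTATTTGAAGGAGTCTAGCAGC"), .Orientation("Forward"), .CDS(true));
ORF BBa_K112806(.ID("BBa_K112806"), .Sequence("GCAGTAAGGCACAATACCTCGTCCGTGTT"), .Orientation("Forward"), .CDS(true));
Terminator BBa_B0010(.ID("BBa_B0010"), .Sequence("CCAGACCAAACAAGACGTCCTCTTCAA"), .Orientation("Forward"), .Strength([0.98]));
Terminator BBa_B0012(.ID("BBa_B0012"), .Sequence("GTTTAAATGACCCTCTCGTCATAAAACCTTTCTACTATGTGTTCCGC"), .Orientation("Forward"), .Strength([0.84]));
Promoter BBa_J23116(.ID("BBa_J23116"), .Sequence("GATCTttgacagctagctcagtcctagggactatgctagcG"), .Orientation("Forward"));
ORF BBa_K112807(.ID("BBa_K112807"), .Sequence("AGAATCAACAACTACAATGGCGC"), .Orientation("Forward"), .CDS(true));
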