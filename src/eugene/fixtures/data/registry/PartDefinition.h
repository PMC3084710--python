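Part Promoter(ID, Sequence, Orientation, Inducible);
Part ORF(ID, Sequence, Orientation, CDS);
Part RBS(ID, Sequence, Orientation);
Part Terminator(ID, Sequence, Orientation, Strength);
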