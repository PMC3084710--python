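Property ID(txt);
Property Sequence(txt);
Property Orientation(txt);
Property CDS(boolean);
Property Strength(num[]);
Property Inducible(boolean);
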