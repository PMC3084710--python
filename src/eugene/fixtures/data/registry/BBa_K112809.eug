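include PropertyDefinition.h, PartDefinition.h, PartDeclaration.h;
Device BBa_K112809(Promoter BBa_I0500, ORF BBa_K112805, ORF BBa_K112806, Terminator BBa_B0010, Terminator BBa_B0012, Promoter BBa_J23116, ORF BBa_K112807, Terminator BBa_B0010);
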