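include csd_parts.h;
Device DeviceType1(PassNeedle, SpacerINP, Disp_upaG, T01);
permute(DeviceType1);
Device DeviceType2(PassNeedle, Disp_upaG, T01);
permute(DeviceType2);
Rule NoAg4(NOTCONTAINS PassAg4);
Rule NoLeu(NOTCONTAINS PassLeu);
Rule NoCell(NOTCONTAINS PassCell);
Rule NeedleSpacers1(PassNeedle NOTWITH SpacerINP);
Rule NeedleSpacers2(PassNeedle NOTWITH SpacerGly_Ser);
Rule NeedleSpacers3(PassNeedle NOTWITH SpacerGfp_Iva);
Rule NeedleSpacers4(PassNeedle NOTWITH SpacerBeta_Roll);
Rule NeedleSpacers5(PassNeedle NOTWITH SpacerBeta_Helix);
Rule StrepSpacers1(PassStrep NOTWITH SpacerGly_Ser);
Rule StrepSpacers2(PassStrep NOTWITH SpacerGfp_Iva);
Rule StrepSpacers3(PassStrep NOTWITH SpacerBeta_Roll);
Rule StrepSpacers4(PassStrep NOTWITH SpacerBeta_Helix);
Assert(NoAg4 AND NoLeu AND NoCell AND NeedleSpacers1 AND NeedleSpacers2 AND NeedleSpacers3 AND NeedleSpacers4 AND NeedleSpacers5 AND StrepSpacers1 AND StrepSpacers2 AND StrepSpacers3 AND StrepSpacers4);
Rule MgfpSpacers1(PassMgfp NOTWITH SpacerGly_Ser);
Rule MgfpSpacers2(PassMgfp NOTWITH SpacerGfp_Iva);
Rule StrepSpacers5(PassStrep NOTWITH SpacerINP);
Assert(MgfpSpacers1 AND MgfpSpacers2 AND StrepSpacers5);
Rule Rule2((PassStrep WITH Disp_Vta) OR (PassStrep WITH Disp_ehaB) OR (PassStrep WITH Disp_CPG6) OR (PassStrep WITH Disp_AIDA));
Rule Rule3((PassNeedle NOTWITH Disp_cl) AND (PassNeedle NOTWITH Disp_Pcryo) AND (PassNeedle NOTWITH Disp_CPG6));
Rule Rule4(NOTCONTAINS PassMgfp);
Assert(Rule4 AND Rule2 AND Rule3);
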