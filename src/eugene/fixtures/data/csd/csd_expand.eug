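include csd_parts.h;
Device DeviceType1(PassNeedle, SpacerINP, Disp_upaG, T01);
permute(DeviceType1);
Device DeviceType2(PassNeedle, Disp_upaG, T01);
permute(DeviceType2);
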