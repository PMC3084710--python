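include pt_parts.h;
Device deviceTypeNN(P1, ntag01, cs1, osORF1, ntag02, cs1, osORF2, T1);
Device deviceTypeCC(P1, rsoORF1, cs1, ctag01, rsoORF2, cs1, ctag02, T1);
Device deviceTypeCN(P1, rsoORF1, cs1, ctag01, ntag01, cs1, osORF1, T1);
Device deviceTypeNC(P1, ntag01, cs1, osORF1, rsoORF1, cs1, ctag01, T1);
permute(deviceTypeNN);
permute(deviceTypeCC);
permute(deviceTypeCN);
permute(deviceTypeNC);
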