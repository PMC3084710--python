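include pt_parts.h;
Device deviceTypeNN(P1, ntag01, cs1, osORF1, ntag02, cs1, osORF2, T1);
Device deviceTypeCC(P1, rsoORF1, cs1, ctag01, rsoORF2, cs1, ctag02, T1);
Device deviceTypeCN(P1, rsoORF1, cs1, ctag01, ntag01, cs1, osORF1, T1);
Device deviceTypeNC(P1, ntag01, cs1, osORF1, rsoORF1, cs1, ctag01, T1);
permute(deviceTypeNN);
permute(deviceTypeCC);
permute(deviceTypeCN);
permute(deviceTypeNC);
Rule r1a_01(ctag01 NOTWITH ntag01);
Rule r1b_01(ctag01 NOTMORETHAN once);
Rule r1c_01(ntag01 NOTMORETHAN once);
Rule r1a_02(ctag02 NOTWITH ntag02);
Rule r1b_02(ctag02 NOTMORETHAN once);
Rule r1c_02(ntag02 NOTMORETHAN once);
Rule r1a_03(ctag03 NOTWITH ntag03);
Rule r1b_03(ctag03 NOTMORETHAN once);
Rule r1c_03(ntag03 NOTMORETHAN once);
Rule r1a_04(ctag04 NOTWITH ntag04);
Rule r1b_04(ctag04 NOTMORETHAN once);
Rule r1c_04(ntag04 NOTMORETHAN once);
Rule r1a_05(ctag05 NOTWITH ntag05);
Rule r1b_05(ctag05 NOTMORETHAN once);
Rule r1c_05(ntag05 NOTMORETHAN once);
Rule r1a_06(ctag06 NOTWITH ntag06);
Rule r1b_06(ctag06 NOTMORETHAN once);
Rule r1c_06(ntag06 NOTMORETHAN once);
Rule r1a_07(ctag07 NOTWITH ntag07);
Rule r1b_07(ctag07 NOTMORETHAN once);
Rule r1c_07(ntag07 NOTMORETHAN once);
Rule r1a_08(ctag08 NOTWITH ntag08);
Rule r1b_08(ctag08 NOTMORETHAN once);
Rule r1c_08(ntag08 NOTMORETHAN once);
Rule r1a_09(ctag09 NOTWITH ntag09);
Rule r1b_09(ctag09 NOTMORETHAN once);
Rule r1c_09(ntag09 NOTMORETHAN once);
Rule r1a_10(ctag10 NOTWITH ntag10);
Rule r1b_10(ctag10 NOTMORETHAN once);
Rule r1c_10(ntag10 NOTMORETHAN once);
Rule r1a_11(ctag11 NOTWITH ntag11);
Rule r1b_11(ctag11 NOTMORETHAN once);
Rule r1c_11(ntag11 NOTMORETHAN once);
Rule r1a_12(ctag12 NOTWITH ntag12);
Rule r1b_12(ctag12 NOTMORETHAN once);
Rule r1c_12(ntag12 NOTMORETHAN once);
Assert(r1a_01 AND r1b_01 AND r1c_01 AND r1a_02 AND r1b_02 AND r1c_02 AND r1a_03 AND r1b_03 AND r1c_03 AND r1a_04 AND r1b_04 AND r1c_04 AND r1a_05 AND r1b_05 AND r1c_05 AND r1a_06 AND r1b_06 AND r1c_06 AND r1a_07 AND r1b_07 AND r1c_07 AND r1a_08 AND r1b_08 AND r1c_08 AND r1a_09 AND r1b_09 AND r1c_09 AND r1a_10 AND r1b_10 AND r1c_10 AND r1a_11 AND r1b_11 AND r1c_11 AND r1a_12 AND r1b_12 AND r1c_12);
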