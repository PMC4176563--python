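@r01_keep
ACGTACGTACGTACGTACGTACTGGAATTCTCGG
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r02_keep_readthrough
GCATGCATGCATGCATGCATTGGAATTCTCGGGTGCCAAGGAC
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r03_adapter5
GTTCAGAGTTCTACAGTCCGACGATCACGTACGTACTGGAATTC
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r04_no_adapter
CATCATCATCATCATCATCATCATCATCAT
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r05_short_flank
GCATGCATGCATGCATGCATTGGAA
+
IIIIIIIIIIIIIIIIIIIIIIIII
@r06_ambiguous
ACGNACGTACGTACGTACGTGGAATTCTC
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r07_polya_run
AAAAAAAAAAAAAAAAAAAAAATGGAATTCTCGG
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r08_polya_frac
AAAACAAAACAAAACAAAACTGGAATTCTC
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r09_too_short
GCGCGCGCGCTGGAATTCTC
+
IIIIIIIIIIIIIIIIIIII
@r10_too_long
GCTAGCGCTAGCGCTAGCGCTAGCGCTAGCTGGAAT
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r11_keep_dup
ACGTACGTACGTACGTACGTACTGGAATTCTCGG
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
@r12_keep_maxflank
CCGGTTAACCGGTTAACCTGGAATTCTCGGGTGCCA
+
IIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIIII
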