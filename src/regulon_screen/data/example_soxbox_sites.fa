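>synthetic_site_1 SYNTHETIC illustrative operator site (not from any published alignment)
GCCTCAAGTTAACTTGAGGC
>synthetic_site_2 SYNTHETIC illustrative operator site (not from any published alignment)
GCCTCAAGTTAACTTGAGGC
>synthetic_site_3 SYNTHETIC illustrative operator site (not from any published alignment)
GCTTCAAGTTAACTTGAAGC
>synthetic_site_4 SYNTHETIC illustrative operator site (not from any published alignment)
GCCTCAAGTCGACTTGAGGC
>synthetic_site_5 SYNTHETIC illustrative operator site (not from any published alignment)
GACTCAAGTTAACTTGAGTC
>synthetic_site_6 SYNTHETIC illustrative operator site (not from any published alignment)
GCCTCAGGTTAACCTGAGGC
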