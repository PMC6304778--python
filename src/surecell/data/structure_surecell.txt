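# Read 1 anatomy for SureCell WTA 3' libraries (all keys optional;
# values below are the package defaults, shown for editing)
linker1 = TAGCCATCGCATTGC
linker2 = TACCTCTGAGCTGAA
barcode_len = 6
umi_len = 8
pre_umi_flanker = ACG
post_umi_flanker = GAC
expected_linker_gap = 21
min_l1_start = 7
max_linker_edits = 1
max_flanker_mismatches = 1
max_barcode_edits = 1
strict_gap = false
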