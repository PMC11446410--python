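# HCR v3 B-series amplifier initiators (36 nt), split into 18-nt halves,
# as published for the v3 split-initiator system (Choi et al. 2018) and
# redistributed by open-source probe designers. Replace with vendor-issued
# sequences if yours differ. Columns are tab-separated.
id	full_seq	half_up	half_dn	conn_up	conn_dn
B1	GAGGAGGGCAGCAAACGGGAAGAGTCTTCCTTTACG	GAGGAGGGCAGCAAACGG	GAAGAGTCTTCCTTTACG	AA	TT
B2	CCTCGTAAATCCTCATCAATCATCCAGTAAACCGCC	CCTCGTAAATCCTCATCA	ATCATCCAGTAAACCGCC	AA	TT
B3	GTCCCTGCCTCTATATCTCCACTCAACTTTAACCCG	GTCCCTGCCTCTATATCT	CCACTCAACTTTAACCCG	AA	TT
B4	CCTCAACCTACCTCCAACTCTCACCATATTCGCTTC	CCTCAACCTACCTCCAAC	TCTCACCATATTCGCTTC	AA	TT
B5	CTCACTCCCAATCTCTATCTACCCTACAAATCCAAT	CTCACTCCCAATCTCTAT	CTACCCTACAAATCCAAT	AA	TT
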