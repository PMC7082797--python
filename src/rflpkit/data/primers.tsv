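# pair_name	forward_name	forward_seq	reverse_name	reverse_seq	expected_length
16S	16S-Forward	TTAAATTGCTGTRGTATT	16S-Reverse	CCGGTCTGAACTCASAWC	438
COI-long	Cox1-F	GGAACAATATATTTAATTTTTGG	CoxI-R	ATCTATCCCTACTGTAAATATATG	849
COI-short	COI-F	ATCATAAAKAYHTTGG	COI-R	GGGTGACCRAARAAHCA	691
COI-LCO	LCO1490	GGTCAACAAATCATAAAGATATTGG	HCO2198	TAAACTTCAGGGTGACCAAAAAATCA	710
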