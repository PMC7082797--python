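# name	site	cut_offset (top-strand positions from the site 5' end)
AluI	AGCT	2
DraI	TTTAAA	3
AflII	CTTAAG	1
ApaI	GGGCCC	5
AseI	ATTAAT	2
AvaII	GGWCC	1
BamHI	GGATCC	1
BclI	TGATCA	1
BglII	AGATCT	1
BstNI	CCWGG	2
ClaI	ATCGAT	2
DdeI	CTNAG	1
EcoRI	GAATTC	1
EcoRV	GATATC	3
HaeIII	GGCC	2
HhaI	GCGC	3
HindIII	AAGCTT	1
HinfI	GANTC	1
HpaII	CCGG	1
KpnI	GGTACC	5
MboI	GATC	0
MseI	TTAA	1
MspI	CCGG	1
NcoI	CCATGG	1
NdeI	CATATG	2
NheI	GCTAGC	1
NlaIII	CATG	4
PstI	CTGCAG	5
RsaI	GTAC	2
SacI	GAGCTC	5
SalI	GTCGAC	1
Sau3AI	GATC	0
ScaI	AGTACT	3
SmaI	CCCGGG	3
SpeI	ACTAGT	1
SphI	GCATGC	5
SspI	AATATT	3
StuI	AGGCCT	3
SwaI	ATTTAAAT	4
TaqI	TCGA	1
XbaI	TCTAGA	1
XhoI	CTCGAG	1
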