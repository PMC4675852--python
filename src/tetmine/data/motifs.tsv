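motif_id	iupac_pattern	category
ABRE	ACGTG	hormone
HSE	AGAANNTTCT	stress
LTR	CCGAC	stress
MeJA_CGTCA	CGTCA	hormone
MeJA_TGACG	TGACG	hormone
ROOTMOTIF	ATATT	tissue
POLLEN1LELAT52	AGAAA	tissue
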