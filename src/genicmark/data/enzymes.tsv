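name	site	common
EcoRI	GAATTC	yes
BamHI	GGATCC	yes
HindIII	AAGCTT	yes
DraI	TTTAAA	yes
EcoRV	GATATC	yes
PstI	CTGCAG	yes
SalI	GTCGAC	yes
XbaI	TCTAGA	yes
XhoI	CTCGAG	yes
KpnI	GGTACC	yes
SacI	GAGCTC	yes
SmaI	CCCGGG	yes
SphI	GCATGC	yes
NcoI	CCATGG	yes
NdeI	CATATG	yes
BglII	AGATCT	yes
ScaI	AGTACT	yes
SspI	AATATT	yes
ApaI	GGGCCC	yes
StuI	AGGCCT	yes
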