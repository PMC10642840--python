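# Bundled restriction-enzyme table (REBASE-style notation).
# name	site (caret = within-site cut; (a/b) = offsets past the 3' end of the site)
EcoRI	G^AATTC
BamHI	G^GATCC
XmaI	C^CCGGG
SmaI	CCC^GGG
PstI	CTGCA^G
NsiI	ATGCA^T
EcoRV	GAT^ATC
DraI	TTT^AAA
HpaI	GTT^AAC
HindIII	A^AGCTT
XhoI	C^TCGAG
SalI	G^TCGAC
NcoI	C^CATGG
NdeI	CA^TATG
NheI	G^CTAGC
SpeI	A^CTAGT
XbaI	T^CTAGA
MfeI	C^AATTG
BglII	A^GATCT
KpnI	GGTAC^C
SacI	GAGCT^C
SphI	GCATG^C
AatII	GACGT^C
NotI	GC^GGCCGC
AvaI	C^YCGRG
BstXI	CCANNNNN^NTGG
BsaI	GGTCTC(1/5)
BsmBI	CGTCTC(1/5)
BbsI	GAAGAC(2/6)
SapI	GCTCTTC(1/4)
PaqCI	CACCTGC(4/8)
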