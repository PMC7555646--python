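# Promoter cis-element library: name, IUPAC consensus, scan both strands
# Literature consensus strings; an approximation of database patterns.
ABRE	ACGTG	true
W-box	TTGACY	true
G-box	CACGTG	true
as-1	TGACG	true
CGTCA-motif	CGTCA	false
MBS	CAACTG	true
TATC-box	TATCCCA	true
GC-motif	CCCCCG	true
TC-rich	ATTTTCTTCA	true
AuxRR-core	GGTCCAT	true
GARE-motif	TCTGTTG	true
P-box	CCTTTTG	true
TGA-element	AACGAC	true
ERE	ATTTCAAA	true
LTR	CCGAAA	true
ARE	AAACCA	true
CAT-box	GCCACT	true
O2-site	GATGACATGG	true
circadian	CAANNNNATC	true
Sp1	GGGCGG	true
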