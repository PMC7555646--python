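# Pfam accession -> domain class used by the family architecture rule
PF00560	LRR
PF13306	LRR
PF13516	LRR
PF13855	LRR
PF08263	LRR
PF00069	kinase
PF07714	kinase
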