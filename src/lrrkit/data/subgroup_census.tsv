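subgroup	arabidopsis	medicago	soybean
RLK-Pelle_LRR-I	50	23	23
RLK-Pelle_LRR-II-1	14	14	26
RLK-Pelle_LRR-II-2	0	16	18
RLK-Pelle_LRR-III-1	46	38	87
RLK-Pelle_LRR-III-2	0	1	3
RLK-Pelle_LRR-IV	3	4	8
RLK-Pelle_LRR-V	9	8	18
RLK-Pelle_LRR-VI-1	5	6	13
RLK-Pelle_LRR-VI-2	8	7	16
RLK-Pelle_LRR-VII-1	5	5	10
RLK-Pelle_LRR-VII-2	3	3	7
RLK-Pelle_LRR-VII-3	2	2	6
RLK-Pelle_LRR-VIII	8	7	17
RLK-Pelle_LRR-IX	4	11	15
RLK-Pelle_LRR-Xa	4	3	5
RLK-Pelle_LRR-Xb-1	9	5	15
RLK-Pelle_LRR-Xb-2	1	2	4
RLK-Pelle_LRR-XI-1	33	99	123
RLK-Pelle_LRR-XI-2	2	1	2
RLK-Pelle_LRR-XII	8	65	28
RLK-Pelle_LRR-XIIIa	4	2	6
RLK-Pelle_LRR-XIIIb	3	2	8
RLK-Pelle_LRR-XIV	2	2	4
RLK-Pelle_LRR-XV	2	3	5
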