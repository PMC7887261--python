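candidate	stratum	platform	a	n_cases	c	n_controls
ATM	discovery	sequencing	2	1045	0	885
ATM	familial/copd	sequencing	0	380	0	318
ATM	tumor_atlas/refpop	sequencing	2	1015	5	134187
ATM	oncoarray	array	5	17878	0	13425
POMC	discovery	sequencing	6	1045	0	885
POMC	familial/copd	sequencing	4	380	0	318
POMC	tumor_atlas/refpop	sequencing	6	1015	207	134187
STAU2	discovery	sequencing	21	1045	4	885
STAU2	familial/copd	sequencing	4	380	0	318
STAU2	tumor_atlas/refpop	sequencing	0	1015	25	134187
MPZL2	discovery	sequencing	3	1045	0	885
MPZL2	familial/copd	sequencing	4	380	0	318
MPZL2	tumor_atlas/refpop	sequencing	5	1015	189	134187
MLNR	discovery	sequencing	9	1045	0	885
MLNR	familial/copd	sequencing	6	380	0	318
MLNR	tumor_atlas/refpop	sequencing	7	1015	431	134187
MLNR	affymetrix	array	29	5364	49	5724
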