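gene	direction	n_variants	n_patterns	carriers_case	carriers_control	kbac_p	cmc_p	cmc_or	cmc_ci_low	cmc_ci_high	oe	oe_ci_low	oe_ci_high	phenotype_score	phenotype
CCDC105	risk	20	11	28	5	0.012	0.013	5.63	0.87	31.4	0.71	0.46	1.12	0.12	PF
BMP8A	risk	3	4	11	2	0.014	0.014	4.22	1.14	36.3	0.80	0.49	1.35	0.32	PF
MME	risk	6	7	7	0	0.014	0.015	1.85	0.65	11.16	0.70	0.54	0.92	0.83	LC
NPHP3	risk	6	7	7	0	0.015	0.015	1.68	0.76	15.4	0.50	0.38	0.65	0.68	PF
MLNR	risk	5	6	11	2	0.005	0.022	4.19	1.12	38.9	0.51	0.50	1.16	0.09	PF
NKX6-1	risk	9	11	47	31	0.064	0.048	1.30	0.82	2.06	0.39	0.18	1.00	0.28	LC
ENAM	risk	7	8	9	2	0.043	0.065	2.94	0.79	9.07	0.60	0.44	0.84	0.32	PF
ATM	risk	15	15	16	11	0.591	0.098	1.58	0.69	7.04	0.60	0.51	0.71	0.95	LC
RHBDD3	risk	9	10	11	4	0.101	0.102	1.64	0.85	23.6	0.71	0.41	1.27	0.16	PF
STAU2	risk	27	31	107	76	0.141	0.213	1.21	0.89	1.65	0.14	0.07	0.32	0.23	LC
TALPID3	risk	11	12	17	8	0.139	0.403	1.64	0.93	2.24	0.54	0.42	0.72	0.61	PF
MPZL2	risk	6	7	7	3	0.153	0.403	1.34	0.77	2.13	1.34	0.90	1.86	0.12	LC
TP63	risk	6	7	9	3	0.396	0.539	1.20	0.59	12.3	0.13	0.07	0.27	0.87	LC
POMC	risk	6	7	7	5	0.744	0.790	1.45	0.57	3.71	0.74	0.42	1.38	0.30	PF
F13B	risk	5	6	7	5	0.965	0.905	1.02	0.81	1.27	0.59	0.41	0.85	0.34	PF
TXNDC15	protective	11	12	10	27	0.746	0.001	0.31	0.15	0.64	0.38	0.21	0.76	0.60	PF
GJB6	protective	2	3	0	6	0.877	0.008	0.12	0.02	0.66	1.07	0.66	1.74	0.31	LC
MOB3A	protective	3	4	3	12	0.587	0.008	0.21	0.05	0.67	0.96	0.54	1.70	0.10	LC
CASQ2	protective	2	4	15	26	0.955	0.013	0.73	0.44	1.23	0.94	0.65	1.38	0.36	PF
OR51J1	protective	2	3	1	6	0.351	0.037	0.14	0.03	0.84	0.19	0.07	0.88	0.10	PF
FAM111A	protective	5	6	11	21	0.406	0.076	0.42	0.20	0.92	2.09	0.66	1.95	0.29	LC
PHF13	protective	9	10	16	12	0.097	0.742	1.23	0.53	5.17	0.01	0.00	0.25	0.28	LC+PF
MLKL	protective	17	19	30	28	0.055	0.689	0.95	0.54	3.52	0.87	0.63	1.24	0.20	PF
CHEK2	protective	8	9	7	5	0.484	0.811	1.11	0.64	2.02	1.15	0.87	1.53	0.97	LC
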