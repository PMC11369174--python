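# Affinity validation set: FP-displacement K_D values (micromolar) for wild-type/mutant
# peptide pairs against bait domains, with the phage-selection mutation enrichment score
# and Mann-Whitney p value of the corresponding domain-mutation pair.
# kd values: "n.b." = no displacement within the titrated range; "<x" = upper limit.
# agreement_set = 1 marks the 24 primary records scored for phage/affinity agreement
# (importin-alpha minor-pocket rows and the score-less KPNA7 row are supplementary).
domain	pocket	gene	mutation	region	kd_wt	sem_wt	kd_mut	sem_mut	enrichment_score	p_value	agreement_set
ABL1_SH3		TP53	P72R	64-80	650	30	560	30	-6	6.30E-04	1
CASK_kinase		MAPT	R723W	717-731	n.b.		39	4	12	9.60E-07	1
CASK_kinase		FANCA	S4L	1-16	n.b.		15.0	0.7	6	6.30E-04	1
CLTC_NTD		BCL11A	C48F	44-56	1100	380	361	43	12	9.60E-07	1
CLTC_NTD		MITF	Y265C	258-271	191	27	206	13	-9.8	1.90E-07	1
CREBBP_KIX		KMT2A	L2854Q	2847-2861	380	30	340	10	-6.7	2.00E-04	1
GABARAPL1_ATG8		BUB1	S492F	486-501	5.5	0.7	<0.3		16	1.30E-08	1
G3BP1_NTF2		NSD1	L1797P	1793-1808	12	2	49	1	-7.4	5.10E-05	1
G3BP1_NTF2		CTNNB1	S33F	27-42	n.b.		57	2	9	1.90E-05	1
G3BP2_NTF2		BCL11A	C48F	44-56	n.b.		215	43	10	6.90E-06	1
GGA1_VHS		MYH9	D1424H	1419-1433	101	3	306	3	-10	8.00E-06	1
KEAP1_KELCH		SQSTM1	P348L	343-356	0.9	0.1	23	3	-16	7.80E-08	1
KPNA4_ARM	major	ABRAXAS1	R361Q	349-364	0.17	0.02	75	3	-6	4.50E-04	1
KPNA4_ARM	major	CREBBP	K13E	5-19	<0.00008		860	20	-6	4.50E-04	1
KPNA4_ARM	major	CDC45	R157C	152-166	0.090	0.003	7	1	-7	1.70E-04	1
KPNA4_ARM	major	ZNF526	K160T	152-167	135	3	n.b.		-6.4	4.80E-04	1
KPNA4_ARM	minor	ABRAXAS1	R361Q	349-364	22	3	297	16	-6	4.50E-04	0
KPNA4_ARM	minor	CREBBP	K13E	5-19	153	5	n.b.		-6	4.50E-04	0
KPNA4_ARM	minor	CDC45	R157C	152-166	91	11	545	70	-7	1.70E-04	0
KPNA4_ARM	minor	ZNF526	K160T	152-167	69	1	395	10	-6.4	4.80E-04	0
KPNA7_ARM	major	CDC45	R157C	152-166	6.6	0.7	380	15	n.d.		0
MAP1LC3A_ATG8		KRT1	L214P	209-224	55	5	580	30	-6	3.90E-04	1
MAP1LC3B_ATG8		BUB1	S492F	486-501	7	1	1.6	0.1	12	7.40E-07	1
MAP1LC3B_ATG8		SQSTM1	P348L	334-349	0.5	0.1	0.6	0.1	7.6	1.90E-04	1
MAP1LC3B_ATG8		BRCA2	T298I/V299L/V300R	292-307	3.12	0.08	0.52	0.01	15	3.70E-08	1
NEDD4_WW2		SCNN1B	P616R	611-626	39	3	80	7	-12	7.40E-07	1
NEDD4_WW2		SCNN1B	P618R	611-626	39	3	603	73	-16	1.20E-08	1
PPIA		KMT2D	P2301S	2993-3008	177	20	1675	144	-8	5.10E-05	1
USP7_MATH		CHK2	Q51K	38-53	3.1	0.2	4.7	0.3	-6	3.60E-04	1
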