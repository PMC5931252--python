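gene	mean_carcinoma	mean_normal	fold_change	p_value	adj_p_value	subset_note
ANAPC1	75.40	43.01	1.75	<0.001	<0.001	overall_subnote
ANAPC11	11.96	7.71	1.55	<0.001	<0.001	.
ANAPC13	26.31	17.35	1.52	<0.001	<0.001	mss_only
ANAPC7	65.84	43.85	1.50	<0.001	<0.001	overall_subnote
BUB1	53.35	18.38	2.90	<0.001	<0.001	.
BUB1B	41.59	17.15	2.42	<0.001	<0.001	.
BUB3	94.35	60.85	1.55	<0.001	<0.001	overall_subnote
CCNA2	40.09	14.62	2.74	<0.001	<0.001	.
CCNB1	32.40	9.25	3.50	<0.001	<0.001	.
CCNB2	21.30	12.39	1.72	<0.001	<0.001	.
CCND1	317.79	122.64	2.59	<0.001	<0.001	.
CCND2	773.45	483.06	1.60	<0.001	<0.001	.
CCNE1	8.70	4.80	1.81	<0.001	<0.001	.
CDC14A	16.20	31.59	0.51	<0.001	<0.001	.
CDC16	90.37	58.88	1.53	<0.001	<0.001	overall_subnote
CDC20	22.28	10.17	2.19	<0.001	<0.001	.
CDC25A	21.63	10.61	2.04	<0.001	<0.001	.
CDC25B	169.88	60.96	2.79	<0.001	<0.001	.
CDC25C	7.95	3.46	2.30	<0.001	<0.001	.
CDC45	14.50	6.61	2.19	<0.001	<0.001	.
CDC6	32.30	11.33	2.85	<0.001	<0.001	.
CDC7	19.56	10.85	1.80	<0.001	<0.001	.
CDK1	41.36	11.94	3.46	<0.001	<0.001	.
CDK2	45.70	24.96	1.83	<0.001	<0.001	.
CDK4	66.65	26.90	2.48	<0.001	<0.001	.
CDK6	289.15	166.12	1.74	<0.001	<0.001	.
CDK7	23.94	13.17	1.82	<0.001	<0.001	.
CDKN1C	5.45	3.38	1.61	<0.001	<0.001	overall_subnote
CDKN2B	24.21	74.65	0.32	<0.001	<0.001	.
CHEK1	37.56	15.63	2.40	<0.001	<0.001	.
DBF4	23.05	11.73	1.97	<0.001	<0.001	.
E2F1	27.36	9.14	2.99	<0.001	<0.001	.
E2F3	57.78	34.90	1.66	<0.001	<0.001	overall_subnote
E2F5	46.80	30.87	1.52	<0.001	<0.001	overall_subnote
ESPL1	39.52	18.82	2.10	<0.001	<0.001	.
HDAC2	102.64	58.70	1.75	<0.001	<0.001	.
MAD2L1	15.96	4.92	3.24	<0.001	<0.001	.
MAD2L2	9.52	5.51	1.73	<0.001	<0.001	.
MCM2	44.16	17.25	2.56	<0.001	<0.001	.
MCM3	107.53	41.43	2.60	<0.001	<0.001	.
MCM4	115.85	43.65	2.65	<0.001	<0.001	.
MCM5	78.55	50.31	1.56	<0.001	0.002	msi_only
MCM6	55.02	23.15	2.38	<0.001	<0.001	.
MCM7	135.12	64.18	2.11	<0.001	<0.001	.
MDM2	358.47	229.39	1.56	<0.001	<0.001	msi_only
MYC	181.11	49.00	3.70	<0.001	<0.001	.
ORC1	13.40	7.68	1.74	<0.001	<0.001	.
ORC5	23.07	15.12	1.53	<0.001	<0.001	overall_subnote
ORC6	13.15	4.62	2.84	<0.001	<0.001	.
PCNA	37.26	12.83	2.91	<0.001	<0.001	.
PKMYT1	45.18	16.72	2.70	<0.001	<0.001	.
PRKDC	927.46	395.35	2.35	<0.001	<0.001	.
PTTG1	14.78	5.48	2.70	<0.001	<0.001	.
RAD21	257.68	139.20	1.85	<0.001	<0.001	.
RB1	104.85	58.44	1.79	<0.001	<0.001	overall_subnote
RBL1	53.52	23.32	2.30	<0.001	<0.001	.
SKP2	49.31	24.13	2.04	<0.001	<0.001	.
SMC1A	208.24	133.73	1.56	<0.001	<0.001	.
SMC1B	3.71	6.20	0.60	<0.001	<0.001	overall_subnote
SMC3	123.45	66.72	1.85	<0.001	<0.001	.
TFDP1	119.20	54.04	2.21	<0.001	<0.001	.
TGFB2	9.23	4.52	2.04	<0.001	<0.001	overall_subnote
TP53	105.07	59.63	1.76	<0.001	<0.001	.
TTK	28.80	10.97	2.62	<0.001	<0.001	.
WEE1	129.22	85.54	1.51	<0.001	<0.001	msi_only
WEE2	1.33	2.11	0.63	0.002	0.002	.
YWHAB	389.26	223.04	1.75	<0.001	<0.001	overall_subnote
YWHAE	214.66	141.14	1.52	<0.001	<0.001	overall_subnote
YWHAG	241.75	119.30	2.03	<0.001	<0.001	.
YWHAH	102.59	66.00	1.55	<0.001	<0.001	.
YWHAQ	130.47	72.74	1.79	<0.001	<0.001	.
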