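subject	ipl_x	ipl_y	ipl_z	ipl_label	dist_P3	dist_IPL	dlpfc_x	dlpfc_y	dlpfc_z	dlpfc_label	dist_BA9	dist_BA46	dist_5cm	dist_F3	dist_BA8/9
Ctrl1	-60	-60	14	MTG	43.46	36.28	-40	12	58	MFG	31.87	44.11	6.78	16.52	12.33
Ctrl2	-50	-72	26	AG	28.37	27.57	-42	26	46	MFG	14.70	25.88	12.57	4.58	9.38
Ctrl3	-54	-72	26	AG	36.89	33.76	-42	24	48	MFG	17.20	28.67	9.90	4.12	7.48
Ctrl4	-48	-62	42	AG	14.04	9.80	-36	32	46	MFG	8.49	24.21	18.71	7.55	11.66
Ctrl5	-50	-74	24	MTG/MOG	30.61	30.33	-52	16	38	MFG	27.28	29.29	17.83	19.42	22.09
Ctrl6	-62	-48	12	MTG	49.20	38.94	-34	34	48	MFG	9.17	26.04	20.64	9.85	12.81
Ctrl7	-56	-70	32	AG	26.48	24.41	-42	24	52	MFG	19.39	31.97	9.06	5.74	6.32
Ctrl8	-36	-72	50	IPL	6.40	20.10	-48	10	52	PCG	32.74	41.30	8.60	18.47	16.97
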