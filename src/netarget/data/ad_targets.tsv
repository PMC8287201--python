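subject	ipl_x	ipl_y	ipl_z	ipl_label	dist_P3	dist_IPL	dlpfc_x	dlpfc_y	dlpfc_z	dlpfc_label	dist_BA9	dist_BA46	dist_5cm	dist_F3	dist_BA8/9
Pt1	-34	-80	44	IPL	16.16	27.93	-52	24	40	MFG	21.26	24.04	18.60	16.16	20.10
Pt2	-38	-66	42	AG	9.00	14.00	-48	4	56	PCG	39.45	48.44	13.64	24.60	22.00
Pt3	-44	-68	24	MOG	27.73	26.08	-46	38	22	MFG	20.59	4.69	38.13	30.15	35.44
Pt4	-52	-72	26	AG	29.27	28.07	-48	32	32	MFG	15.62	12.08	27.17	20.12	25.38
Pt5	-36	-82	42	MOG	18.47	29.39	-58	16	40	MFG/PCG	31.11	32.34	20.83	23.35	25.77
Pt6	-34	-82	44	IPL/MOG	17.92	29.80	-50	32	38	MFG	15.36	16.91	23.79	17.12	22.18
Pt7	-40	-66	36	AG	15.13	16.12	-50	16	46	MFG	26.76	33.20	10.86	15.13	16.37
Pt8	-56	-54	28	AG	31.58	21.63	-40	28	56	MFG	19.29	33.85	13.64	8.77	8.25
Pt9	-32	-88	24	MOG	35.34	42.24	-38	18	50	MFG	22.45	4.69	4.69	7.28	4.90
Pt10	-42	-62	30	AG	21.75	18.00	-42	20	26	IFG	23.58	26.50	26.50	22.91	26.76
Pt11	-38	-80	40	MOG	17.80	27.35	-30	36	44	MFG	7.48	25.02	25.02	14.18	17.20
Pt12	-54	-56	40	IPL	21.84	11.83	-52	10	54	MFG/PCG	35.16	12.25	12.25	21.38	20.10
Pt13	-34	-84	42	MOG	20.52	31.87	-38	12	50	MFG	27.93	4.69	4.69	13.15	10.39
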