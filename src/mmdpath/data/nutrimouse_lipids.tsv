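sample_id	C14.0	C16.0	C18.0	C16.1n.9	C16.1n.7	C18.1n.9	C18.1n.7	C20.1n.9	C20.3n.9	C18.2n.6	C18.3n.6	C20.2n.6	C20.3n.6	C20.4n.6	C22.4n.6	C22.5n.6	C18.3n.3	C20.3n.3	C20.5n.3	C22.5n.3	C22.6n.3
m01	0.34	26.45	10.22	0.35	3.1	16.98	2.41	0.26	0	8.93	0	0	0.78	3.07	0	0	5.97	0.37	8.62	1.75	10.39
m02	0.38	24.04	9.93	0.55	2.54	20.07	3.92	0.23	0	14.98	0.3	0.3	1.64	15.34	0.58	2.1	0	0	0	0.48	2.61
m03	0.36	23.7	8.96	0.55	2.65	22.89	3.96	0.26	0.19	16.06	0.27	0.33	1.51	13.27	0.54	1.77	0	0	0	0.22	2.51
m04	0.22	25.48	8.14	0.49	2.82	21.92	2.52	0	0	13.89	0	0	1.1	3.92	0	0	0.49	0	2.99	1.04	14.99
m05	0.37	24.8	9.63	0.46	2.85	21.38	2.96	0.3	0.27	14.55	0.27	0.23	1.58	11.85	0.32	0.44	0.42	0	0.3	0.35	6.69
m06	1.7	26.04	6.59	0.66	7.26	28.23	8.99	0.36	2.89	3.47	2.66	0	0.81	5.09	0	0.56	0	0	0	2.13	2.56
m07	0.35	25.94	9.68	0.36	3.6	17.62	2.15	0.25	0	8.73	0	0	0.68	2.57	0	0	8.4	0.42	7.37	2.05	9.84
m08	0.34	28.63	9.95	0.29	3.27	17.02	1.99	0.31	0	7.75	0	0	0.72	2.64	0	0	6.01	0.39	7.96	2.33	10.4
m09	0.22	25.34	8.81	0.44	2.36	18.39	1.81	0	0	15.65	0	0	1.07	4.23	0	0	0.55	0	3.13	1.65	16.36
m10	1.38	28.49	5.63	0.9	7.01	36.68	8.85	0.21	2.03	2.31	0	0	0.59	3.67	0	0.39	0	0	0	0	1.86
m11	0.26	25.73	8.3	0.43	2.74	21.75	2.64	0	0	12.64	0	0	1.05	3.75	0	0	0.43	0	2.9	1.16	16.21
m12	0.44	24.28	8.63	0.53	3.33	23.86	3.02	0.26	0.2	15.02	0.23	0.21	1.32	10.3	0.27	0.29	0.53	0	0.25	0.43	6.61
m13	0.32	24.63	9.99	0.45	2.39	17.93	3.49	0.27	0.21	15.74	0.28	0.36	1.64	15.76	0.72	2.52	0	0	0	0	3.27
m14	0.34	26.04	9.81	0.35	2.36	20.14	2.33	0.26	0.22	15.53	0.3	0.19	1.37	11.76	0.31	0.45	0.54	0	0.23	0.45	7.04
m15	0.35	24.76	9.38	0.54	2.47	19.66	4.02	0.22	0.19	15.65	0.47	0.35	1.6	15.07	0.66	1.89	0	0	0	0	2.71
m16	0.24	26.46	10.97	0.31	2.81	14.69	1.88	0.31	0	9.38	0	0	0.78	3.12	0	0	6.22	0.37	9.48	2.01	10.96
m17	1.21	23.45	5.59	0.67	6.31	33.84	8.56	0.47	2.54	2.77	5.07	0	0.67	3.87	0	0.43	0	0	0	2.58	1.99
m18	0.3	29.72	8.95	0.45	2.86	17.79	2.01	0	0	11.89	0	0	1	3.83	0	0	0	0	2.79	1.08	17.35
m19	1.3	27	5.72	0.81	7.86	33.5	9.88	0	2.13	3.56	0	0	0.82	4.96	0	0	0	0	0	0	2.44
m20	0.38	24.09	8.22	0.6	3.89	24.61	3.89	0.27	0.27	13.54	0.24	0.23	1.44	10.6	0.31	0.36	0.43	0	0.35	0.31	5.97
m21	3.24	23.59	2.68	1.11	13.09	35.61	11.41	0.37	0.22	5.65	0.17	0.05	0.2	1.55	0	0.17	0.09	0	0.15	0	0.64
m22	0.6	19.95	3.18	1.21	4.89	35.91	4.58	0.3	0.07	21.1	0.41	0.31	0.53	2.98	0.18	0.08	1	0.07	0.25	0.24	2.16
m23	0.38	17.64	6.99	0.74	2.58	21.23	2.85	0.26	0	33.14	0.66	0.61	0.74	8.67	0.65	0.98	0.1	0	0.09	0	1.7
m24	0.44	22.73	4.71	0.75	2.27	25.1	1.91	0.38	0	22.65	0	0.27	0.38	1.27	0	0.21	1.16	0	2.17	2.04	11.56
m25	0.47	14.65	4.29	0.66	2.88	23.15	2.85	0.45	0.07	40.02	0.85	0.83	1.04	4.72	0.73	1.13	0.14	0	0.07	0.06	0.91
m26	0.64	20.49	2.71	1.09	4.05	38.32	5.07	0.26	0.07	21.52	0.28	0.32	0.35	1.85	0.14	0.07	1.17	0.07	0.16	0.15	1.22
m27	0.52	18.44	5.21	0.87	3.37	32.04	3.76	0.42	0	23.93	0.32	0.09	0.64	4.76	0.26	0.19	1.16	0	0.3	0.28	3.44
m28	0.49	17.72	6.02	0.58	3.77	21.04	1.77	0.65	0	13.84	0.09	0.12	0.22	1.39	0.11	0	21.5	0.64	4.1	1.94	4.02
m29	0.4	21.7	6.12	0.78	2.07	22.49	1.82	0.44	0	22.05	0	0.24	0.47	1.87	0	0.19	1.31	0	2.65	2.16	13.26
m30	0.61	16.25	4.55	0.61	5.42	21.43	2.22	0.25	0	14.75	0.12	0.1	0.22	1.52	0	0	21.62	0.48	3.86	1.55	4.45
m31	3.19	22.91	3.6	0.99	13.9	33.55	10.64	0.3	0.07	5.45	0.18	0	0.4	2.97	0.07	0.38	0.07	0	0.18	0	1.16
m32	2.26	23.27	1.68	1.5	10.38	41.23	15.03	0.2	0.23	2.79	0.14	0	0.11	0.75	0	0.07	0	0	0.07	0	0.28
m33	0.6	20.25	3.09	1.18	3.66	36.59	4.75	0.36	0.07	22.93	0.31	0.33	0.41	2	0.17	0.07	1.31	0.07	0.2	0.23	1.41
m34	0.54	20.18	4.51	0.71	3.55	24.82	3.77	0.39	0	31.31	0.46	0.54	0.73	5.47	0.6	0.95	0.17	0	0	0.21	1.11
m35	0.39	20.71	6.41	0.71	2.18	24.09	1.83	0.4	0	23.09	0	0.24	0.4	1.9	0	0	1.45	0	2.82	1.8	11.57
m36	2.92	21.79	3.56	1.23	10.66	38.27	11.55	0.38	0.33	5.6	0.18	0.07	0.26	1.83	0.05	0.17	0.07	0	0.13	0.3	0.64
m37	0.63	21.57	3.97	0.82	5.14	25.53	3.18	0.33	0	12.6	0.08	0.11	0.17	0.96	0.06	0	18.11	0.52	2.66	1.27	2.29
m38	0.36	25.23	10.33	0.45	1.59	16.49	1.53	0.37	0	18.25	0	0.26	0.57	3.02	0	0	0.71	0	2.91	1.64	16.28
m39	0.64	16.2	5.77	0.67	4.1	25.12	2.11	0.21	0	21.06	0.21	0.13	0.14	1.84	0	0	14.39	0.24	2.31	0.98	3.87
m40	0.4	20.7	7.4	0.63	2.72	19.97	3.13	0.4	0	27.33	0.43	0.59	0.89	11.18	0.63	1.62	0	0	0.13	0	1.83
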