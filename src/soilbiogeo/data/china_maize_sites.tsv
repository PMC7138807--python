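sample_id	latitude	longitude	pH	AK	OC	TN	AN	AP	PRE	TEM	soil_type
S01	18.65	109.67	7.68	117.10	18.26	0.78	43.75	61.98	2162.8	24.8	sandy clay loam
S02	25.00	101.51	5.46	167.70	26.40	1.06	103.25	15.83	937.2	16.2	clay loam
S03	27.92	112.75	7.93	125.20	14.87	0.68	35.00	17.44	1377.0	17.4	loamy clay
S04	29.23	120.05	8.00	116.10	10.42	0.44	19.25	8.30	1386.6	17.7	sandy loam
S05	29.52	106.66	7.96	145.40	29.72	0.96	98.00	30.48	1108.0	18.4	sandy loam
S06	31.88	106.16	8.39	55.10	3.16	0.44	3.50	3.39	1013.5	16.6	loamy clay
S07	33.28	114.30	5.23	135.30	13.62	0.56	94.50	21.82	863.1	14.8	clay loam
S08	34.36	109.12	8.33	198.20	16.49	0.84	31.50	14.17	569.4	13.8	clay loam
S09	35.15	111.23	8.65	234.70	16.75	0.50	35.00	17.03	519.2	13.2	silty clay loam
S10	35.95	116.57	7.87	86.50	14.86	0.56	87.50	9.45	614.3	14.0	clay loam
S11	36.25	106.39	8.72	208.30	11.67	0.44	49.00	4.92	425.5	6.9	clay loam
S12	36.59	107.27	8.74	102.80	5.86	0.16	5.25	4.45	409.5	9.2	silty clay loam
S13	36.64	119.41	6.37	288.20	15.25	0.62	31.50	87.36	546.5	12.8	loamy clay
S14	37.36	114.79	5.83	135.40	37.52	1.24	63.00	175.37	478.2	13.2	sandy loam
S15	38.45	77.25	8.76	207.30	13.73	0.50	5.25	38.06	61.3	12.0	sandy loam
S16	39.52	112.53	8.50	80.70	23.17	0.68	29.75	127.64	407.3	6.1	sandy loam
S17	39.88	117.73	8.86	248.90	18.94	0.78	87.50	52.70	623.8	11.9	clay loam
S18	39.94	121.52	7.04	105.00	10.06	0.56	21.00	14.10	617.5	9.9	sandy clay loam
S19	40.75	111.97	8.45	143.40	8.81	0.40	175.00	57.88	396.5	7.3	loamy clay
S20	43.87	126.75	8.04	323.00	34.16	1.00	47.25	56.16	580.0	5.0	loamy clay
S21	46.51	124.96	8.18	144.40	26.59	1.00	66.50	28.88	434.6	3.8	sandy loam
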