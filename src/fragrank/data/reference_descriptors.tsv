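pdb	hac_ligand	hac_fragment	hbd_ligand	hbd_fragment	hba_ligand	hba_fragment	mw_ligand	mw_fragment
1TQF	40	28	4	1	9	6	571.7	395.1
1W51	39	28	3	3	7	4	531.7	374.2
2EWY	38	37	3	3	5	5	504.6	490.2
2F3F	34	19	5	3	8	3	514.7	297.1
2IQG	41	28	3	3	6	6	677.6	374.2
2OF0	19	17	1	1	4	4	265.3	237.1
2OHL	13	10	2	0	2	1	144.2	129.1
2OHK	13	10	2	0	2	1	144.2	129.1
2OHM	15	14	3	1	3	2	199.3	184.1
2OHN	15	13	1	1	1	1	193.3	175.1
2OHP	21	17	3	1	3	2	237.3	222.1
2OHQ	23	20	2	0	3	1	304.4	259.1
2OHR	23	20	3	1	4	3	276.3	261.1
2OHS	24	20	3	1	5	3	306.4	261.1
2OHT	24	23	4	2	4	3	314.4	299.1
2OHU	32	31	4	2	6	5	421.5	406.2
2P83	44	28	5	3	10	4	610.7	374.2
2Q11	31	30	2	0	6	5	288.4	403.2
2Q15	37	36	2	0	6	5	496.6	487.3
2QK5	42	28	3	3	7	4	581.7	374.2
2QMD	44	32	3	3	7	5	607.7	430.2
2QMF	43	31	3	3	7	5	593.7	416.2
2QP8	40	25	3	3	7	4	559.7	338.2
2QU2	24	17	4	1	5	1	318.4	219.1
2QU3	29	17	4	0	5	0	427.9	236.1
2VA5	19	17	4	2	5	3	254.3	223.1
2VA6	24	18	2	1	5	2	323.4	234.1
2VA7	26	18	2	1	5	2	341.4	234.1
2WF4	40	35	2	4	9	7	554.7	492.2
2WJO	35	34	3	1	4	5	473.6	458.2
2ZDZ	35	24	4	1	7	2	486.9	311.1
2ZE1	34	26	5	2	7	3	516.4	338.1
2ZJH	20	13	1	0	3	1	292.4	175.1
2ZJI	24	13	1	0	5	1	352.5	175.1
2ZJJ	20	13	2	1	4	2	297.4	176.1
2ZJK	21	13	2	1	4	2	311.4	176.1
2ZJL	15	13	1	0	5	1	431.4	175.1
2ZJM	35	24	3	1	9	4	526.1	324.1
2ZJN	36	24	3	1	9	4	540.1	324.1
3BRA	10	6	3	0	2	0	137.2	78.1
3BUF	11	6	3	0	2	0	151.2	78.1
3BUG	12	6	3	0	2	0	165.2	78.1
3BUH	16	12	3	0	2	0	219.3	160.1
3CIB	44	32	3	3	6	4	605.8	428.2
3CIC	45	32	3	3	8	5	620.7	427.2
3CID	44	31	3	3	8	5	606.7	413.2
3DV5	35	27	3	4	6	4	487.7	372.2
3EXO	25	19	2	1	6	3	340.4	247.1
3FKT	36	30	2	1	7	4	491.6	400.2
3H0B	28	19	3	1	8	2	386.4	248.1
3HVG	11	6	3	1	4	2	153.2	80.1
3HW1	16	15	2	0	4	3	214.3	199.1
3IGB	22	19	2	0	4	3	418.5	275.1
3IN3	26	23	2	1	6	4	343.4	298.1
3IN4	30	23	2	1	7	5	400.5	299.1
3IND	24	21	2	1	4	2	323.5	278.2
3INE	27	21	2	1	5	2	367.5	278.2
3INF	29	23	2	1	6	3	386.4	297.1
3INH	32	23	2	1	7	4	445.4	298.1
3IVH	34	28	3	3	4	4	472.6	380.2
3IVI	37	31	4	4	6	6	510.6	418.2
3KMX	17	6	3	0	3	0	272.8	78.1
3KMY	16	14	2	0	2	1	232.7	183.1
3KN0	24	23	2	0	4	3	321.4	306.2
3L3A	32	24	2	0	5	2	442.9	310.2
3L5B	20	12	2	1	4	2	293.8	158.1
3L5C	32	23	4	3	8	5	432.3	306.1
3L5D	28	12	4	1	7	2	387.5	158.1
3L5E	39	33	3	2	7	4	535.8	446.3
3L5F	23	20	2	2	4	2	319.5	274.2
3L38	33	31	2	0	6	5	453.9	404.1
3L58	42	28	3	3	7	4	581.7	374.2
3L59	17	12	2	1	4	2	251.7	158.1
3LHG	28	23	2	1	5	3	378.4	297.1
3LNK	45	33	3	3	7	6	620.7	443.2
3LPI	46	34	3	3	7	7	656.8	479.2
3LPJ	44	32	3	3	7	6	606.7	429.2
3MSJ	15	9	3	1	4	2	225.7	118.1
3MSK	24	22	2	0	5	4	348.9	299.2
3MSL	25	23	3	1	5	4	347.9	313.2
3MSM	28	26	3	1	5	4	400.9	351.2
3PI5	29	24	3	1	5	1	480.4	337.2
3QBH	38	27	3	2	8	3	544.7	380.2
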