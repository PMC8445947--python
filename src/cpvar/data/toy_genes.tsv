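gene	contig	coding_start	coding_end
GENE01	1	1000000	1009999
GENE02	1	1100000	1109999
GENE03	1	1200000	1209999
GENE04	1	1300000	1309999
GENE05	1	1400000	1409999
GENE06	1	1500000	1509999
GENE07	1	1600000	1609999
GENE08	1	1700000	1709999
GENE09	1	1800000	1809999
GENE10	1	1900000	1909999
GENE11	1	2000000	2009999
GENE12	1	2100000	2109999
GENE13	1	2200000	2209999
GENE14	1	2300000	2309999
GENE15	1	2400000	2409999
GENE16	1	2500000	2509999
GENE17	1	2600000	2609999
GENE18	1	2700000	2709999
GENE19	1	2800000	2809999
GENE20	1	2900000	2909999
GENE21	1	3000000	3009999
GENE22	1	3100000	3109999
GENE23	1	3200000	3209999
GENE24	1	3300000	3309999
GENE25	1	3400000	3409999
GENE26	1	3500000	3509999
GENE27	1	3600000	3609999
GENE28	1	3700000	3709999
GENE29	1	3800000	3809999
GENE30	1	3900000	3909999
GENE31	2	1000000	1009999
GENE32	2	1100000	1109999
GENE33	2	1200000	1209999
GENE34	2	1300000	1309999
GENE35	2	1400000	1409999
GENE36	2	1500000	1509999
GENE37	2	1600000	1609999
GENE38	2	1700000	1709999
GENE39	2	1800000	1809999
GENE40	2	1900000	1909999
GENE41	2	2000000	2009999
GENE42	2	2100000	2109999
GENE43	2	2200000	2209999
GENE44	2	2300000	2309999
GENE45	2	2400000	2409999
GENE46	2	2500000	2509999
GENE47	2	2600000	2609999
GENE48	2	2700000	2709999
GENE49	2	2800000	2809999
GENE50	2	2900000	2909999
GENE51	2	3000000	3009999
GENE52	2	3100000	3109999
GENE53	2	3200000	3209999
GENE54	2	3300000	3309999
GENE55	2	3400000	3409999
GENE56	2	3500000	3509999
GENE57	2	3600000	3609999
GENE58	2	3700000	3709999
GENE59	2	3800000	3809999
GENE60	2	3900000	3909999
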