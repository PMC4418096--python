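sno	name	length	mature	precursor	mature_offset	published_arm	tpm_values	note
1	ast-Novel-1-3p	20	AGTCATTAATGATATTAGAC	AUUUAUGGGAAAUAAUCUCUUUAAUCAGGCUUUAUAGUCAUUAAUGAUAUUAGACUGCAAUUCUAAAGGAAUAAUUUAAUUUAUUAAGGCUUAAGAAUUAAAAGAUUAAUACAAAUAUUUUCA	35	3p	0.37;0.00;0.06;0.05;0.08;0.00	
2	ast-Novel-1-5p	21	ATAATTTAATTTATTAAGGCT	AUUUAUGGGAAAUAAUCUCUUUAAUCAGGCUUUAUAGUCAUUAAUGAUAUUAGACUGCAAUUCUAAAGGAAUAAUUUAAUUUAUUAAGGCUUAAGAAUUAAAAGAUUAAUACAAAUAUUUUCA	70	5p	0.18;0.16;2.84;0.18	
3	ast-Novel-2-3p	23	GTATTCAATTTGTATATCGTCGT	UUGGACCUUACUUAAAUUUGUAUUCAAUUUGUAUAUCGUCGUCAUCAGAAUAUAUUAUAAGAUUAAUAAUUUUCUAAAUAUUUUAUUAAAUAAUAUGUCAGGUCAAGGUGCAGUUUAUGUUUAAGUAG	19	3p	0.18;0.10;0.08	
4	ast-Novel-2-5p	19	ATTGATAATCCACGTTGGA	AUUGAUAAUCCACGUUGGACCUUACUUAAAUUUGUAUUCAAUUUGUAUAUCGUCGUCAUCAGAAUAUAUUAUAAGAUUAAUAAUUUUCUAAAUAUUUUAUUAAAUAAUAUGUCAGGUCAAGGUGCAGUUUAUGUUUAAGUAG	0	5p	0.37;0.54;0.16;0.11	precursor extended 5prime (layout truncation)
5	ast-Novel-3-3p	24	TTAAGATTGGTATGATTAGCGTCT	UUUCCUUUAAGAUUGGUAUGAUUAGCGUCUUGUUUAGCAGAAACUAAUCGUACUCCUUUU	6	3p	0.16;0.12;0.24	
6	ast-Novel-3-5p	24	AAACTAATCGTACTCCTTTTGATT	UUUCCUUUAAGAUUGGUAUGAUUAGCGUCUUGUUUAGCAGAAACUAAUCGUACUCCUUUUGAUU	40	5p	0.16	precursor extended 3prime (layout truncation)
7	ast-Novel-4-3p	18	AATGGGTAGTCGAAGATT	AAUUGCUCAUGGUUUAUGUUCAUCUGGAUUAUUUUGUUUAGCUAAUAUUUCUUACGAACGAAUGGGUAGUCGAAGAUUAUUAAUUAAUAA	60	3p	6.00;0.47;0.16	
8	ast-Novel-4-5p	22	AATTGCTCATGGTTTATGTTCA	AAUUGCUCAUGGUUUAUGUUCAUCUGGAUUAUUUUGUUUAGCUAAUAUUUCUUACGAACGAAUGGGUAGUCGAAGAUUAUUAAUUAAUAA	0	5p	0.39	
9	ast-Novel-5-3p	21	CGTAGTTTCTACATTAGGAGT	UUUUACUUUUUUUGUAGGAUCAAUAUGAUUUAUACCCGUAGUUUCUACAUUAGGAGUAAU	36	3p	0.12;0.10;0.04	
10	ast-Novel-5-5p	21	ACTTTTTTTGTAGGATCAATA	UUUUACUUUUUUUGUAGGAUCAAUAUGAUUUAUACCCGUAGUUUCUACAUUAGGAGUAAU	4	5p	0.60;0.42;0.56;0.18	
11	ast-Novel-6-3p	25	TTTCGGATATGAATCAAAGTAATTT	ACCACUUAAAUUUCGGAUAUGAAUCAAAGUAAUUUUCAUCAAUUCCCUCUACCCUCAUGAGCGAGUGAUGUAAUGUACUCUCGUUCUGGACGAUUUUCAACCACUUAAAU	10	3p	100.76;44.78;95.03;141.73;135.20;796.74	
12	ast-Novel-6-5p	21	CGTTCTGGACGATTTTCAACC	ACCACUUAAAUUUCGGAUAUGAAUCAAAGUAAUUUUCAUCAAUUCCCUCUACCCUCAUGAGCGAGUGAUGUAAUGUACUCUCGUUCUGGACGAUUUUCAACCACUUAAAU	81	5p	0.37;0.61	
13	ast-Novel-7-3p	23	AGCCGAACCAGCAGTACGAGTTT	GACCCGACCGAGCCGAACCAGCAGUACGAGUUUUAACGCACGUUUCUUCGACUGGGAGCGUGGCGUCUCCUGUAACGCGGCUACUCGUGG	10	3p	0.04	
14	ast-Novel-7-5p	22	CGTCTCCTGTAACGCGGCTACT	GACCCGACCGAGCCGAACCAGCAGUACGAGUUUUAACGCACGUUUCUUCGACUGGGAGCGUGGCGUCUCCUGUAACGCGGCUACUCGUGG	63	5p	0.28;0.30;0.31;0.04;0.18	
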