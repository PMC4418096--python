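sno	mirna	target	pbs_category	scr_category	antimir_category	rnahybrid_predicted	go_term	cleavage_position	ortholog	curation
1	miR-989	ASTE002227	2	4	2	1	protein binding	500	AGAP003558	printed
2	miR-989	ASTE014169	0	0	0	0		151		printed
3	miR-989	ASTE004090	3	3	4	0	signal transduction	3429	AGAP002261	printed
4	miR-989	ASTE010155	0			0	DNA binding	840	AGAP003982	printed
5	miR-989	ASTE008099	4			0	protein binding	553	AGAP003439	printed
6	miR-989	ASTE003651	4			0	aminoacyl-tRNA ligase activity	1680	AGAP004708	printed
7	miR-989	ASTE007120	4	2	2	0		2092 and 1931	AGAP000879	printed
8	miR-989	ASTE014120	2	4	2	0		275		printed
9	miR-989	ASTE010290	4	2	2	0		1682	AGAP005504	printed
10	miR-989	ASTE002911	2	4	2	0	nucleic acid binding	731	AGAP004361	printed
11	miR-989	ASTE008381	4	2		1		984	AGAP010075	layout
12	miR-989	ASTE004431	4			0	proteolysis	1824	AGAP007280	printed
13	miR-989	ASTE003701	4			1		795	AGAP010226	printed
14	miR-989	ASTE011654	2	3	2	0		2304		printed
15	miR-989	ASTE005749	4			1		2347	AGAP001150	printed
16	miR-989	ASTE003996	2	4		0	integral component of membrane	1681	AGAP004486	layout
17	miR-219	ASTE006120	4			0		1650	AGAP004892	printed
18	miR-219	ASTE006196	4			0	proteolysis	4239	AGAP006203	printed
19	miR-219	ASTE011346	4			0		1764	AGAP004892	printed
20	miR-219	ASTE007196	4			0		1442	AGAP001357	printed
21	miR-219	ASTE002692	4			0	GTP binding	1763	AGAP009441	printed
22	miR-219	ASTE009304	4			0	protein binding	1268	AGAP011439	printed
23	miR-285	ASTE005579	2			0	acid phosphatase activity	337	AGAP002387	printed
24	miR-7	ASTE008161	4			0		428	AGAP010789	printed
25	miR-7	ASTE001260	4			0		677	AGAP008905	printed
26	miR-7	ASTE008160	4			0		383	AGAP010789	printed
27	miR-7	ASTE010939	4			0		2608	AGAP012493	printed
28	miR-7	ASTE002046	4			0	ATP binding	211	AGAP002996	printed
29	miR-7	ASTE003640	2			0	metabolic process	1342	AGAP004721	printed
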