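sno	mirna	target	condition	fpkm
1.1	miR-172	DnaJ homolog subfamily A member 2	JH	83.43
1.2	miR-172	polyadenylate-binding protein	JH	133.95
1.3	miR-172	peroxin-5	JH	188.29
2.1	miR-414	ditrans,polycis-polyprenyl diphosphate synthase [EC:2.5.1.87]	JH	13.78
2.2	miR-414	DnaJ homolog subfamily C member 3	JH	53.58
2.3	miR-414	glycerol-3-phosphate acyltransferase [EC:2.3.1.15]	JH	55.11
2.4	miR-414	heat shock 70 kDa protein 1/8	JH	50.52
3.1	miR-529	1,4-alpha-glucan branching enzyme [EC:2.4.1.18]	JH	578.65
3.2	miR-529	phosphatidylinositol phospholipase C, delta [EC:3.1.4.11]	JH	188.29
4.1	miR-2910	4-coumarate-CoA ligase [EC:6.2.1.12]	JV	100.6
4.2	miR-2910	imidazoleglycerol-phosphate dehydratase [EC:4.2.1.19]	JV	103.21
5	miR-2914	Cu+ exporting ATPase [EC:3.6.3.54]	JV	69.24
6	miR-477	elongation factor 1 gamma	JV	101.91
7	miR-f11953	two-component response regulator ARR-B family	JV	160.7
8	miR-f12158	two-component response regulator ARR-B family	JV	160.7
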