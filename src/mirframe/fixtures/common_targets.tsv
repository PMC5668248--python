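sno	mirna	jh_target	jv_target	jh_fpkm	jv_fpkm	regulation
1.1	miR-156	choline monooxygenase [EC:1.14.15.7]	choline monooxygenase [EC:1.14.15.7]	2092.64	6282.87	up
1.2	miR-156		ferrochelatase [EC:4.99.1.1]		114.97	absent
1.3	miR-156		histone H3		292.65	absent
1.4	miR-156		ketol acid reductoisomerase [EC:1.1.1.86]		261.3	absent
2.1	miR-157	choline monooxygenase [EC:1.14.15.7]	choline monooxygenase [EC:1.14.15.7]	2092.64	6282.87	up
2.2	miR-157		ferrochelatase [EC:4.99.1.1]		114.97	absent
2.3	miR-157		ketol acid reductoisomerase [EC:1.1.1.86]		261.3	absent
3.1	miR-159	acetyl-CoA carboxylase, biotin carboxylase subunit [EC:6.4.1.2 6.3.4.14]	acetyl-CoA carboxylase, biotin carboxylase subunit [EC:6.4.1.2 6.3.4.14]	205.13	287.43	up
3.2	miR-159	ubiquitin-conjugating enzyme E2 W [EC:2.3.2.25]	ubiquitin-conjugating enzyme E2 W [EC:2.3.2.25]	253.35	296.57	up
4	miR-319	ubiquitin-conjugating enzyme E2 W [EC:2.3.2.25]	ubiquitin-conjugating enzyme E2 W [EC:2.3.2.25]	253.35	296.57	up
5.1	miR-4995	RecQ-mediated genome instability protein 2		25.26		absent
5.2	miR-4995	small subunit ribosomal protein S5	small subunit ribosomal protein S5	131.65	64.02	down
6.1	miR-5021	acetyl-CoA C-acetyltransferase [EC:2.3.1.9]	acetyl-CoA C-acetyltransferase [EC:2.3.1.9]	100.27	74.47	down
6.2	miR-5021	alanine-glyoxylate transaminase/(R)-3-amino-2-methylpropionate-pyruvate transaminase [EC:2.6.1.44 2.6.1.40]	alanine-glyoxylate transaminase/(R)-3-amino-2-methylpropionate-pyruvate transaminase [EC:2.6.1.44 2.6.1.40]	101.03	155.47	up
6.3	miR-5021	bud site selection protein 31	bud site selection protein 31	39.04	33.97	down
6.4	miR-5021	DNA polymerase epsilon subunit 2 [EC:2.7.7.7]	DNA polymerase epsilon subunit 2 [EC:2.7.7.7]	32.91	35.28	up
6.5	miR-5021	fanconi anemia group M protein	fanconi anemia group M protein	382.71	475.56	down
6.6	miR-5021	ferulate-5-hydroxylase	ferulate-5-hydroxylase	123.23	189.44	up
6.7	miR-5021	hydroxymethylglutaryl-CoA synthase [EC:2.3.3.10]	hydroxymethylglutaryl-CoA synthase [EC:2.3.3.10]	100.27	355.36	up
6.8	miR-5021	mRNA export factor	mRNA export factor	265.62	33.86	down
6.9	miR-5021	nucleolar protein 58	nucleolar protein 58	88.02	151.55	up
6.10	miR-5021	protein disulfide-isomerase A6 [EC:5.3.4.1]	protein disulfide-isomerase A6 [EC:5.3.4.1]	141.6	220.8	up
6.11	miR-5021	translation initiation factor 5B	translation initiation factor 5B	991.98	2164.84	up
6.12	miR-5021		(+)-abscisic acid 8'-hydroxylase [EC:1.14.13.93]		84.92	absent
6.13	miR-5021		1-deoxy-D-xylulose-5-phosphate synthase [EC:2.2.1.7]		154.16	absent
6.14	miR-5021		beta-fructofuranosidase [EC:3.2.1.26]		148.94	absent
6.15	miR-5021		crossover junction endonuclease EME1		220.8	absent
6.16	miR-5021		glutathione reductase (NADPH) [EC:1.8.1.7]		265.22	absent
6.17	miR-5021		large subunit ribosomal protein L17		33.97	absent
6.18	miR-5021		peroxidase [EC:1.11.1.7]		90.15	absent
6.19	miR-5021		phosphoenolpyruvate carboxylase [EC:4.1.1.31]		1085.69	absent
6.20	miR-5021		photosystem I subunit X		57.49	absent
6.21	miR-5021		Ras GTPase activating protein 4		151.55	absent
6.22	miR-5021		signal recognition particle subunit SRP14		52.26	absent
6.23	miR-5021		small ubiquitin related modifier		37.89	absent
6.24	miR-5021		STIP1 homology and U box containing protein 1 [EC:2.3.2.27]		53.57	absent
6.25	miR-5021		tRNA specific 2-thiouridylase		163.31	absent
6.26	miR-5021		ubiquinone biosynthesis monooxygenase Coq6		145.02	absent
7.1	miR-5658	1-phosphatidylinositol-3-phosphate 5-kinase [EC:2.7.1.150]	1-phosphatidylinositol-3-phosphate 5-kinase [EC:2.7.1.150]	269.43	283.51	up
7.2	miR-5658	bloom syndrome protein [EC:3.6.4.12]		114.05		absent
7.3	miR-5658	diacylglycerol kinase (ATP) [EC:2.7.1.107]	diacylglycerol kinase (ATP) [EC:2.7.1.107]	41.33	32.66	down
7.4	miR-5658	DNA (cytosine-5)-methyltransferase 1 [EC:2.1.1.37]	DNA (cytosine-5)-methyltransferase 1 [EC:2.1.1.37]	229.62	320.09	up
7.5	miR-5658	large subunit ribosomal protein L9		45.16		absent
7.6	miR-5658	serine/threonine-protein kinase CTR1 [EC:2.7.11.1]	serine/threonine-protein kinase CTR1 [EC:2.7.11.1]	166.09	271.75	up
7.7	miR-5658	small subunit ribosomal protein S6	small subunit ribosomal protein S6	143.13	142.41	down
7.8	miR-5658	transcription initiation factor TFIIF subunit alpha	transcription initiation factor TFIIF subunit alpha	244.17	282.2	up
7.9	miR-5658	transcription-repair coupling factor (superfamily II helicase)	transcription-repair coupling factor (superfamily II helicase)	433.22	257.38	down
7.10	miR-5658	translation initiation factor 5B	translation initiation factor 5B	991.98	2164.84	up
7.11	miR-5658	U4/U6.U5 tri-snRNP-associated protein 2	U4/U6.U5 tri-snRNP-associated protein 2	241.11	244.31	up
7.12	miR-5658		non-lysosomal glucosylceramidase [EC:3.2.1.45]		310.94	absent
7.13	miR-5658		peptidyl-prolyl cis-trans isomerase-like 2 [EC:5.2.1.8]		121.5	absent
7.14	miR-5658		RIO kinase 1 [EC:2.7.11.1]		299.18	absent
7.15	miR-5658		serine/threonine protein phosphatase PP1 catalytic subunit [EC:3.1.3.16]		84.92	absent
7.16	miR-5658		translation initiation factor eIF-2B subunit beta		180.29	absent
7.17	miR-5658		xanthine dehydrogenase/oxidase [EC:1.17.1.4 1.17.3.2]		326.62	absent
8.1	miR-f11908	lupus La protein	lupus La protein	120.17	94.07	down
8.2	miR-f11908	splicing factor, arginine/serine-rich 4/5/6	splicing factor, arginine/serine-rich 4/5/6	96.44	91.45	up
8.3	miR-f11908		hydroxymethylpyrimidine kinase/phosphomethylpyrimidine kinase/thiamine-phosphate diphosphorylase [EC:2.7.1.49 2.7.4.7 2.5.1.3]		134.57	absent
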