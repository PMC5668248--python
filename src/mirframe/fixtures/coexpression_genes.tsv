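gene	mirnas	co_expressed_genes	pathways
CMO	miR-156;miR-157	RCC1;DUF1624;NF-YC12;MIR5344;3767731;hydrolase;kinase;tudor-like;CAMP;CHT-type C;SCAMP;MIR-834a;MBD7;TRAF-Like;NHX5;BET10;TAF6B4;DUF2358;PLDGAMMA2;TIR-NBS-LR;MRS2-7;Phosphoester	Biosynthesis of Secondary Metabolites;Carbon Metabolism
RPS5	miR-4995	TIR-NBS-LR;ENTH;NLP7;ARM repeat;CC-NBS-LRR;PP2-A7;PP2-A6;KINASE;RFL1;F-box;Calmodulin;RPP4;RPP5;SNC1;LRR;RLM3	Disease Resistance Response
RPL9	miR-5658	Emb1473;RPL15;PSRP5;EMB3105;S10p/S20e;PRPL11;L19;RPS17;L28;ribosome;EMB3113;Heavy metal ion;L5P;TWN3;GHS1;ROC4;S20;emb2394;NDPK2;RPL21C	Ribosomal Machinery
EIF5	miR-5658;miR-5021	Hydrolase;inhibitor;CYN;CUTA;NAT;819216;UBC30;GB2;G18a;GRXC2;OB-Fold Ligand;TRXH3;UBQ7;ADF6;UBC3;CHMP1A;W1H1;G8B;UBC11	Protein Processing in Endoplasmic Reticulum;Ubiquitin Mediated Proteolysis
MVA1	miR-5021	ACP1;MOD1;PLE2;KASI;Thioesterase;BIOB;840894;CAC2;FPS1;MVD1;EMB1276;URH2;hydrolase;mutase;FaTA;NagB;UPF0041;ZHD13;CAC1-B	Biosynthesis of Secondary Metabolites;Fatty Acid Biosynthesis;Fatty Acid Metabolism;Carbon Metabolism
PPC	miR-5021	SOS1;MMT;alpha/beta subunit;kinase;PFK7;iPGAM2;PGM3;MDAR1;PGM2;Galactose;UGP1;mMDH2;HXK1;RR10;GLU2;JAR1;PGDH;ACO3;EMB1467;Kinase	Biosynthesis of Secondary Metabolites;Carbon Metabolism;Glycolysis/Gluconeogenesis;Galactose Metabolism
PSAX	miR-5021	PDAD-2;PSII;Photosynthesis;NdhS;LHCA1;PSAH-1;PSAL;LHCA3;PSAG;YCF32;PSAF;PSBW;LHCB5;PSBX;PSAN;PSAE-1;838749;PSAD-1;PSII-Q	Photosynthesis;Photosynthesis-Antenna Proteins
SUMO	miR-5021	HMGA;HTB1;HTB2;819315;TYRDC1;alpha/beta ligand;PEL3;CYP7731;LTP6;PIP2D;hydrolase;kinase;inhibitor;DRG;PME5;PDCB2;Putative mutase	Ribosomal Machinery;Spliceosome
CYP707A1	miR-5021	AFP1;AFP3;SAG113;AB12;RAB18-PUB19;PP2-B11;SPSA2;BETAVPE;LEA7;LEA;LEA4-5;TSPO;transporter;RD29B;phosphotriase;XERO2;FMO-GS-OX-4;ESL1	Plant Hormone Signal Transduction
DXS	miR-5021	GUN5;OSA1;JAC1;821278;CH1;SIGB;PSY;CP5;815980;DUF2358;COLA4;PSII;PSAD2;LHCB6;CRD1;oxidoreductase;HEMA1;818819;SLP1;rosamann	Biosynthesis of Secondary Metabolites;Photosynthesis-Antenna Proteins;Porphyrin and Chlorophyll Metabolism;Proteasome;mRNA Surveillance Pathway
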