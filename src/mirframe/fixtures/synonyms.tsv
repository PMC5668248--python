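symbol	target_name
CMO	choline monooxygenase [EC:1.14.15.7]
RPS5	small subunit ribosomal protein S5
RPL9	large subunit ribosomal protein L9
EIF5	translation initiation factor 5B
MVA1	hydroxymethylglutaryl-CoA synthase [EC:2.3.3.10]
PPC	phosphoenolpyruvate carboxylase [EC:4.1.1.31]
PSAX	photosystem I subunit X
SUMO	small ubiquitin related modifier
CYP707A1	(+)-abscisic acid 8'-hydroxylase [EC:1.14.13.93]
DXS	1-deoxy-D-xylulose-5-phosphate synthase [EC:2.2.1.7]
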