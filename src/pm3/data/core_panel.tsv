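symbol	enzyme_name	domain	pathway	cofactors	compartment	functional_role
SUCLA2	Succinate-CoA ligase (ADP-forming beta)	mitochondrial	TCA Cycle	ATP;pantothenate_CoA	mitochondrial	Succinyl-CoA to Succinate
GOT1	Aspartate transaminase 1 (AST1)	other	Transamination	PLP_B6	cytosolic	Glutamate/Oxaloacetate Shuttle
SLC25A11	2-Oxoglutarate/malate carrier (OGC)	mitochondrial	Mitochondrial Transport		mitochondrial	Malate Shuttle (Mito)
CKMT1A	Mitochondrial creatine kinase 1A	mitochondrial	Energy Buffering	Mg2plus;ATP	mitochondrial	Phosphocreatine Shuttle
GPT2	Alanine transaminase 2 (ALT2)	mitochondrial	Transamination	PLP_B6	mitochondrial	Alanine-Pyruvate Interconversion
GOT2	Aspartate transaminase 2 (AST2)	mitochondrial	Transamination	PLP_B6	mitochondrial	Mitochondrial Transamination
GLS	Glutaminase	mitochondrial	Glutamate Metabolism		mitochondrial	Glutamine to Glutamate
IDH3A	Isocitrate dehydrogenase 3 alpha (NAD-linked)	mitochondrial	TCA Cycle	NAD	mitochondrial	Isocitrate to alpha-Ketoglutarate
MDH2	Malate dehydrogenase 2 (mitochondrial)	mitochondrial	TCA Cycle	NAD	mitochondrial	Malate to Oxaloacetate (mito)
IDH3B	Isocitrate dehydrogenase 3 beta (NAD-linked)	mitochondrial	TCA Cycle	NAD	mitochondrial	Isocitrate to alpha-Ketoglutarate
SHMT1	Serine hydroxymethyltransferase 1	redox_sulfur_one_carbon	One Carbon Metabolism	PLP_B6	cytosolic	Serine to Glycine
MDH1	Malate dehydrogenase 1 (cytosolic)	redox_sulfur_one_carbon	NAD Cycling/Redox	NAD	cytosolic	Malate to Oxaloacetate
OGDH	Oxoglutarate dehydrogenase	mitochondrial	Energy/TCA Cycle	thiamine_TPP;NAD;pantothenate_CoA;lipoic_acid	mitochondrial	alpha-Ketoglutarate to Succinyl-CoA
PDHA1	Pyruvate dehydrogenase E1 alpha subunit	mitochondrial	Energy/PDH Complex	thiamine_TPP;NAD;pantothenate_CoA;lipoic_acid	mitochondrial	Pyruvate to Acetyl-CoA
MAT2B	Methionine adenosyltransferase II beta	redox_sulfur_one_carbon	Methylation		cytosolic	Methionine to SAM (Regulation)
SFXN1	Sideroflexin 1 (serine transporter)	mitochondrial	Mitochondrial Transport		mitochondrial	Mitochondrial Serine Transport
MTHFD1	Methylene-THF dehydrogenase 1	redox_sulfur_one_carbon	Folate/One-Carbon Metabolism	NAD	cytosolic	Folate Interconversion
DLD	Dihydrolipoamide dehydrogenase	mitochondrial	Energy/Redox	FAD;NAD	mitochondrial	E3 Subunit of PDH/OGDH Complexes
SUOX	Sulfite oxidase	redox_sulfur_one_carbon	Sulfur Metabolism	molybdenum;heme	mitochondrial	Sulfite Oxidation
TST	Thiosulfate sulfurtransferase (rhodanese)	redox_sulfur_one_carbon	Detoxification		mitochondrial	Thiosulfate Sulfurtransferase (Detoxification)
SUCLG2	Succinate-CoA ligase (GDP-forming beta)	mitochondrial	TCA Cycle	GDP;pantothenate_CoA	mitochondrial	Succinyl-CoA to Succinate
SLC5A6	Sodium-dependent multivitamin transporter (SMVT)	other	Cofactor Transport	biotin;pantothenate_CoA;lipoic_acid	cytosolic	Biotin/Pantothenate/Lipoate Uptake
SLC19A2	Thiamine transporter 1 (THTR1)	other	Cofactor Transport	thiamine_TPP	cytosolic	Thiamine Uptake
SLC19A3	Thiamine transporter 2 (THTR2)	other	Cofactor Transport	thiamine_TPP	cytosolic	Thiamine Uptake (Compensatory)
PANK1	Pantothenate kinase 1	other	CoA Biosynthesis	pantothenate_CoA;ATP	cytosolic	Pantothenate Phosphorylation
PANK2	Pantothenate kinase 2	other	CoA Biosynthesis	pantothenate_CoA;ATP	mitochondrial	Pantothenate Phosphorylation (Mitochondrial)
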