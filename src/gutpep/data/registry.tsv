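accession	name	origin	secretion_sites	chain_length	scenarios
Q02817	Mucin-2	endogenous	small_intestine;colon	5159
Q02505	Mucin-3A	endogenous	small_intestine	2520
Q9H195	Mucin-3B	endogenous	small_intestine;colon	901
P98088	Mucin-5AC	endogenous	stomach;duodenum	5003	gastric;gastric_plus_small_intestinal
Q6W4X9	Mucin-6	endogenous	stomach	2417
Q8TAX7	Mucin-7	endogenous	mouth	355
Q9H3R2	Mucin-13	endogenous	stomach;small_intestine;colon	493
Q8N387	Mucin-15	endogenous	small_intestine;colon	311
Q8N307	Mucin-20	endogenous	stomach;small_intestine;colon	684
P02768	Serum albumin	endogenous	stomach;small_intestine	591
P17538	Chymotrypsinogen B	endogenous	pancreas	245
Q6GPI1	Chymotrypsinogen B2	endogenous	pancreas	245
P07098	Gastric triacylglycerol lipase	endogenous	stomach	379
P04746	Pancreatic alpha-amylase	endogenous	pancreas	496
P16233	Pancreatic triacylglycerol lipase	endogenous	pancreas	449
P00790	Pepsin A	endogenous	stomach	373
P04745	Salivary alpha-amylase	endogenous	mouth	496
P07477	Trypsin	endogenous	pancreas	232
P06307	Cholecystokinin	endogenous	small_intestine	95
P01350	Gastrin	endogenous	stomach;duodenum;pancreas	80
P12872	Promotilin	endogenous	small_intestine	90	gastric;gastric_plus_small_intestinal;small_intestinal_only
P09683	Secretin	endogenous	duodenum	103	gastric;gastric_plus_small_intestinal;small_intestinal_only
P61278	Somatostatin	endogenous	stomach;small_intestine;pancreas	92
P09681	Gastric inhibitory peptide	endogenous	stomach	132
P27352	Gastric intrinsic factor	endogenous	stomach	399
P61626	Lysozyme C	endogenous	stomach;small_intestine;colon	130
P02666	Beta-casein (bovine milk)	dietary		209
P02863	Gliadin (wheat)	dietary		266
P10385	Glutenin (wheat)	dietary		337
P04347	Glycinin (soya)	dietary		492
P01012	Ovalbumin (chicken egg)	dietary		386
P60706	Actin (chicken meat)	dietary		375
P13538	Myosin (chicken meat)	dietary		1939
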