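# Chromosomal genes present in at least four beer-spoiler strains
# (published study, beer-adaptation gene list), transcribed as printed;
# the 26 additional hypothetical proteins are not itemized in the source.
# Product strings are verbatim, including source typography.
family_id	category	product	TMW1.2108	TMW1.2111	TMW1.2112	TMW1.2113	UCCLB95	UCCLBBS124	UCCLBBS449
T5_01	Energy production and conversion	Flavodoxin	1	1	1	1	1	1	1
T5_02	Energy production and conversion	NADH-Flavin reductase	1	1	0	0	1	1	1
T5_03	Energy production and conversion	Oxidoreductase	1	1	1	1	1	1	1
T5_04	Energy production and conversion	NADPH:quinone reductase	1	1	0	0	1	1	1
T5_05	Energy production and conversion	FMN-dependent NADH-azoreductase	1	1	0	0	1	1	1
T5_06	Energy production and conversion	Nitrobenzoate reductase	1	1	0	0	1	1	1
T5_07	Amino acid transport and metabolism	Shikimate dehydrogenase	1	1	1	1	1	1	1
T5_08	Amino acid transport and metabolism	Acetyltransferase GNAT family	1	1	0	0	1	1	1
T5_09	Amino acid transport and metabolism	Serine O-acetyltransferase EC	1	1	0	0	1	1	1
T5_10	Carbohydrate transport and metabolism	MFS transporter	1	1	0	0	1	1	1
T5_11	Carbohydrate transport and metabolism	Alpha-glucosidase	1	1	1	1	1	1	1
T5_12	Carbohydrate transport and metabolism	lycoside hydrolase	1	1	0	0	0	1	1
T5_13	Carbohydrate transport and metabolism	Hydrolase	1	1	1	1	1	1	1
T5_14	Carbohydrate transport and metabolism	Transketolase	1	1	1	1	0	0	0
T5_15	Carbohydrate transport and metabolism	MFS transporter	1	1	1	0	1	1	0
T5_16	Carbohydrate transport and metabolism	PTS system2C IIA component 1	1	1	0	0	1	1	1
T5_17	Carbohydrate transport and metabolism	Putative integral membrane protein 1	1	1	0	0	1	1	1
T5_18	Carbohydrate transport and metabolism	PTS2C EIIB 1	1	1	0	0	1	1	1
T5_19	Carbohydrate transport and metabolism	PTS mannitol transporter subunit IIA	1	1	0	0	1	1	1
T5_20	Carbohydrate transport and metabolism	Putative oligogalacturonide transporter	1	1	1	1	1	0	1
T5_21	Coenzyme transport and metabolism	6-pyruvoyl tetrahydropterin synthase	1	1	1	1	0	1	0
T5_22	Lipid transport and metabolism	NADH peroxidase	1	1	1	1	1	1	1
T5_23	Lipid transport and metabolism	Peroxidase	1	1	0	0	1	1	1
T5_24	Lipid transport and metabolism	Citrate lyase	1	1	0	0	1	1	1
T5_25	Transcription	Transcriptional regulator2C TetR family	1	1	0	0	1	1	1
T5_26	Transcription	Transcriptional regulator	1	1	1	1	1	1	1
T5_27	Transcription	Transcriptional regulator TetR family	1	1	0	0	1	1	1
T5_28	Transcription	Transcriptional regulator	1	1	1	1	1	1	1
T5_29	Transcription	Internalin-J	0	1	1	1	1	1	1
T5_30	Transcription	RNA polymerase sigma-24 subunit ECF subfamily	1	1	1	1	1	1	1
T5_31	Transcription	ECF-type sigma factor negative effector	1	1	1	1	1	1	1
T5_32	Transcription	Transcriptional regulator	1	1	1	1	1	1	1
T5_33	Transcription	Transcriptional regulator MarR family	1	1	0	0	1	1	1
T5_34	Transcription	Transcriptional regulator	1	1	0	0	1	1	1
T5_35	Transcription	Transcriptional regulator MarR family	1	1	0	0	1	1	1
T5_36	Transcription	Transcriptional regulator TetR	1	1	0	0	0	1	1
T5_37	Transcription	Transcriptional regulator ArsR family	1	1	0	0	1	1	1
T5_38	Cell wall/membrane/envelope biogenesis	Membrane protein	1	1	0	1	0	1	0
T5_39	Cell wall/membrane/envelope biogenesis	Cell surface protein	1	1	1	1	0	0	0
T5_40	Cell wall/membrane/envelope biogenesis	Cell surface protein	1	1	0	0	0	1	1
T5_41	Cell wall/membrane/envelope biogenesis	Endo polygalacturonase	1	1	1	1	0	0	1
T5_42	Cell wall/membrane/envelope biogenesis	Glutamyl endopeptidase precursor	1	1	1	1	1	1	1
T5_43	Cell wall/membrane/envelope biogenesis	NLP-P60 protein	1	1	1	1	1	1	1
T5_44	Cell wall/membrane/envelope biogenesis	Short-chain dehydrogenase-oxidoreductase	1	1	0	0	1	1	1
T5_45	Inorganic ion transport and metabolism	Permease	1	1	1	1	1	1	1
T5_46	Inorganic ion transport and metabolism	Permease	1	1	1	1	1	0	1
T5_47	Inorganic ion transport and metabolism	Na + -H+ antiporter	1	1	0	0	1	1	0
T5_48	General function prediction only	NADPH-quinone reductase	1	1	1	1	1	1	1
T5_49	General function prediction only	Short-chain dehydrogenase-oxidoreductase	1	1	1	1	1	1	1
T5_50	General function prediction only	Short-chain dehydrogenase	1	1	1	1	1	1	0
T5_51	General function prediction only	Cell surface adherence protein	0	0	1	1	1	1	1
T5_52	General function prediction only	Mucus-binding protein LPXTG-motif cell wall anchor	1	1	1	1	1	0	1
T5_53	Function unknown	Cell surface hydrolase	1	1	1	1	1	1	1
T5_54	Function unknown	Membrane protein	1	1	1	1	0	1	1
T5_55	Function unknown	Cell surface protein	1	1	0	0	1	1	1
T5_56	Defence mechanisms	ABC transporter ATP-binding protein	1	1	1	1	1	1	1
T5_57	Defence mechanisms	ABC transporter permease	1	1	1	1	1	1	1
T5_58	Defence mechanisms	Prophage protein	1	1	1	1	0	0	1
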