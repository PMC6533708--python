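# Genes specifically only present in plasmid sequences of at least three
# beer-spoiler strains (published study, plasmid gene list), transcribed
# as printed. NOTE: the Transposase row (T6_23) is printed with only six
# presence symbols for seven strains in the typeset source; the missing
# final (UCCLBBS449) column is transcribed as absent and flagged for
# manual verification.
family_id	category	product	TMW1.2108	TMW1.2111	TMW1.2112	TMW1.2113	UCCLB95	UCCLBBS124	UCCLBBS449
T6_01	Defence mechanisms	Membrane protein HorC	1	1	1	0	1	1	1
T6_02	Cell wall biogenesis	Lipopolysaccharide biosynthesis glycosyltransferase	1	1	1	1	0	1	1
T6_03	Cell wall biogenesis	Lipopolysaccharide biosynthesis glycosyltransferase	1	1	1	1	0	1	1
T6_04	Lipid transport and metabolism	Phospholipid-glycerol acyltransferase	1	1	1	1	0	1	1
T6_05	Lipid transport and metabolism	1-acyl-sn-glycerol-3-phosphate acyltransferase	1	1	1	1	0	1	1
T6_06	Lipid transport and metabolism	Fatty acid-binding protein DegV	0	0	1	1	0	1	1
T6_07	Carbohydrate transport and metabolism	Glycosyl transferase family 2	1	1	1	0	0	1	0
T6_08	Carbohydrate transport and metabolism	Enolase	1	1	0	0	0	0	1
T6_09	Carbohydrate transport and metabolism	MFS transporter	1	1	1	1	0	0	0
T6_10	Transcription	Sigma-70 region 4 family protein	1	1	0	0	0	0	1
T6_11	Transcription	Transcriptional regulator TetR family	1	1	1	0	0	1	1
T6_12	Nucleotide transport and metabolism	Cytosine deaminase	1	1	0	1	0	1	1
T6_13	Inorganic ion transport and metabolism	CrcB-like protein	1	1	0	0	0	0	1
T6_14	Replication, recombination and repair	Cytosine-specific methyltransferase	1	1	0	0	0	1	0
T6_15	Replication, recombination and repair	Initiator RepB protein	1	1	0	0	0	0	1
T6_16	Function unknown	Hypothetical protein	1	1	0	0	0	0	1
T6_17	Function unknown	Hypothetical protein	1	1	1	1	0	0	1
T6_18	Function unknown	Hypothetical protein	1	1	1	1	0	0	0
T6_19	Function unknown	Hypothetical protein	1	1	0	0	0	0	1
T6_20	Function unknown	Hypothetical protein	1	1	0	0	0	1	0
T6_21	Function unknown	Hypothetical protein	1	0	1	0	0	1	0
T6_22	Function unknown	PemK family protein	1	1	0	0	0	1	0
T6_23	Mobilome	Transposase	1	1	0	0	0	1	0
T6_24	Mobilome	Mobilization protein	1	1	0	0	0	0	1
T6_25	Mobilome	Mobilization protein	1	1	0	0	0	0	1
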