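# Published EMBOSS-water percent identity/similarity of dog and human CEACAM
# proteins against the dog CEACAM24 protein (query NP_001091023).
species	gene	accession	pct_identity	pct_similarity
Dog	CEACAM1	NP_00101026	52.2	58.4
Dog	CEACAM16	ENSCAFP00000039084	22.5	37.7
Dog	CEACAM18	ENSCAFP00000058450	19.3	32.5
Dog	CEACAM20	ENSCAFP00000036293	21.2	31.9
Dog	CEACAM23	NP_001091021	38.4	40.8
Dog	CEACAM24	NP_001091023	100	100
Dog	CEACAM28	NP_001091015	42.2	46.3
Dog	CEACAM30	NP_001091022	53.6	58.3
Human	CEACAM1	NP_001171744	53.1	60.8
Human	CEACAM3	NP_001806	47	58.2
Human	CEACAM4	NP_001808	50.4	63.4
Human	CEACAM5	NP_004354	53.2	61
Human	CEACAM6	NP_002474	37.8	48
Human	CEACAM7	NP_008821	45.1	58.3
Human	CEACAM8	NP_001807	53.8	63.6
Human	CEACAM16	NP_001034302	28	43.5
Human	CEACAM18	NP_001265321	26.9	46.2
Human	CEACAM19	NP_064604	23.7	38.1
Human	CEACAM20	NP_001096067	25.7	39.9
Human	CEACAM21	NP_001091976	34.1	42.3
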