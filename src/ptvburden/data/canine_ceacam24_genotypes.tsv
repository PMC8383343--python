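# Genotype counts of the CEACAM24 c.247dupG frameshift allele across canine cohorts.
# Columns: cohort (analysis unit), label (breed), n dogs, hom-alt, het, and the
# cohort's reported MAF (%) where one was published alongside the counts.
cohort	label	n	hom_alt	het	reported_maf
cmt_cases	Golden Retriever	18	6	9	66.7
golden_controls	Golden Retriever	87	42	34	67.8
akc_nongolden_controls	Petit Basset Griffon Vendeen	10	7	2	
akc_nongolden_controls	Gordon Setter	8	5	2	
akc_nongolden_controls	Australian Cattle Dog	10	4	2	
akc_nongolden_controls	Siberian Husky	10	4	1	
akc_nongolden_controls	Dalmatian	10	3	2	
akc_nongolden_controls	Irish Setter	9	0	1	
akc_nongolden_controls	Welsh Pembroke Corgi	10	0	0	
akc_nongolden_controls	Standard Schnauzer	10	0	0	
akc_nongolden_controls	Newfoundland	10	0	0	
akc_nongolden_controls	Keeshond	10	0	0	
akc_nongolden_controls	Great Dane	8	0	0	
akc_nongolden_controls	Doberman Pinscher	10	0	0	
akc_nongolden_controls	Boxer	10	0	0	
eva_controls	European General Dog Population	196	12	44	17.3
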