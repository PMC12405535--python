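strain	total_tcs	grouped	sapi_compatible	bsai_compatible_not_sapi	amplified	library1	library2
Bacteroides caccae	9	5	5	0	4	1	1
Bacteroides dorei	14	7	3	4	2	0	2
Bacteroides fragilis	13	8	6	0	5	2	0
Bacteroides thetaiotaomicron	12	8	3	3	1	1	0
Blautia producta	90	26	19	6	14	5	5
Citrobacter rodentium	22	14	11	2	13	11	2
Clostridium difficile	43	8	8	1	3	0	1
Edwardsiella tarda	20	11	8	1	5	5	0
Enterococcus faecalis	13	4	3	0	3	2	0
Klebsiella oxytoca	25	12	8	5	2	1	0
Klebsiella pneumoniae	25	12	10	0	8	7	0
Lactobacillus gasseri	6	1	1	0	1	1	0
Lactobacillus plantarum	13	2	2	1	2	1	0
Ruminococcus gnavus	36	13	8	4	6	2	3
Salmonella Typhimurium	22	11	6	2	5	3	0
Vibrio cholerae	24	13	8	3	5	3	2
Yersinia enterocolitica	20	8	7	1	5	4	0
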