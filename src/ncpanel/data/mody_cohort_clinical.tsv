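case_id	age_years	sex	onset_age_years	family_history_dm_n	bmi_kg_m2	hba1c_pct	fasting_glucose_mg_dl	c_peptide_ng_ml	secondary_complications	insulin	metformin	dpp4i	sglt2i	glp1ra
M1	61	M	48	7	31.8	7.2	110	1.1	No	Yes	No	No	Yes	No
M2	85	M	49	4	19.6	7	126	0.8	Yes	No	Yes	No	No	No
M3	47	M	27	5	25.1	6.9	128	0.5	Yes	Yes	Yes	No	Yes	No
M4	78	F	65	9	24.3	7.6	90	0.3	No	Yes	No	No	No	No
M5	34	M	25	2	20.8	7.5	122	1.8	No	No	No	Yes	No	No
M6	35	M	23	5	30.6	8.2	113	1.6	No	Yes	No	No	No	No
M7	53	M	18	2	25.6	8.2	142	1.3	Yes	Yes	Yes	Yes	No	No
M8	46	M	26	1	19.8	6	125	0.3	No	Yes	No	No	No	No
M9	35	M	14		27.5	8	191	0.7	No	Yes	No	No	No	No
M10	32	F	20	2	40.2	9.8	138	0.4	No	Yes	Yes	No	Yes	No
M11	55	M	27	6	27	6.9	145		No	No	Yes	No	No	No
M12	48	F	25	2	30.4	5.9	102	3	No	Yes	No	No	No	No
M13	48	M	46	3	24.8	6.8	159	0.8	No	No	Yes	No	No	No
M14	24	M	17	4	23.6	7.6	127	1.4	No	No	Yes	No	No	No
M15	42	F	11	3	38.7	6.2	90	0.57	Yes	No	No	No	No	Yes
M16	57	M	35	2	25.5	7.9	167	1.2	No	Yes	No	No	No	No
M17	38	F	35		29.1	7.3	124	0.5	No	Yes	No	No	No	No
M18	41	F	25		27.2	8.4	143		No	No	No	No	Yes	No
M19	38	M	35	2	22	6.4	124	1.4	No	No	No	No	No	No
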