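patient	gene	z
M15	APPL1	-2.48
M15	HADH	-3.27
M23	HADH	-2.03
M1	PLAGL1	-2.46
M4	PLAGL1	-2.32
M6	PLAGL1	-3.59
M14	PLAGL1	-3.73
M8	PLAGL1	4.54
M15	PLAGL1	3.63
M18	PLAGL1	2.12
M3	PLAGL1	2.24
M10	GLIS3	4.38
M6	GLIS3	3.36
M9	GLIS3	2.89
M13	UCP2	5.22
M14	UCP2	4.7
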