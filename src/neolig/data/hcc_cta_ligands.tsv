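patient	tissue	peptide	q	accessions	hla
HCC045	tumor	EQIEDLAKY	0.01	Q5W041	A*26:01
HCC023	tumor	AYAIIKEEL	0.01	Q6PL18	A*24:02
HCC045	tumor	AEFRTNKTL	0.01	Q6PL18	B*44:03
HCC045	tumor	MVVLDAGRY	0.01	Q96JY0	A*26:01
HCC041	tumor	SLLQHLIGL	0.01	P78395	B*08:01
HCC035	tumor	AFDDIATYF	0.01	Q16384	C*04:01
HCC041	tumor	RLRERKQLV	0.01	Q16384;Q16385;Q99909;O60224;Q7RTT6;Q7RTT5;Q7RTT3	B*08:01
HCC045	tumor	EVVGELVAKF	0.01	Q5H9I0	A*26:01
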