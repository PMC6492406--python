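accession	antigen	family
Q5W041	ARMC3
Q6PL18	ATAD2
Q96JY0	MAEL
P78395	PRAME
Q16384	SSX1	SSX family
Q16385	SSX2	SSX family
Q99909	SSX3	SSX family
O60224	SSX4	SSX family
Q7RTT6	SSX6	SSX family
Q7RTT5	SSX7	SSX family
Q7RTT3	SSX9	SSX family
Q5H9I0	TFDP3
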