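# Novel miRNA candidate table: mature sequence, length, per-library TPM
# (superior S / inferior I at 10,15,21,27,35 DAF) and the published
# evidence code (H = >50 TPM in some library, F = detected in at least
# half of the libraries, * = miRNA* strand observed in some library).
candidate_id	sequence	length	S10	S15	S21	S27	S35	I10	I15	I21	I27	I35	evidence
miRn1	TCTTCGATAAGAATGCTGGCA	21	0	0	0	0	0	1.03	0	181.5	0	0	H
miRn2	TGATGTGTAGCACAATGCGGCTT	23	0	0	0	0	0	254.34	176.41	93.89	0	0	H
miRn3	TTGAGACGTAGAGGATAAGGT	21	0	0	0	1.29	1.31	0	1.79	1.58	0	2.31	F
miRn4	TTGGCAACGGACGCGATGGT	20	1.97	0.9	0	0	0	3.27	2.47	2.16	2.2	0.58	F
miRn5	TTTTGCTCAAGACCGCGCAAC	21	0.91	0.45	0	0	0	2.84	1.45	1.78	0.34	0	F
miRn6	TAAAGGAAGAAGAGAGAGAGT	21	0.7	0.6	0	0	0	3.27	0.6	1.14	0.56	0.72	F
miRn7	TGGATACTGGTAGAGGCGCCGCT	23	0	0	0	0	0	0	0	0	0	1.3	*
miRn8	TCCGACGCGAACTGGATGAGGCC	23	0	0	0	0	0	0.6	0	0	0	0	*
miRn9	TTCTGCTTGTGTATCGTCGCC	21	0	0	0	0	0	1.55	0	0.63	0	0	*
miRn10	AAGTGTGTAATGTTGAACGGA	21	0	0	0	0	0	1.03	0	0	0	0	*
miRn11	TGGTGAGCCACTGGGATGAGGATG	24	0	0	0	0	0	0	0	1.01	0	0	*
miRn12	TTTGAGATCTGGTGAGAATGTA	22	0	0	0	0	0	0	0	0.89	0	0	*
miRn13	AAGGGGCGCTTACTGAGAGTTCT	23	0	0.38	0	0	0	0.43	0	0	0.28	0.36	*
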