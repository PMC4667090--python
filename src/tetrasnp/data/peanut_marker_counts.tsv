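marker	variant_class	count1	count2	pic_published
EST-11SNP	C/G	4	92	0.080
EST-12SNP	C/T	1	95	0.021
EST-21SNP	G/T	15	81	0.264
EST-26SNP	A/C	8	88	0.153
EST-33SNP	G/T	92	4	0.080
EST-45SNP	G/T	88	8	0.153
EST-48SNP	G/T	83	13	0.234
EST-66SNP	A/G	28	68	0.413
EST-70SNP	C/T	79	17	0.291
EST-80SNP	A/G	5	91	0.099
EST-87SNP	A/G	13	83	0.234
EST-92SNP	A/T	2	94	0.041
GSS-2SNP	A/G	14	82	0.249
GSS-10SNP	A/C	21	75	0.234
GSS-26SNP	C/A	85	11	0.203
GSS-35SNP	A/T	24	72	0.375
GSS-44SNP	A/C	16	80	0.278
GSS-45SNP	A/G	87	9	0.170
GSS-46SNP	C/T	4	92	0.080
GSS-49SNP	A/C	18	78	0.305
GSS-52SNP	C/T	89	7	0.135
GSS-54SNP	C/T	82	14	0.249
GSS-56-1SNP	A/G	6	90	0.117
GSS-56-2SNP	C/T	15	81	0.264
GSS-67-1SNP	C/T	87	9	0.170
GSS-67-2SNP	C/T	83	13	0.234
GSS-69SNP	A/C	26	70	0.395
GSS-72SNP	A/T	71	15	0.429
GSS-74SNP	C/T	89	7	0.135
GSS-76SNP	A/G	33	61	0.478
GSS-80SNP	A/G	17	79	0.291
GSS-81SNP	C/T	83	13	0.234
GSS-99SNP	C/T	90	6	0.117
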