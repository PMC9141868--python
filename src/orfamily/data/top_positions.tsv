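dataset	times_predictive	alignment_position	dmel_orco_position	abakeri_orco_position	residue_dmel	residue_abakeri
1	8	1472	207	203	L	V
1	7	508	67	63	N	E
1	7	430	48	44	V	V
1	7	2529	414	402	R	R
1	7	2493	406	394	F	F
1	7	1069	143	139	T	T
1	7	2581	420	408	S	S
1	7	2855	486	474	K	K
1	7	620	83	79	F	F
1	7	1398	197	193	I	F
2	14	1210	170	166	S	E
2	11	1208	168	164	T	T
2	10	2345	387	375	V	V
2	10	430	48	44	V	V
2	9	1024	-	-	-	-
2	9	550	70	66	E	D
2	9	2591	421	409	S	S
2	9	2391	392	380	F	A
2	9	1594	229	225	E	E
2	9	334	30	25	F	F
3	2	216	16	11	D	D
3	2	1380	-	-	-	-
3	2	865	110	106	Q	N
3	2	1607	232	228	Q	Q
3	2	2771	-	-	-	-
3	2	2600	424	412	E	E
3	2	601	77	73	N	N
3	2	993	-	-	-	-
3	2	1474	208	204	F	I
3	2	2827	479	467	F	F
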