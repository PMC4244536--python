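peptide	sequence	pKa_dhx	kmax_dhx	pKa_hdx	kmax_hdx
1RH0	AARHAF	7.01	250	7.23	234
2DH0	AADHAF	7.58	284	7.72	331
3RH1	ARAHAF	7.37	263	6.71	230
4DH1	ADAHAF	7.20	279	7.63	331
5RH2	RAAHAF	7.67	291	7.23	258
6DH2	DAAHAF	7.59	255	7.49	330
70H0	AAAHAF	7.61	323	7.56	270
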