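peptide	k_pH7.9	k_pH8.2	k_pH8.7	k_pH9.0
1RH0	4.2	3.7	2.8	2.5
2DH0	3.4	4.4	4.3	4.6
3RH1	3.3	3.9	3.3	2.4
4DH1	3.8	3.2	3.6	4.6
5RH2	5.4	5.3	2.4	3.1
6DH2	3.2	3.2	4.2	3.7
70H0	3.7	3.2	3.2	3.2
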