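id_a	id_b	ks	ka
CmaGSTU3	CmaGSTU4	0.215	0.127
CmaGSTU4	CmaGSTU5	0.139	0.056
CmaGSTU12	CmaGSTU14	0.038	0.017
CmaGSTU12	CmaGSTU13	0.412	0.142
CmaGSTU12	CmaGSTU15	0.455	0.137
CmaGSTU12	CmaGSTU16	0.533	0.229
CmaGSTU13	CmaGSTU14	0.387	0.142
CmaGSTU13	CmaGSTU15	0.405	0.172
CmaGSTU13	CmaGSTU16	0.309	0.242
CmaGSTU14	CmaGSTU15	0.398	0.151
CmaGSTU15	CmaGSTU16	0.308	0.226
CmaGSTZ1	CmaGSTZ2	0.382	0.220
CmaEF1G1	CmaEF1G2	0.080	0.119
CmaEF1G1	CmaEF1G3	0.536	0.293
CmaEF1G2	CmaEF1G3	0.566	0.279
CmaGSTT1	CmaGSTT2	0.201	0.130
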