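dataset	gene	genorm_eff	genorm_noeff	genorm_reffinder	normfinder_eff	normfinder_noeff	normfinder_reffinder	bestkeeper_r	bestkeeper_sd
fs1	ACTB	13	13	13	13	12	12	14	1
fs1	B2M	9	1/2	1/2	9	9	9	4	12
fs1	GAPDH	11	11	11	11	11	11	10	13
fs1	HMBS	1/2	7	7	1	1	1	5	3
fs1	HPRT1	7	3	3	7	3	3	1	9
fs1	IGF1R	8	5	5	8	8	8	6	8
fs1	RLP13	14	14	14	14	14	14	12	14
fs1	RPS18	12	12	12	12	13	13	13	4
fs1	SDHA	1/2	9	9	4	4	4	8	2
fs1	SOX9	10	10	10	10	10	10	11	10
fs1	TBP	4	4	4	2	2	2	3	6
fs1	TOP2B	6	1/2	1/2	5	6	6	2	11
fs1	UBC	3	6	6	3	5	5	7	7
fs1	YWHAZ	5	8	8	6	7	7	9	5
cis	ACTB	4	1/2	1/2	2	3	3	7	4
cis	B2M	11	8	8	11	10	10	10	12
cis	GAPDH	7	7	7	7	7	7	1	11
cis	HMBS	3	1/2	1/2	1	1	1	4	2
cis	HPRT1	12	13	13	12	12	12	14	5
cis	IGF1R	5	4	4	4	2	2	5	6
cis	RLP13	13	10	10	13	13	13	9	13
cis	RPS18	10	9	9	10	11	11	12	3
cis	SDHA	6	3	3	6	4	4	6	1
cis	SOX9	8	11	11	9	8	8	11	8
cis	TBP	9	12	12	8	9	9	8	9
cis	TOP2B	1/2	5	5	5	5	5	2	7
cis	UBC	14	14	14	14	14	14	13	14
cis	YWHAZ	1/2	6	6	3	6	6	3	10
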