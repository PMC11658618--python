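subtraction	passed_somatic_variants	pams	pams_vaf95
A2T-A2N	14644	355	18
A6T-A6N	28968	1695	210
A10T-A10N	18911	664	70
A32T1-A32N	16896	614	33
A32T2-A32N	9679	379	188
A38T1-A38N	21201	2195	410
A38T2-A38N	21210	1801	312
A38T3-A38N	13022	1645	266
A38T4-A38N	16646	1775	448
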