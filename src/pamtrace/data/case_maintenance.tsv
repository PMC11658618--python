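case	n_metastases	n_truncal_pams	percent_maintained	percent_truncal	percent_shared_all
A2	6	76	91.7	89.2	81.6
A6	6	183	81.3	81.3	67.8
A10	6	120	93.1	93.6	80.8
A32	3	180	92.6	92.6	78.9
A38	11	1360	88.9	92.2	65.1
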