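subject	blood	rpe_choroid	retina	total
S1	71	44	45	160
S2	144	12	17	175
S3	205	70	41	316
Total	420	128	103	651
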