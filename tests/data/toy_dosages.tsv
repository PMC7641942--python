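individual_id	rs1	rs2	rs3
s1	0	1	2
s2	1	0	0
s3	2	NA	1
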