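snp_id	effect_allele	other_allele	odds_ratio
rs1	A	G	10.0
rs2	C	T	2.0
rs3	G	A	1.25
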