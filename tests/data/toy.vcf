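##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
##contig=<ID=2>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	s1	s2	s3
1	1000	rs1	G	A	.	PASS	.	GT	0/0	0/1	1/1
1	2000	rs2	C	T	.	PASS	.	GT	0/1	1/1	./.
2	3000	rs3	A	G	.	PASS	.	GT	1/1	0/0	0/1
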