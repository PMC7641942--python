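snp_id	effect_allele	other_allele	odds_ratio
rs9000001	A	G	8.0
rs9000002	C	T	5.8
rs9000003	G	A	4.2
rs9000004	T	C	2.4
rs9000005	A	G	2.0
rs9000006	C	T	1.9
rs9000007	G	A	1.8
rs9000008	T	C	1.7
rs9000009	A	G	1.65
rs9000010	C	T	1.6
rs9000011	G	A	1.55
rs9000012	T	C	1.5
rs9000013	A	G	1.45
rs9000014	C	T	1.4
rs9000015	G	A	1.38
rs9000016	T	C	1.35
rs9000017	A	G	1.32
rs9000018	C	T	1.3
rs9000019	G	A	1.28
rs9000020	T	C	1.25
rs9000021	A	G	1.22
rs9000022	C	T	1.2
rs9000023	G	A	1.18
rs9000024	T	C	1.16
rs9000025	A	G	1.14
rs9000026	C	T	1.12
rs9000027	G	A	1.11
rs9000028	T	C	1.1
rs9000029	A	G	1.09
rs9000030	C	T	1.08
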