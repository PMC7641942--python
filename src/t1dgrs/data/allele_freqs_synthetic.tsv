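snp_id	effect_allele_freq
rs9000001	0.48
rs9000002	0.64
rs9000003	0.57
rs9000004	0.24
rs9000005	0.28
rs9000006	0.62
rs9000007	0.1
rs9000008	0.59
rs9000009	0.58
rs9000010	0.38
rs9000011	0.28
rs9000012	0.27
rs9000013	0.25
rs9000014	0.37
rs9000015	0.4
rs9000016	0.43
rs9000017	0.7
rs9000018	0.58
rs9000019	0.47
rs9000020	0.69
rs9000021	0.23
rs9000022	0.2
rs9000023	0.47
rs9000024	0.13
rs9000025	0.12
rs9000026	0.41
rs9000027	0.38
rs9000028	0.65
rs9000029	0.48
rs9000030	0.41
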