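sample_id	somatic_snv	somatic_indel	subclonal_snv	subclonal_indel	total_snv	total_indel	total
PCL-016	148	4	17	0	165	4	169
PCL-017	160	11	0	0	160	11	171
PCL-018	25	2	9	1	34	3	37
PCL-019	133	5	17	0	150	5	155
PCL-020	195	15	0	0	195	15	210
PCL-026	232	6	34	0	266	6	272
PCL-027	156	16	0	0	156	16	172
PCL-030	179	11	0	0	179	11	190
PCL-032	176	8	0	0	176	8	184
PCL-035	203	14	0	0	203	14	217
PCL-036	146	16	0	0	146	16	162
PCL-038	40	2	17	0	57	2	59
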