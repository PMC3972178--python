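name	kind	mean_a	sd_a	n_a	mean_b	sd_b	n_b	a_yes	a_no	b_yes	b_no
age_at_blood_draw	summary	25.4	2.71	12	25.8	2.87	8
familial_adversity_score	summary	0.34	0.29	12	0.51	0.41	7
psychiatric_record_21y	count							6	4	3	4
criminal_record_21y	count							2	10	6	2
self_reported_violence_21y	count							1	9	4	3
attention_deficit_score	summary	3.23	2.18	12	4.00	1.89	8
hyperactivity_trajectories	count							3	9	4	4
opposition_trajectories	count							0	12	6	2
anxiety_trajectories	count							1	11	1	7
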