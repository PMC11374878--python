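measure	unit	mean_m	sd_m	n_m	mean_f	sd_f	n_f	printed_rel_pct	printed_d
total_brain_volume	cm3	1290	102	490	1128	90	575	12.6	1.7
white_matter_volume	cm3	476	49	490	409	42	575	13.6	1.4
right_lenticular_radiations_frontal	pct_tbv	1.10	0.42	490	0.90	0.41	575	17.9	0.48
left_middle_cortico_cerebellar	pct_tbv	2.17	0.46	490	1.97	0.46	575	9.2	0.43
right_slf2	pct_tbv	1.26	0.30	490	1.14	0.28	575	9.8	0.42
left_lenticular_radiations_frontal	pct_tbv	1.17	0.39	490	1.01	0.38	575	13.3	0.40
right_thalamic_radiations_parietal	pct_tbv	1.61	0.25	490	1.51	0.23	575	5.7	0.38
left_thalamic_radiations_parietal	pct_tbv	1.58	0.26	490	1.50	0.23	575	5.1	0.33
left_slf2	pct_tbv	0.96	0.28	490	0.88	0.27	575	9.1	0.32
right_slf3	pct_tbv	1.11	0.27	490	1.03	0.24	575	7.1	0.31
left_ifof	pct_tbv	3.15	0.41	490	3.04	0.35	575	3.7	0.30
left_thalamic_radiations_frontal	pct_tbv	2.58	0.26	490	2.50	0.26	575	3.0	0.30
left_dorsal_cingulum	pct_tbv	1.20	0.17	490	1.16	0.17	575	3.6	0.25
right_lenticular_radiations_central	pct_tbv	0.17	0.11	490	0.15	0.10	575	14.9	0.25
right_thalamic_radiations_temporal	pct_tbv	1.50	0.18	490	1.55	0.16	575	-3.2	-0.28
left_fornix	pct_tbv	0.27	0.14	490	0.31	0.14	575	-15.4	-0.30
left_thalamic_radiations_temporal	pct_tbv	1.57	0.17	490	1.63	0.15	575	-3.6	-0.35
corpus_callosum_genu	pct_tbv	2.06	0.27	490	2.21	0.27	575	-7.3	-0.56
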