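network_index	network_name	abbreviation	member_nodes
1	Uncertain	Uncertain	1-12,84-85,132,140-142,182-185,247-250,253-254
2	Sensory_Somatomotor_Hand	SSHN	13-41,255
3	Sensory_Somatomotor_Mouth	SSMN	42-46
4	Cingulo-opercular_Task_Control	CON	47-60
5	Auditory	AN	61-73
6	Default_mode	DMN	74-83,86-131,137,139
7	Memory_retrieval	MRN	133-136,221
8	Ventral_attention	VAN	138,235-242
9	Visual	VN	143-173
10	Fronto-parietal_Task_Control	FPN	174-181,186-202
11	Salience	SN	203-220
12	Subcortical	Subcortical	222-234
13	Cerebellar	Cerebellar	243-246
14	Dorsal_attention	DAN	251-252,256-264
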