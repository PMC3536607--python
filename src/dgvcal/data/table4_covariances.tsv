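trait	breed	var_trait	var_dgv	cov_trait_dgv
birth_weight	limousin	2.80	0.93	0.93
calving_ease_direct	limousin	55.92	11.46	13.12
calving_ease_maternal	limousin	78.12	25.91	22.97
carcass_weight	limousin	107.82	25.67	29.67
docility	limousin	423.76	84.86	75.85
marbling	limousin	0.009	0.002	0.003
rib_eye_muscle_area	limousin	5.00	1.53	1.73
scrotal_circumference	limousin	831.28	154.71	162.65
stayability	limousin	93.07	11.91	12.96
weaning_weight_direct	limousin	68.08	18.76	20.80
weaning_weight_maternal	limousin	26.00	2.83	3.94
yield_grade	limousin	0.018	0.005	0.006
yearling_weight	limousin	111.76	22.82	38.44
birth_weight	simmental	3.49	1.29	1.39
calving_ease_direct	simmental	108.62	29.90	25.72
calving_ease_maternal	simmental	118.60	28.24	18.50
carcass_weight	simmental	122.07	30.87	36.49
fat_thickness	simmental	7.10	1.29	0.64
marbling	simmental	0.145	0.051	0.054
rib_eye_muscle_area	simmental	12.82	4.16	4.33
shear_force	simmental	0.085	0.021	0.022
stayability	simmental	114.30	28.00	32.90
weaning_weight_direct	simmental	75.14	18.01	19.13
weaning_weight_maternal	simmental	53.37	10.14	7.86
yield_grade	simmental	0.073	0.026	0.027
yearling_weight	simmental	726.42	61.77	96.28
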