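trait	breed	h2_dgv	h2_dgv_se	r_g	r_g_se
birth_weight	limousin	1.00	0.00	0.58	0.04
calving_ease_direct	limousin	1.00	0.00	0.52	0.05
calving_ease_maternal	limousin	1.00	0.00	0.51	0.03
carcass_weight	limousin	1.00	0.00	0.56	0.06
docility	limousin	1.00	0.00	0.40	0.04
marbling	limousin	1.00	0.00	0.65	0.06
rib_eye_muscle_area	limousin	1.00	0.00	0.63	0.05
scrotal_circumference	limousin	1.00	0.00	0.45	0.05
stayability	limousin	1.00	0.00	0.39	0.06
weaning_weight_direct	limousin	1.00	0.00	0.58	0.04
weaning_weight_maternal	limousin	1.00	0.00	0.46	0.07
yield_grade	limousin	1.00	0.00	0.67	0.05
yearling_weight	limousin	1.00	0.00	0.76	0.08
birth_weight	simmental	1.00	0.00	0.65	0.03
calving_ease_direct	simmental	1.00	0.00	0.45	0.02
calving_ease_maternal	simmental	0.99	0.02	0.32	0.02
carcass_weight	simmental	1.00	0.00	0.59	0.04
fat_thickness	simmental	0.98	0.02	0.29	0.02
marbling	simmental	1.00	0.00	0.63	0.04
rib_eye_muscle_area	simmental	1.00	0.00	0.59	0.04
shear_force	simmental	1.00	0.00	0.53	0.08
stayability	simmental	1.00	0.00	0.58	0.06
weaning_weight_direct	simmental	1.00	0.00	0.52	0.04
weaning_weight_maternal	simmental	1.00	0.00	0.34	0.03
yield_grade	simmental	1.00	0.00	0.62	0.06
yearling_weight	simmental	1.00	0.00	0.45	0.02
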