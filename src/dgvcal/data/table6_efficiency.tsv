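trait	breed	cohort	r2_pa	efficiency
birth_weight	limousin	genotyped	0.42	0.89
calving_ease_direct	limousin	genotyped	0.41	0.81
calving_ease_maternal	limousin	genotyped	0.41	0.80
carcass_weight	limousin	genotyped	0.39	0.89
docility	limousin	genotyped	0.35	0.68
marbling	limousin	genotyped	0.38	1.05
rib_eye_muscle_area	limousin	genotyped	0.38	1.02
scrotal_circumference	limousin	genotyped	0.32	0.80
stayability	limousin	genotyped	0.32	0.69
weaning_weight_direct	limousin	genotyped	0.40	0.92
weaning_weight_maternal	limousin	genotyped	0.39	0.74
yield_grade	limousin	genotyped	0.38	1.08
yearling_weight	limousin	genotyped	0.36	1.28
birth_weight	simmental	genotyped	0.37	1.06
calving_ease_direct	simmental	genotyped	0.36	0.75
calving_ease_maternal	simmental	genotyped	0.34	0.55
carcass_weight	simmental	genotyped	0.31	1.07
fat_thickness	simmental	genotyped	0.33	0.51
marbling	simmental	genotyped	0.33	1.10
rib_eye_muscle_area	simmental	genotyped	0.32	1.05
shear_force	simmental	genotyped	0.14	1.44
stayability	simmental	genotyped	0.17	1.39
weaning_weight_direct	simmental	genotyped	0.35	0.87
weaning_weight_maternal	simmental	genotyped	0.35	0.57
yield_grade	simmental	genotyped	0.28	1.17
yearling_weight	simmental	genotyped	0.36	0.75
birth_weight	simmental	young	0.37	1.08
calving_ease_direct	simmental	young	0.33	0.78
calving_ease_maternal	simmental	young	0.28	0.60
carcass_weight	simmental	young	0.28	1.11
fat_thickness	simmental	young	0.22	0.62
marbling	simmental	young	0.20	1.41
rib_eye_muscle_area	simmental	young	0.19	1.35
shear_force	simmental	young	0.07	2.04
stayability	simmental	young	0.15	1.48
weaning_weight_direct	simmental	young	0.33	0.91
weaning_weight_maternal	simmental	young	0.28	0.64
yield_grade	simmental	young	0.20	1.40
yearling_weight	simmental	young	0.32	0.79
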