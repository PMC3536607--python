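trait	h2	breed	n	reliability
birth_weight	0.42	limousin	2185	0.65
calving_ease_direct	0.12	limousin	1687	0.61
calving_ease_maternal	0.13	limousin	1669	0.59
carcass_weight	0.40	limousin	1459	0.67
docility	0.35	limousin	1225	0.54
marbling	0.54	limousin	1447	0.61
rib_eye_muscle_area	0.46	limousin	1449	0.62
scrotal_circumference	0.43	limousin	1294	0.44
stayability	0.21	limousin	757	0.50
weaning_weight_direct	0.30	limousin	2150	0.53
weaning_weight_maternal	0.14	limousin	1480	0.55
yield_grade	0.40	limousin	1446	0.62
yearling_weight	0.29	limousin	1780	0.43
birth_weight	0.42	simmental	2664	0.59
calving_ease_direct	0.12	simmental	2443	0.57
calving_ease_maternal	0.13	simmental	2441	0.43
carcass_weight	0.40	simmental	2663	0.46
fat_thickness	0.35	simmental	2463	0.59
marbling	0.54	simmental	2439	0.57
rib_eye_muscle_area	0.46	simmental	2435	0.55
shear_force	0.40	simmental	1045	0.36
stayability	0.21	simmental	563	0.66
weaning_weight_direct	0.30	simmental	2663	0.55
weaning_weight_maternal	0.14	simmental	2661	0.41
yield_grade	0.40	simmental	2574	0.45
yearling_weight	0.29	simmental	2663	0.56
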