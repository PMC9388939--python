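# oofdose-plan v1	technique=IMRT	prescribed_gy=54.0	fraction_gy=1.8	plan_id=pediatric-brain-imrt
field_id	gantry_deg	collimator_deg	couch_deg	field_x_cm	x1_cm	x2_cm	field_y_cm	y1_cm	y2_cm	weight	ssd_cm	mu
1	340.0	0.0	0.0	5.0	2.5	2.5	3.6	1.8	1.8	1.0	93.5	51.0
2	314.0	0.0	0.0	5.0	2.5	2.5	3.6	1.8	1.8	1.0	95.4	47.0
3	266.0	0.0	0.0	5.0	2.5	2.5	3.6	1.8	1.8	1.0	96.5	43.0
4	228.0	0.0	0.0	5.0	2.5	2.5	3.6	1.8	1.8	1.0	95.8	43.0
5	197.0	0.0	0.0	5.0	2.5	2.5	3.6	1.8	1.8	1.0	94.2	47.0
6	173.0	0.0	0.0	5.0	2.5	2.5	3.6	1.8	1.8	1.0	92.7	50.0
7	154.0	0.0	0.0	5.0	2.5	2.5	3.6	1.8	1.8	1.0	91.5	53.0
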