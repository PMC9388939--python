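# oofdose-plan v1	technique=3DCRT	prescribed_gy=54.0	fraction_gy=1.8	plan_id=pediatric-brain-3dcrt
field_id	gantry_deg	collimator_deg	couch_deg	field_x_cm	x1_cm	x2_cm	field_y_cm	y1_cm	y2_cm	weight	ssd_cm	mu
1	320.0	0.0	0.0	3.2	1.6	1.6	3.2	1.6	1.6	0.70	95.1	32
2	270.0	0.0	0.0	3.2	1.6	1.6	3.2	1.6	1.6	0.70	96.5	30
3	235.0	0.0	15.0	3.4	1.7	1.7	3.4	1.7	1.7	0.70	95.9	31
4	40.0	0.0	50.0	3.4	1.7	1.7	3.4	1.7	1.7	1.10	90.1	63
5	155.0	0.0	345.0	3.4	1.7	1.7	3.4	1.7	1.7	1.00	91.5	53
6	60.0	309.0	30.0	3.4	1.7	1.7	3.5	1.7	1.8	1.00	89.3	60
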