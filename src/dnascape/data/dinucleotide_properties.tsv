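# Bundled dinucleotide property model table (test/demo FIXTURE).
# Synthetic stand-in for a full property-model database: a small selection of
# named models with literature-typical magnitudes and correct strand symmetry
# (helical parameters symmetric under reverse complement; Tilt/Shift
# antisymmetric).  Values are plausible, not authoritative measurements.
id	name	units	AA	AC	AG	AT	CA	CC	CG	CT	GA	GC	GG	GT	TA	TC	TG	TT
1	Twist	deg	35.6	32.2	27.7	31.5	34.5	33.7	29.8	27.7	36.9	40.0	33.7	32.2	36.0	36.9	34.5	35.6
3	Rise	A	3.27	3.36	3.34	3.31	3.33	3.42	3.39	3.34	3.37	3.40	3.42	3.36	3.29	3.37	3.33	3.27
7	Major Groove Width	A	11.1	11.4	11.3	11.0	11.7	11.8	11.9	11.3	11.4	11.6	11.8	11.4	11.2	11.4	11.7	11.1
11	Minor Groove Width	A	4.9	5.9	5.4	4.3	5.8	6.1	6.4	5.4	5.5	6.0	6.1	5.9	5.2	5.5	5.8	4.9
15	Persistence Length	nm	50.4	44.7	48.8	40.1	46.8	54.4	47.0	48.8	49.1	52.1	54.4	44.7	39.0	49.1	46.8	50.4
28	Slide	A	-0.08	-0.58	-0.25	-0.59	0.53	-0.22	0.41	-0.25	0.09	-0.38	-0.22	-0.58	0.05	0.09	0.53	-0.08
30	Shift	A	-0.02	0.14	-0.02	0.0	0.07	0.05	0.0	0.02	-0.12	0.0	-0.05	-0.14	0.0	0.12	-0.07	0.02
62	Tilt	deg	-1.4	-0.1	-1.7	0.0	0.5	-0.1	0.0	1.7	-1.5	0.0	0.1	0.1	0.0	1.5	-0.5	1.4
63	Roll	deg	0.7	0.7	4.5	1.1	4.7	3.6	5.4	4.5	1.9	-5.8	3.6	0.7	3.3	1.9	4.7	0.7
67	Slide stiffness	kcal/mol/A2	2.26	3.03	2.03	3.85	1.78	1.65	1.20	2.03	1.93	2.61	1.65	3.03	1.20	1.93	1.78	2.26
71	Twist stiffness	kcal/mol/deg2	0.035	0.033	0.028	0.043	0.021	0.026	0.025	0.028	0.031	0.036	0.026	0.033	0.017	0.031	0.021	0.035
94	Roll	deg	0.6	0.9	3.1	0.0	5.1	4.0	5.6	3.1	1.5	-6.2	4.0	0.9	2.8	1.5	5.1	0.6
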