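# Serum metabolite multiplet library, 500.26 MHz.
# One row per resolved multiplet: name, proton group, chemical shift (ppm),
# splitting pattern (s/d/t/q/dd/m), J couplings (Hz, ';'-separated, empty for
# s and m), proton count, and a default relative concentration (arbitrary
# units, shared by all multiplets of a metabolite) used by the simulator.
metabolite	group	shift_ppm	pattern	couplings_hz	protons	concentration
lactate	CH3	1.31	d	6.98	3	2.0
lactate	CH	4.10	q	7.0	1	2.0
threonine	CH3	1.32	m		3	0.15
threonine	CH	3.56	d	5.0	1	0.15
threonine	CH	4.23	dd	4.9;6.6	1	0.15
leucine	CH3	0.94	d	6.24	3	0.15
leucine	CH3	0.95	d	6.24	3	0.15
valine	CH3	0.97	d	7.00	3	0.25
valine	CH3	1.03	d	7.00	3	0.25
valine	CH	3.59	d	4.39	1	0.25
glutamine	CH2	2.12	m		2	0.55
glutamine	CH2	2.44	m		2	0.55
glutamate	CH2	2.04	m		1	0.08
glutamate	CH2	2.11	m		1	0.08
citrate	CH2	2.51	d	16.0	2	0.12
citrate	CH2	2.68	d	16.0	2	0.12
aspartate	CH2	2.66	dd	8.8;17.5	1	0.03
aspartate	CH2	2.80	dd	3.8;17.4	1	0.03
asparagine	CH2	2.82	m		1	0.05
asparagine	CH2	2.93	m		1	0.05
alanine	CH3	1.46	d	7.26	3	0.45
3-hydroxybutyrate	CH3	1.19	d	6.4	3	0.10
3-hydroxybutyrate	CH2	2.40	dd	7.2;14.4	1	0.10
3-hydroxybutyrate	CH2	2.29	dd	6.4;14.4	1	0.10
gaba	CH2	3.04	t	7.6	2	0.03
choline	CH2	4.05	m		2	0.04
acylglycerols	CH2	4.10	m		1	0.12
acylglycerols	CH2	4.23	m		1	0.12
acylglycerols	CH	5.20	m		1	0.12
glucose	CH-4	3.40	m		1	5.0
glucose	CH-2	3.52	dd	3.7;9.7	1	5.0
glucose	CH-3	3.70	m		1	5.0
glucose	CH2-6	3.75	dd	5.1;12.0	1	5.0
glucose	CH2-6	3.83	m		1	5.0
glucose	CH-5	3.82	m		1	5.0
glucose	CH-1	5.22	d	3.9	1	5.0
arginine	CH2	3.23	t	6.6	2	0.08
arginine	CH2	1.70	m		1	0.08
arginine	CH2	1.64	m		1	0.08
lysine	CH2	1.91	m		2	0.18
2-hydroxybutyrate	CH3	0.88	t	7.50	3	0.05
2-hydroxybutyrate	CH2	1.70	m		1	0.05
2-hydroxybutyrate	CH2	1.64	m		1	0.05
isoleucine	CH3	0.92	t	7.4	3	0.06
isoleucine	CH3	0.99	d	7.0	3	0.06
isoleucine	CH	3.65	d	4.04	1	0.06
serine	CH2	3.97	dd	3.8;12.2	1	0.12
serine	CH2	3.92	dd	5.7;12.2	1	0.12
serine	CH	3.82	m		1	0.12
mannose	CH	3.55	t	9.4	1	0.06
mannose	CH	3.79	m		1	0.06
mannose	CH	3.84	dd	2.2;4.0	1	0.06
mannose	CH	3.95	m		1	0.06
mannose	CH-1	5.17	d	1.4	1	0.06
glycine	CH2	3.54	s		2	0.25
glycerol	CH2	3.64	m		1	0.08
glycerol	CH2	3.55	m		1	0.08
glycerol	CH	3.70	m		1	0.08
tyrosine	CH	3.96	dd	5.0;8.1	1	0.06
tyrosine	Ar	6.88	m		2	0.06
tyrosine	Ar	7.18	m		2	0.06
phenylalanine	Ar	7.30	m		2	0.06
phenylalanine	Ar	7.37	m		2	0.06
phenylalanine	Ar	7.41	m		1	0.06
paba	Ar	6.93	m		2	0.02
paba	Ar	7.80	m		2	0.02
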