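set	size	p_value	fdr	altered	increased	decreased
Unsaturated_LPC	9	2.2E-20	1.1E-18	9	0	9
Unsaturated_TG	46	1.5E-15	3.7E-14	31	30	1
PC	44	5E-13	8.2E-12	29	1	28
Saturated_LPC	3	2.7E-12	3.4E-11	3	0	3
BCAA	3	5.8E-12	5.7E-11	3	3	0
Saturated_TG	4	1.6E-11	1.3E-10	4	4	0
butyrates	3	6.1E-10	4.3E-09	3	2	1
sphingomyelins	16	1.1E-09	6.8E-09	13	11	2
hexoses	9	2.2E-06	1.2E-05	7	6	1
pentoses	3	4.1E-06	1.8E-05	3	3	0
plasmalogens	3	4.1E-06	1.8E-05	3	0	3
disaccharides	7	7.1E-06	2.9E-05	6	6	0
hydroxybutyrates	3	1.1E-05	4E-05	3	3	0
PI	6	2.2E-05	7.6E-05	5	0	5
sugar acids	9	1.4E-04	4.6E-04	6	6	0
cholesterol esters	4	5.1E-04	1.6E-03	3	0	3
DiHODE	4	1.0E-03	3E-03	2	0	2
PE	9	2.3E-03	6.3E-03	5	1	4
indoles	3	1.6E-02	4.2E-02	2	2	0
amino acids, aromatic	3	2.0E-02	4.8E-02	2	0	2
sugar alcohols	9	2.2E-02	5.1E-02	4	3	1
Saturated FA	9	2.7E-02	5.7E-02	3	2	1
HETrE	3	2.7E-02	5.7E-02	2	0	2
HETE	6	2.8E-02	5.7E-02	3	0	3
oxo-ETE	4	3.0E-02	5.8E-02	2	0	2
amino acids, sulfur	4	3.8E-02	7E-02	2	0	2
pyridines	3	3.9E-02	7E-02	2	2	0
hexosephosphates	3	4.0E-02	7E-02	2	2	0
tricarboxylic acids	3	4.1E-02	7E-02	2	2	0
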