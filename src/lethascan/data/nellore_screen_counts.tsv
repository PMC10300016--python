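# Zero-homozygote haplotype counts from a published depletion-of-homozygotes
# screen of 62,022 genotyped Nellore cattle (30 candidate haplotypes).
# Columns: haplotype id (segment.rank), chromosome (BTA), carrier count,
# printed haplotype percentage, printed simple expected-homozygote count,
# printed simple zero-homozygote probability, carrier-sire x carrier-MGS
# pair count, printed mating zero-homozygote probability. n_genotyped=62022.
haplotype	chrom	n_carriers	hap_pct_printed	exp_hom_simple_printed	phh_simple_printed	n_carrier_matings	phh_mating_printed
25.1	1	5929	4.78	141	4.07E-16	69	2.39E-09
108.7	1	4750	3.83	91	1.32E-10	123	4.29E-16
231.4	2	4998	4.03	101	1.15E-11	73	7.58E-10
346.2	2	11771	9.49	560	1.93E-61	368	1.05E-46
396.3	3	4291	3.46	74	8.65E-09	7	1.33E-01
461.4	3	5941	4.79	142	3.51E-16	96	1.01E-12
479.2	3	3783	3.05	57	5.43E-07	60	3.19E-08
676.1	5	4130	3.33	69	3.40E-08	2	5.63E-01
769.3	5	4143	3.34	69	3.07E-08	26	5.64E-04
966.2	7	6053	4.88	148	9.09E-17	58	5.67E-08
988.14	7	4329	3.49	76	6.26E-09	26	5.64E-04
1045.24	7	4564	3.68	84	7.57E-10	3	4.22E-01
1077.1	7	6958	5.61	196	6.29E-22	170	5.76E-22
1184.1	8	3832	3.09	59	3.71E-07	37	2.38E-05
1192.1	8	12441	10.03	625	1.48E-68	588	3.44E-74
1277.30	9	4056	3.27	66	6.29E-08	5	2.37E-01
1278.37	9	3733	3.01	56	7.91E-07	4	3.16E-01
1283.33	9	3981	3.21	63	1.15E-07	4	3.16E-01
1312.67	9	3721	3.0	56	8.68E-07	4	3.16E-01
1457.2	10	4378	3.53	77	4.05E-09	55	1.34E-07
1655.2	12	4242	3.42	72	1.33E-08	79	1.35E-10
2213.8	17	3696	2.98	55	1.05E-06	9	7.51E-02
2237.1	18	4775	3.85	92	1.04E-10	4	3.16E-01
2270.1	18	3795	3.06	58	4.94E-07	38	1.79E-05
2329.1	19	5358	4.32	116	2.69E-13	55	1.34E-07
2371.1	19	15145	12.21	927	2.63E-101	1028	3.66E-129
2585.3	22	4192	3.39	71	1.82E-08	78	1.80E-10
2620.2	22	4180	3.37	70	2.25E-08	10	5.63E-02
2724.2	24	4651	3.75	87	3.38E-10	76	3.20E-10
3063.3	29	6189	4.99	154	1.69E-17	163	4.32E-21
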