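substrate	substrate_class	mean_plus	sd_plus	mean_minus	sd_minus	t	df	p_adj	outcome
α-D-glucose	monosaccharides	1.49	0.02	1.16	0.04	14.63	6.21	<0.00001	5
D-arabinose	monosaccharides	0.71	0.04	1.04	0.07	9.31	6.90	<0.00001	4
D-fructose	monosaccharides	1.69	0.18	1.47	0.14	2.20	7.60	0.08	2
D-galactose	monosaccharides	1.80	0.08	1.41	0.10	6.75	7.38	0.0004	5
D-mannose	monosaccharides	1.58	0.05	1.18	0.07	10.90	7.09	<0.00001	5
D-psicose	monosaccharides	0.25	0.01	0.15	0.00	19.99	4.90	NA	1
D-ribose	monosaccharides	1.91	0.06	1.23	0.18	8.00	4.84	0.001	5
D-tagatose	monosaccharides	0.15	0.01	0.13	0.01	2.73	7.29	NA	1
D-xylose	monosaccharides	2.06	0.06	1.39	0.05	19.12	7.44	<0.000001	5
L-arabinose	monosaccharides	1.72	0.08	1.53	0.07	3.86	7.67	0.008	5
L-fucose	monosaccharides	1.81	0.26	1.51	0.06	2.55	4.40	0.08	2
L-sorbose	monosaccharides	2.14	0.03	1.44	0.05	30.13	6.44	<0.0000001	5
α-D-lactose	disaccharides	0.91	0.08	0.39	0.02	14.44	4.76	0.0001	5
D-cellobiose	disaccharides	1.61	0.18	1.19	0.04	5.08	4.32	0.009	5
D-melibiose	disaccharides	1.55	0.04	1.38	0.04	6.00	7.99	0.0007	5
D-trehalose	disaccharides	2.55	0.01	2.15	0.04	21.83	5.05	<0.00001	5
gentiobiose	disaccharides	1.71	0.05	0.80	0.03	35.20	7.28	<0.0000001	5
isomaltulose	disaccharides	1.69	0.04	1.19	0.04	19.49	7.92	<0.0000001	5
lactulose	disaccharides	0.66	0.04	0.12	0.04	20.91	7.98	<0.0000001	3
maltose	disaccharides	1.59	0.03	1.38	0.03	10.51	7.84	<0.00001	5
sucrose	disaccharides	1.92	0.06	1.30	0.09	13.28	6.90	<0.00001	5
turanose	disaccharides	2.13	0.04	1.62	0.05	17.54	7.83	<0.000001	5
D-melezitose	trisaccharides	1.81	0.06	1.34	0.04	14.53	7.38	<0.000001	5
D-raffinose	trisaccharides	1.46	0.04	1.34	0.06	3.93	7.03	0.009	5
maltotriose	trisaccharides	1.54	0.04	1.39	0.05	4.76	7.58	0.003	5
stachyose	tetrasaccharides	1.52	0.05	1.35	0.11	3.03	5.76	0.03	5
dextrin	oligosaccharides	0.91	0.03	0.76	0.03	7.45	7.72	0.0002	5
α-cyclodextrin	cyclic oligosaccharides	0.14	0.01	0.11	0.00	9.26	7.35	NA	1
β-cyclodextrin	cyclic oligosaccharides	0.38	0.08	0.32	0.04	1.74	6.39	0.2	2
adenosine	nucleosides	0.77	0.59	0.64	0.40	0.41	6.97	0.7	2
uridine	nucleosides	0.14	0.01	0.13	0.01	1.52	5.67	NA	1
glycogen	polysaccharides	0.96	0.03	0.81	0.02	8.57	6.03	0.0003	5
D-arabitol	sugar alcohols	2.28	0.07	1.64	0.09	12.81	7.71	<0.00001	5
D-mannitol	sugar alcohols	2.44	0.06	2.36	0.14	1.29	5.54	0.3	2
D-sorbitol	sugar alcohols	2.54	0.03	1.45	0.36	6.67	4.05	0.004	5
glycerol	sugar alcohols	1.68	0.07	1.37	0.05	7.84	6.81	0.0003	5
i-erythritol	sugar alcohols	1.95	0.44	1.92	0.14	0.15	4.77	0.9	2
myo-inositol	sugar alcohols	1.45	0.04	1.18	0.02	12.56	6.01	<0.00001	5
maltitol	sugar alcohols	2.12	0.04	1.32	0.17	10.08	4.40	0.0007	5
ribitol	sugar alcohols	1.18	0.06	0.32	0.02	31.43	5.13	<0.000001	5
xylitol	sugar alcohols	0.17	0.01	0.17	0.01	0.88	6.07	NA	1
L-rhamnose	methyl sugars	2.05	0.04	1.79	0.07	7.72	6.17	0.0005	5
methyl α-D-galactoside	methyl sugars	1.89	0.29	1.32	0.16	3.90	6.18	0.01	5
methyl β-D-galactoside	methyl sugars	0.58	0.04	0.34	0.02	13.42	5.73	<0.00001	5
methyl α-D-glucoside	methyl sugars	2.14	0.04	2.20	0.07	1.77	6.71	0.1	2
methyl β-D-glucoside	methyl sugars	2.21	0.06	1.52	0.06	18.02	7.97	<0.000001	5
salicin	alcoholic β-glucosides	0.97	0.02	0.54	0.02	30.08	8.00	<0.0000001	5
arbutin	glycosides	0.90	0.06	0.70	0.03	7.16	5.99	0.0007	5
sedoheptulosan	misc. carbohydrates	0.12	0.01	0.14	0.03	1.63	4.77	NA	1
D-glucosamine	amino sugars	0.39	0.11	0.59	0.05	3.69	5.71	0.02	4
N-acetyl-D-galactosamine	amino sugars	0.11	0.00	0.10	0.00	7.00	5.82	NA	1
N-acetyl-D-glucosamine	amino sugars	2.38	0.08	1.06	0.04	34.01	5.89	<0.0000001	5
N-acetyl-D-mannosamine	amino sugars	0.11	0.00	0.10	0.00	3.04	5.77	NA	1
L-alanine	amino acids	1.65	0.13	0.95	0.20	6.61	6.75	0.0007	5
L-proline	amino acids	2.12	0.04	1.24	0.20	9.86	4.31	0.0008	5
L-serine	amino acids	1.50	0.11	0.79	0.23	6.36	5.71	0.002	5
L-threonine	amino acids	1.97	0.04	0.79	0.01	65.09	4.49	<0.000001	5
L-aspartic acid	amino acids	1.18	0.06	1.18	0.11	0.03	5.92	1.0	2
L-glutamic acid	amino acids	1.51	0.06	0.88	0.04	18.40	6.94	<0.000001	5
N-acetyl-L-glutamic acid	amino acids	0.13	0.00	0.13	0.01	0.34	6.90	NA	1
glycyl-L-glutamic acid	amino acids	0.13	0.00	0.13	0.01	1.79	7.22	NA	1
L-pyroglutamic acid	amino acids	1.77	0.07	1.25	0.12	8.26	6.39	0.0003	5
γ-aminobutyric acid	amino acids	2.24	0.03	0.84	0.12	24.28	4.63	<0.00001	5
L-asparagine	amino acids	1.86	0.02	0.91	0.11	18.56	4.35	<0.00001	5
L-phenylalanine	amino acids	1.21	0.05	1.23	0.29	0.12	4.26	0.9	2
L-ornithine	amino acids	1.81	0.03	0.92	0.15	13.18	4.24	0.0003	5
L-alanyl-glycine	amino acids	1.09	0.05	1.06	0.07	0.61	7.64	0.6	2
amygdalin	amino acid derivatives	1.03	0.04	0.83	0.03	8.55	7.63	0.0001	5
2-keto-D-gluconic acid	carboxylic acids	0.84	0.02	0.70	0.07	4.43	4.46	0.01	5
α-ketoglutaric acid	carboxylic acids	0.69	0.06	0.62	0.13	1.16	5.38	0.3	2
β-hydroxybutyric acid	carboxylic acids	1.09	0.07	0.72	0.06	9.35	7.90	<0.00001	5
D-glucuronic acid	carboxylic acids	0.79	0.04	0.49	0.06	9.03	7.21	0.0001	5
D-galacturonic acid	carboxylic acids	1.14	0.07	0.92	0.07	5.10	8.00	0.002	5
D-gluconic acid	carboxylic acids	0.98	0.02	0.67	0.06	11.77	4.84	0.0002	5
D-saccharic acid	carboxylic acids	0.87	0.04	0.57	0.04	13.52	7.99	<0.000001	5
D-malic acid	carboxylic acids	1.23	0.04	1.47	0.04	9.28	7.91	<0.00001	4
L-malic acid	carboxylic acids	0.81	0.02	0.94	0.09	3.06	4.40	0.04	4
L-lactic acid	carboxylic acids	0.54	0.02	0.40	0.02	11.45	7.91	<0.00001	5
γ-hydroxybutyric acid	carboxylic acids	0.23	0.10	0.15	0.01	1.71	4.08	NA	1
fumaric acid	carboxylic acids	1.09	0.05	1.13	0.15	0.62	4.99	0.6	2
p-hydroxyphenylacetic acid	carboxylic acids	1.46	0.08	1.24	0.24	1.94	4.92	0.1	2
quinic acid	carboxylic acids	1.89	0.09	1.15	0.17	8.41	6.04	0.0003	5
sebacic acid	carboxylic acids	1.43	0.06	0.94	0.15	6.70	5.05	0.002	5
succinic acid	carboxylic acids	0.70	0.02	0.52	0.05	7.70	4.90	0.001	5
D-lactic acid methyl ester	esters	0.22	0.00	0.17	0.00	15.96	8.00	NA	1
succinic acid monomethyl ester	esters	1.20	0.11	0.79	0.16	4.76	6.87	0.004	5
alaninamide	amides	0.21	0.01	0.20	0.01	1.14	5.81	NA	1
glucuronamide	amides	0.10	0.01	0.11	0.00	3.21	5.48	NA	1
succinamic acid	amides	1.13	0.10	1.82	0.13	9.78	7.48	<0.00001	4
ethanolamine	amides	0.92	0.04	1.05	0.21	1.41	4.23	0.3	1
putrescine	amides	1.90	0.06	0.77	0.18	13.66	4.76	0.0001	5
glucose-1-phosphate	phosphorylated chemicals	0.14	0.01	0.14	0.00	0.35	7.71	NA	1
adenosine-5′-monophosphate	phosphorylated chemicals	0.12	0.01	0.11	0.00	2.28	5.97	NA	1
bromosuccinic acid	brominated chemicals	0.38	0.02	0.25	0.01	13.54	7.90	<0.000001	3
Tween 80	surfactants	0.62	0.06	0.55	0.03	2.25	5.63	0.09	2
water	surfactants	0.11	0.00	0.10	0.00	2.98	6.86	NA	1
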