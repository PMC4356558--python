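compound	class_label	replicate	d	published_call
Chloramine T	respiratory	1	0.52	sensitizer
Chloramine T	respiratory	2	0.59	sensitizer
Ethylenediamine	respiratory	1	-0.32	non_sensitizer
Ethylenediamine	respiratory	2	-0.20	non_sensitizer
Isophorone diisocyanate	respiratory	1	0.10	sensitizer
Isophorone diisocyanate	respiratory	2	0.17	sensitizer
Phtalic Anhydride	respiratory	1	0.20	sensitizer
Phtalic Anhydride	respiratory	2	-0.12	sensitizer
Piperazine	respiratory	1	-0.05	non_sensitizer
Piperazine	respiratory	2	-0.12	non_sensitizer
Reactive Orange	respiratory	1	0.41	sensitizer
Reactive Orange	respiratory	2	0.41	sensitizer
1-Butanol	non_respiratory	1	-0.32	sensitizer
1-Butanol	non_respiratory	2	0.12	sensitizer
2,4-dinitrochlorobenzene	non_respiratory	1	-1.66	non_sensitizer
2,4-dinitrochlorobenzene	non_respiratory	2	-1.18	non_sensitizer
2,4-dinitrochlorobenzene	non_respiratory	3	-1.90	non_sensitizer
2-mercaptobenzothiazole	non_respiratory	1	-0.44	non_sensitizer
2-mercaptobenzothiazole	non_respiratory	2	-0.43	non_sensitizer
2-mercaptobenzothiazole	non_respiratory	3	-0.57	non_sensitizer
Benzaldehyde	non_respiratory	1	-0.79	non_sensitizer
Benzaldehyde	non_respiratory	2	-0.87	non_sensitizer
Benzaldehyde	non_respiratory	3	-0.70	non_sensitizer
Chlorobenzene	non_respiratory	1	-1.03	sensitizer
Chlorobenzene	non_respiratory	2	-0.76	sensitizer
Chlorobenzene	non_respiratory	3	-1.15	sensitizer
Chlorobenzene	non_respiratory	4	0.24	sensitizer
Chlorobenzene	non_respiratory	5	0.06	sensitizer
Cinnamyl alcohol	non_respiratory	1	-0.57	non_sensitizer
Cinnamyl alcohol	non_respiratory	2	-1.44	non_sensitizer
Cinnamyl alcohol	non_respiratory	3	-1.26	non_sensitizer
Diethyl phthalate	non_respiratory	1	-1.37	non_sensitizer
Diethyl phthalate	non_respiratory	2	-0.96	non_sensitizer
Diethyl phthalate	non_respiratory	3	-1.22	non_sensitizer
Eugenol	non_respiratory	1	-1.67	non_sensitizer
Eugenol	non_respiratory	2	-1.53	non_sensitizer
Eugenol	non_respiratory	3	-1.51	non_sensitizer
Glycerol	non_respiratory	1	-1.05	non_sensitizer
Glycerol	non_respiratory	2	-1.11	non_sensitizer
Glycerol	non_respiratory	3	-0.77	non_sensitizer
Glyoxal	non_respiratory	1	-1.02	non_sensitizer
Glyoxal	non_respiratory	2	-0.69	non_sensitizer
Glyoxal	non_respiratory	3	-0.56	non_sensitizer
Isoeugenol	non_respiratory	1	-1.44	non_sensitizer
Isoeugenol	non_respiratory	2	-1.27	non_sensitizer
Isoeugenol	non_respiratory	3	-1.32	non_sensitizer
Lactic acid	non_respiratory	1	-1.20	non_sensitizer
Lactic acid	non_respiratory	2	-0.81	non_sensitizer
Lactic acid	non_respiratory	3	-0.89	non_sensitizer
Octanoic acid	non_respiratory	1	-0.65	non_sensitizer
Octanoic acid	non_respiratory	2	-0.79	non_sensitizer
Octanoic acid	non_respiratory	3	-1.22	non_sensitizer
Phenol	non_respiratory	1	-1.04	non_sensitizer
Phenol	non_respiratory	2	-0.38	non_sensitizer
Phenol	non_respiratory	3	-0.95	non_sensitizer
p-hydroxybenzoic acid	non_respiratory	1	-0.81	non_sensitizer
p-hydroxybenzoic acid	non_respiratory	2	-0.56	non_sensitizer
p-hydroxybenzoic acid	non_respiratory	3	-1.09	non_sensitizer
p-phenylenediamine	non_respiratory	1	-1.38	non_sensitizer
p-phenylenediamine	non_respiratory	2	-1.19	non_sensitizer
p-phenylenediamine	non_respiratory	3	-1.80	non_sensitizer
Resorcinol	non_respiratory	1	-1.01	non_sensitizer
Resorcinol	non_respiratory	2	-0.99	non_sensitizer
Resorcinol	non_respiratory	3	-1.40	non_sensitizer
Salicylic acid	non_respiratory	1	-0.73	non_sensitizer
Salicylic acid	non_respiratory	2	-1.08	non_sensitizer
Salicylic acid	non_respiratory	3	-1.13	non_sensitizer
Sodium dodecyl sulphate	non_respiratory	1	-1.49	non_sensitizer
Sodium dodecyl sulphate	non_respiratory	2	-0.80	non_sensitizer
Sodium dodecyl sulphate	non_respiratory	3	-1.30	non_sensitizer
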