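compound	class_label	role	n_arrays	is_vehicle
Ammonium hexachloroplatinate	respiratory	train	3	False
Ammonium persulfate	respiratory	train	2	False
Ethylenediamine	respiratory	train	3	False
Glutaraldehyde	respiratory	train	3	False
Hexamethylen diisocyanate	respiratory	train	3	False
Maleic Anhydride	respiratory	train	3	False
Methylene diphenol diisocyanate	respiratory	train	3	False
Phtalic Anhydride	respiratory	train	3	False
Toluendiisocyanate	respiratory	train	3	False
Trimellitic anhydride	respiratory	train	3	False
1-Butanol	non_respiratory	train	3	False
2-Aminophenol	non_respiratory	train	3	False
2-Hydroxyethyl acrylate	non_respiratory	train	3	False
2-nitro-1,4-Phenylenediamine	non_respiratory	train	3	False
4-Aminobenzoic acid	non_respiratory	train	6	False
Chlorobenzene	non_respiratory	train	3	False
Dimethyl formamide	non_respiratory	train	3	False
Ethyl vanillin	non_respiratory	train	3	False
Formaldehyde	non_respiratory	train	3	False
Geraniol	non_respiratory	train	3	False
Hexylcinnamic aldehyde	non_respiratory	train	3	False
Isopropanol	non_respiratory	train	3	False
Kathon CG	non_respiratory	train	3	False
Methyl salicylate	non_respiratory	train	3	False
Penicillin G	non_respiratory	train	3	False
Propylene glycol	non_respiratory	train	3	False
Potassium Dichromate	non_respiratory	train	3	False
Potassium permanganate	non_respiratory	train	2	False
Tween 80	non_respiratory	train	3	False
Zinc sulphate	non_respiratory	train	3	False
DMSO	non_respiratory	train	6	True
Water	non_respiratory	train	6	True
Chloramine T	respiratory	test	2	False
Ethylenediamine	respiratory	test	2	False
Isophorone diisocyanate	respiratory	test	2	False
Phtalic Anhydride	respiratory	test	2	False
Piperazine	respiratory	test	2	False
Reactive Orange	respiratory	test	2	False
1-Butanol	non_respiratory	test	2	False
2,4-dinitrochlorobenzene	non_respiratory	test	3	False
2-mercaptobenzothiazole	non_respiratory	test	3	False
Benzaldehyde	non_respiratory	test	3	False
Chlorobenzene	non_respiratory	test	5	False
Cinnamyl alcohol	non_respiratory	test	3	False
Diethyl phthalate	non_respiratory	test	3	False
Eugenol	non_respiratory	test	3	False
Glycerol	non_respiratory	test	3	False
Glyoxal	non_respiratory	test	3	False
Isoeugenol	non_respiratory	test	3	False
Lactic acid	non_respiratory	test	3	False
Octanoic acid	non_respiratory	test	3	False
Phenol	non_respiratory	test	3	False
p-hydroxybenzoic acid	non_respiratory	test	3	False
p-phenylenediamine	non_respiratory	test	3	False
Resorcinol	non_respiratory	test	3	False
Salicylic acid	non_respiratory	test	3	False
Sodium dodecyl sulphate	non_respiratory	test	3	False
DMSO	non_respiratory	test	13	True
Water	non_respiratory	test	9	True
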