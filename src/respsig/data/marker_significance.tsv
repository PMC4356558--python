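compound	class_label	significant
Ammonium hexachloroplatinate	respiratory	True
Ammonium persulfate	respiratory	False
Ethylenediamine	respiratory	False
Glutaraldehyde	respiratory	True
Hexamethylen diisocyanate	respiratory	False
Maleic Anhydride	respiratory	False
Methylene diphenol diisocyanate	respiratory	False
Phtalic Anhydride	respiratory	False
Toluendiisocyanate	respiratory	False
Trimellitic anhydride	respiratory	False
1-Butanol	non_respiratory	False
2-Aminophenol	non_respiratory	True
2-Hydroxyethyl acrylate	non_respiratory	False
2-nitro-1,4-Phenylenediamine	non_respiratory	False
4-Aminobenzoic acid	non_respiratory	False
Chlorobenzene	non_respiratory	False
Dimethyl formamide	non_respiratory	False
Ethyl vanillin	non_respiratory	False
Formaldehyde	non_respiratory	False
Geraniol	non_respiratory	False
Hexylcinnamic aldehyde	non_respiratory	False
Isopropanol	non_respiratory	False
Kathon CG	non_respiratory	True
Methyl salicylate	non_respiratory	False
Penicillin G	non_respiratory	False
Propylene glycol	non_respiratory	False
Potassium Dichromate	non_respiratory	False
Potassium permanganate	non_respiratory	False
Tween 80	non_respiratory	False
Zinc sulphate	non_respiratory	False
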