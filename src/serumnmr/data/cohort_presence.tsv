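# Presence/absence of NMR serum schizophrenia biomarkers across three
# published cohorts, with the source-citation keys per row.  Spellings kept
# verbatim from the source table (e.g. "Serin", "PABA"); a synonym map in
# serumnmr.overlap provides canonical names.
metabolite	Serbian	Brazilian	Chinese	refs	note
Lactate/lactic acid	+	+	+	B9;B10;B12
Threonine	+	+	+	B9;B10
Leucine	+	+	+	B10;B12
Valine	+	+	+	B9;B10;B11;B12
Glutamine	+	+	+	B9;B10;B12
Glutamate/glutamic acid	+	+	−	B9
Citrate/citric acid	+	−	+	B10
Aspartate/aspartic acid	+	−	−
Asparagine	+	+	+	B9;B10;B11
Alanine	+	+	+	B9;B10;B11;B12
3-Hydroxybutyric acid	+	−	+	B10
Gamma-aminobutyric acid	+	+	+	B9;B11;B12
Choline	+	+	+	B10;B12
Acylglycerols	+	−	−
Glucose	+	+	+	B9;B10;B12
Arginine	+	−	+	B10
Lysine	+	−	−
2-Hydroxybutyric acid	+	−	−
Isoleucine	+	+	+	B9;B10;B12
Serin	+	+	−	B9
Mannose	+	+	−	B9
Glycine	+	+	+	B9;B10;B12
Glycerol	+	−	+	B10;B11
Tyrosine	+	+	+	B10;B12
Phenylalanine	+	+	−	B9;B12
PABA	+	+	−	B9
Acetylcholine	−	+	−	B12
Mannitol	−	+	−	B9;B12
Amygdalin	−	+	−	B9
Lipoamide	−	+	−	B12
Myo-inositol	−	+	+	B10;B12
Proline	−	−	+	B10
Acetyl-glycoprotein	−	−	+	B10
Pyruvate	−	−	+	B10;B11
Dimethylamine	−	−	+	B10;B11
Creatine	−	+	+	B10;B12
Taurine	−	−	+	B10;B11
3-Methylhistidine	−	−	+	B10
Hypotaurine	−	−	+	B11
Malonate	−	−	+	B11
Guanidinoacetic acid	−	−	+	B11
Propylene glycol	−	−	+	B11
Threitol	−	−	+	B11
Acetoacetate	−	−	+	B11
Methymalonic acid	−	−	+	B11
Malic acid	−	−	+	B11
N-Acetylglycine	−	−	+	B11
Dimethylglycine	−	−	+	B11
Betaine	−	−	+	B11
Arabitol	−	−	+	B11
Xylitol	−	−	+	B11
Phosphocholine	−	+	−	B11;B12	cites a Chinese-cohort reference while marked absent there
2-Methylglutaric acid	−	−	+	B11
Fructose	−	−	+	B11
D-Gluconic acid	−	−	+	B11
Galactitol	−	−	+	B11
Homovanillic acid	−	−	+	B11
Methylamine	−	−	+	B11
6-Hydroxydopamine	−	+	−	B12
Isovaleryl carnitine	−	+	−	B12
Pantothenate	−	+	−	B9;B12
Guanine	−	+	−	B9
3-methyl-2-oxobutunoic acid	−	+	−	B9
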