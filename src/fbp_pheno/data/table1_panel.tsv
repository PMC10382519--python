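# Published biochemical phenotypes of the 15 FBP1 missense mutations, v1.
# These are wet-lab measurements consumed as fixture data (expression ratio and
# HSP binding are mutant/WT ratios; aggregation is % of cells with aggregates).
# reported_type is the published category, used only for concordance checks.
mutation	location	activity_call	expression_call	expression_ratio	localization	aggregation_pct	hsp70_ratio	hsp90_ratio	wt_class	mut_class	wt_index	mut_index	structure	reported_type
D119N	metal_binding_site	decrease	no_change	1.4	diffuse	9.4	0.1	0.3	hydrophilic-acidic	hydrophilic-neutral	-3.5	-3.5	beta-strand	1
P120L	linker_metal_substrate	decrease	no_change	1.3	diffuse	8.5	1.1	0.5	hydrophobic-aliphatic	hydrophobic-aliphatic	-1.6	3.8	beta-strand	1
N213K	substrate_binding_site	decrease	no_change	1.1	diffuse	13.3	1.5	0.5	hydrophilic-neutral	hydrophilic-basic	-3.5	-3.9	ND	1
E281K	metal_binding_site	decrease	no_change	0.9	diffuse	33.6	2.4	0.5	hydrophilic-acidic	hydrophilic-basic	-3.5	-3.9	turn	1
R158W	-	decrease	decrease	0.5	aggregated_ER	69.6	7.7	7.8	hydrophilic-basic	hydrophobic-aromatic	-4.5	-0.9	alpha-helix	2
G164D	-	decrease	decrease	0.4	aggregated_ER	71.4	13.7	15.8	hydrophobic-aliphatic	hydrophilic-acidic	-0.4	-3.5	beta-strand	2
G164S	-	decrease	decrease	0.6	aggregated_ER	42.7	6.4	12.2	hydrophobic-aliphatic	hydrophilic-neutral	-0.4	-0.8	beta-strand	2
A177D	-	decrease	decrease	0.2	aggregated_ER	73.9	24.0	37.5	hydrophobic-aliphatic	hydrophilic-acidic	1.8	-3.5	beta-strand	2
F194S	-	decrease	decrease	0.4	aggregated_ER	62.6	15.4	19.8	hydrophobic-aromatic	hydrophilic-neutral	2.8	-0.8	beta-strand	2
G260R	-	decrease	decrease	0.4	aggregated_ER	73.5	18.9	28.2	hydrophobic-aliphatic	hydrophilic-basic	-0.4	-4.5	ND	2
P284R	-	decrease	decrease	0.3	aggregated_ER	57.7	41.2	47.2	hydrophobic-aliphatic	hydrophilic-basic	-1.6	-4.5	alpha-helix	2
G294E	-	decrease	decrease	0.4	aggregated_ER	64.1	64.9	89.9	hydrophobic-aliphatic	hydrophilic-acidic	-0.4	-3.5	ND	2
G294V	-	decrease	decrease	0.6	aggregated_ER	65.9	6.1	3.5	hydrophobic-aliphatic	hydrophobic-aliphatic	-0.4	4.2	ND	2
G207R	-	no_change	no_change	1.0	diffuse	12.7	3.1	3.9	hydrophobic-aliphatic	hydrophilic-basic	-0.4	-4.5	ND	3
V325A	-	no_change	no_change	1.0	diffuse	25.4	2.3	1.3	hydrophobic-aliphatic	hydrophobic-aliphatic	4.2	1.8	alpha-helix	3
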