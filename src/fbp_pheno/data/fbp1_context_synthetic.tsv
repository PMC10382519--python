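# SYNTHETIC precomputed structure context for FBP1 panel positions, v1.
# The published analysis reads these geometries off the porcine FBPase dimer
# crystal structure; this table is a synthetic stand-in encoding the same
# qualitative geometry (site residues at distance 0 by self-inclusion; the
# misfolding-class positions clustering within ~15 A of the substrate pocket;
# G207/V325 distant from every catalytic motif). Distances in Angstrom.
# Users with the real structure can regenerate this table via
# structure_context.context_table_from_structure.
# secondary_structure is transcribed from the published panel (ND = no data).
position	min_dist_substrate	min_dist_metal	min_dist_amp	secondary_structure
119	3.6	0.0	24.5	beta-strand
120	4.8	4.2	23.1	beta-strand
121	4.1	0.0	22.7	ND
122	0.0	4.5	21.9	ND
158	11.5	14.2	18.3	alpha-helix
164	9.8	12.6	20.4	beta-strand
177	12.9	15.8	17.6	beta-strand
194	8.7	11.9	22.8	beta-strand
207	21.6	24.3	28.7	ND
213	0.0	8.9	26.2	ND
214	0.0	9.4	25.8	ND
215	0.0	10.1	24.9	ND
216	0.0	10.8	24.1	ND
260	13.4	16.7	19.5	ND
281	6.2	0.0	27.3	turn
284	10.2	7.8	26.6	alpha-helix
294	14.1	17.2	16.9	ND
325	26.9	29.5	31.2	alpha-helix
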