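# Functional-motif residues of human liver FBPase (FBP1), v1.
# metal and substrate positions are the residues named in the source case
# report (metal: D119, L121, E281; substrate: D122 and the N213-Y216 stretch);
# P120 bridges the metal and substrate sites (linker). The amp list is a
# SYNTHETIC curation sketching the N-terminal allosteric AMP pocket region; it
# is a placeholder, not a database export, and nothing downstream depends on
# its exact membership.
site	position
metal	119
metal	121
metal	281
substrate	122
substrate	213
substrate	214
substrate	215
substrate	216
amp	17
amp	20
amp	27
amp	28
amp	29
amp	31
amp	112
amp	113
amp	140
linker	120
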