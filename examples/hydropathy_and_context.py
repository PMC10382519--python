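"""Inspect the two genotype-side features that drive the Type 2 call.

For each mutation, the classifier asks (1) whether the substitution changes
hydrophobicity — a polarity-class flip or a Kyte-Doolittle shift of at least
theta=3.0 — and (2) whether the residue lies within the pocket radius of the
substrate-binding site.  G164D flips class and sits 9.8 A from the pocket
(Type 2); G207R flips class but is 21.6 A away (Type 3); G294V stays
hydrophobic yet shifts by 4.6 units, enough to count as a change.
"""

from fbp_pheno import build_context, hydrophobicity_change

for wt, pos, mut in [("G", 164, "D"), ("G", 207, "R"), ("G", 294, "V"),
                     ("V", 325, "A")]:
    hc = hydrophobicity_change(wt, mut)
    ctx = build_context(pos)
    print(f"{wt}{pos}{mut}: {hc.describe()}")
    print(f"   d(substrate)={ctx.min_dist_substrate:.1f} A, "
          f"pocket_proximal={ctx.pocket_proximal}, "
          f"pivotal_site={ctx.pivotal_site}, "
          f"secondary={ctx.secondary_structure}")
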