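"""Map a coding-sequence substitution to its protein consequence.

Parses HGVS c. notation, locates the affected codon (ceil(pos/3)) and
translates it before and after the change.  The toy CDS below has glycine at
codon 2, so c.5G>A (GGT -> GAT) is the missense change p.G2D — the same
arithmetic that links c.491G>A to p.G164D on the real FBP1 transcript.
"""

from fbp_pheno import apply_cds_substitution, codon_index, parse_hgvs

print("codon_index(491) =", codon_index(491), "(c.491G>A sits in codon 164)")
print("codon_index(581) =", codon_index(581), "(c.581T>C sits in codon 194)")

cds = "ATGGGTTAA"  # M-G-stop
sub = parse_hgvs("c.5G>A")
out = apply_cds_substitution(cds, sub)
print(f"{sub} on {cds}: {out.kind} -> p.{out.mutation.label}")
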