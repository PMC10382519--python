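"""Recover the index family's FBP1 compound heterozygote from a trio VCF.

Builds the family's genotype configuration (paternal c.491G>A, maternal
c.581T>C, plus filter fodder: a low-depth call, a synonymous SNV and a
database-known variant), writes VCF + PED, then runs germline filtering and
in-trans pair detection.  Exactly one gene should survive with exactly two
variants — the molecular diagnosis.
"""

import tempfile
from pathlib import Path

from fbp_pheno.synthetic_data import index_family_trio, write_trio_ped, write_trio_vcf
from fbp_pheno.variant_filtering import trio_comphet_from_files

d = Path(tempfile.mkdtemp())
write_trio_vcf(index_family_trio(), d / "trio.vcf")
write_trio_ped(d / "trio.ped")

calls, filtered = trio_comphet_from_files(d / "trio.vcf", d / "trio.ped")
for who, table in filtered.items():
    print(f"{who}: {len(table)} variants pass the germline filters")
for c in calls:
    p, m = c.paternal_variant, c.maternal_variant
    print(f"\ncompound het in {c.gene}:")
    print(f"  paternal allele {p.chrom}:{p.pos} {p.ref}>{p.alt} (VAF {p.alt_reads}/{p.depth})")
    print(f"  maternal allele {m.chrom}:{m.pos} {m.ref}>{m.alt} (VAF {m.alt_reads}/{m.depth})")
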