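"""Classify the 15-mutation FBP1 panel and score genotype/phenotype agreement.

Runs the full rule cascade (pivotal site >> misfolding >> default) on the
packaged panel, matches each mutation's biochemical record against the three
phenotype signatures, and prints the per-mutation calls plus the agreement
fraction.  A concordance of 100% means the structural/physicochemical rules
alone predict every wet-lab category.
"""

from fbp_pheno import RunConfig, classify_panel

result = classify_panel(RunConfig())

print(result.report[["mutation", "genotype_type", "phenotype_type",
                     "concordant"]].to_string(index=False))
print(f"\nconcordance: {result.concordance:.0%} "
      f"({int(result.report.concordant.sum())}/{len(result.report)})")
print("\nexample rationale (G164D):")
for line in result.assignments[5].rationale:
    print(" ", line)
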