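# Methods

This note documents the models, rules, thresholds and simulation choices the
package implements, the reasoning behind each default, and what the
synthetic-data tests do and do not demonstrate about real data.

## Germline filtering and compound-het detection

A variant call is *adopted* when depth ≥ `min_depth` (8), variant-supporting
reads ≥ `min_alt_reads` (4), and VAF = alt_reads/depth lies in the
heterozygous window [0.4, 0.6] or at/above the homozygous floor. The
homozygous criterion is nominally "VAF = 1"; exact equality is unrealistic
for finite read counts (a single mismapped read breaks it), so the package
adopts `hom_vaf_min = 0.95`, configurable, as the operational form of that
rule. Exclusions: calls seen only on one strand, indels inside simple
repeats, synonymous SNVs, and variants any population database reports at
AF > `max_known_freq` (0.001). Strand support and repeat membership are
consumed as precomputed boolean annotations (INFO flags); deriving them from
alignments is out of scope. Failures are reported exhaustively, in a fixed
rule order, rather than first-failure — this makes planted-violator fixtures
and real triage logs equally easy to read.

Whether the VAF band applies to the parents as well as the proband is not
fixed by the filter's origin; the default applies it to all samples
(`apply_vaf_to_parents = true`), since parental genotypes feed the phase
logic and deserve the same quality bar.

Compound-het detection is a per-gene enumeration of pairs in trans:
paternal candidate = het in proband and father, absent in mother; maternal
candidate = het in mother and proband, absent in father; every cross pair at
distinct positions is reported, sorted by gene then position, independent of
input order. Genes where the proband carries a surviving homozygous variant
belong to the recessive-homozygous model and are not reported by this
operation. Multi-allelic VCF records are decomposed to biallelic before
filtering; gene assignment comes from an annotation column (variants without
one are ignored with a warning, never silently dropped). Both parents are
required — there is no single-parent mode.

## Coordinate mapping

`c.` numbering starts at the A of the initiator ATG, so residue i spans
coding positions 3i−2…3i and residue index = ⌈pos/3⌉. Substitutions are
applied codon-locally and translated with the standard genetic code (the
table is injectable). The stated reference base is verified against the
supplied CDS; a mismatch raises an error naming both bases, since it almost
always indicates the wrong transcript. Only the simple substitution grammar
is supported; indel/splice/frameshift notation raises an explicit
unsupported-notation error. Three-letter protein notation is normalised to
one-letter.

## Hydropathy and the change predicate

The packaged scale is Kyte–Doolittle (all indices printed in the source
panel are consistent with it), shipped as a versioned TSV together with
polarity-class labels. Classes for the residues that appear in the panel
follow the panel's own usage — notably glycine and proline counted as
hydrophobic-aliphatic; the remaining residues follow standard biochemistry
conventions (C and M with the aliphatics, Y with the aromatics, H basic,
T/Q with the neutral hydrophilics). Rows printed in the panel take
precedence where they exist.

The predicate: a substitution *changes hydrophobicity* iff it flips polarity
class, or |Δ hydropathy| ≥ θ. θ defaults to 3.0, the smallest round value
that counts G294V (|Δ| = 4.6 — both residues hydrophobic, yet treated as a
misfolding-class change) while excluding V325A (|Δ| = 2.4). One consequence
is worth stating plainly: P120L (|Δ| = 5.4, aliphatic→aliphatic) also
satisfies the numeric branch, although the panel's own narrative groups it
with the unchanged-hydrophobicity mutations. No symmetric threshold can
admit G294V and exclude P120L (5.4 > 4.6, same class transition in both).
This has no effect on classification — P120L sits in the metal–substrate
linker and is captured by the Type 1 rule before hydropathy is consulted —
but the predicate value itself is True, and the tests assert that actual
behaviour. The predicate is symmetric in wild-type and mutant, matching how
the hydrophilic→hydrophobic substitution R158W is counted as a change.

## Structure context

Distances are minimum heavy-atom (hydrogens excluded — robust to crystal
structures without them) Euclidean distances between the query residue and
any residue of the target motif, minimised over all chains by default so
inter-subunit pockets of the dimer are captured (a per-chain mode exists).
A query residue inside the target motif is at distance 0 by convention.
Residue numbering maps human positions directly onto the model
(`numbering_offset = 0` by default), reflecting the close human/porcine
FBPase correspondence; an offset is available for other models.

The packaged per-position table (`fbp1_context_synthetic.tsv`) is a
**synthetic stand-in**: the real geometry would be read off the FBPase
dimer crystal structure, which this package does not bundle or fetch. The
table encodes the qualitative geometry the classification relies on — motif
residues at 0 Å, misfolding-class positions within ~8.7–14.1 Å of the
substrate pocket, G207 and V325 at ≥ 21.6 Å — and can be regenerated from a
real model with `context_table_from_structure`. All geometry tests run on
toy structures generated with exact coordinates; real-structure ingestion is
a user-facing path.

`pocket_radius` defaults to 16.0 Å, calibrated once on the 15-mutation
panel: every misfolding-class position is nearer than it, G207/V325 are
farther, and the midpoint of the separating gap (14.1 vs 21.6 Å) is taken.
No printed number exists for "clusters around the substrate binding pocket";
the radius is an artifact decision and is configurable.

The AMP-site residue list is likewise a synthetic curation (N-terminal
allosteric-region positions); no classification rule or test depends on its
membership. Secondary-structure labels are transcribed panel values
(α-helix/β-strand/turn/ND), not computed from coordinates.

## Classification

Genotype cascade, strict precedence: (1) pivotal residue (metal site D119,
L121, E281; substrate site D122, N213–Y216; linker P120) → Type 1;
(2) hydrophobicity change AND pocket-proximal → Type 2; (3) otherwise
Type 3. The precedence order is inferred from E281K, which flips charge
class yet is a catalytic-site mutation — the single most load-bearing
inference in the scheme. Every assignment carries an ordered rationale
trace recording which rule fired and why earlier rules did not.

Phenotype signatures: Type 1 = activity decreased, expression kept, diffuse;
Type 2 = activity decreased, expression decreased, ER-aggregated; Type 3 =
activity kept, expression kept, diffuse; anything else is `unclassified`
(first-class output — the three signatures do not tile the combination
space). When only numeric columns are available, "expression decreased"
means ratio < 0.7 (the panel gap runs 0.6 vs 0.9), "aggregated" means
≥ 40 % of cells with aggregates (gap 33.6 vs 42.7), and "chaperone-elevated"
means both HSP70 and HSP90 ratios ≥ 3.0 (the conjunction keeps the
borderline benign mutant, HSP70 ratio 3.1, below the line). All cutoffs are
configurable in `defaults.yaml`.

Concordance is the fraction of mutations whose genotype-rule category equals
their phenotype-signature category; at defaults the packaged panel scores
15/15.

## Statistics

Pearson r with a two-sided p-value from the exact t transform
(`scipy.stats.pearsonr`); an independent textbook two-pass implementation
lives in the test suite as the oracle, not in the library. Inputs with
fewer than 3 points or zero variance raise rather than returning NaN. No
multiple-testing correction is applied to the two planned panel
correlations. The panel correlations are computed on per-mutation values
(one row per mutation), the only resolution the packaged table has.

FBPase activity: the A340 slope is fitted by least squares and converted by
Beer–Lambert with ε(NADPH, 340 nm) = 6220 M⁻¹cm⁻¹ — the assay protocol does
not print the conversion, so this standard coefficient is adopted and
documented here. Defaults correspond to the published mixture (300 µL,
40 µg protein, 1 cm path). A negative fitted slope is reported as zero
activity with a warning flag. Measured headline activities (e.g. wild-type
4.82, G164D 0.73 mmol/min/mg) are wet-lab measurements consumed as fixture
data, not computable targets.

## Synthetic data

No distributional detail is published for any measurement, so all simulation
distributions are artifact choices:

* **Trios** (PCG64 via `numpy.random.default_rng`, seeded per call; fixed
  seeds give byte-identical VCFs). Het variants draw depth ∈ [20, 60) and
  alt reads at VAF ∈ [0.42, 0.58] (clamped ≥ 4). Background variants are
  assigned genotype configurations that cannot satisfy the trans rule
  (het in all three, single-parent-only, proband-only), so planted pairs
  are the only true positives by construction. Planted violators each break
  exactly one filter rule; a *sole* alt-read violation is arithmetically
  impossible (alt ≤ 3 with VAF ∈ [0.4, 0.6] forces depth ≤ 7, which also
  breaks the depth rule), so the plantable set is the other six rules.
* **Phenotypes**. A latent misfolding severity m ~ N(0,1) enters every
  measurement with weight √|r|, independent unit residuals carry the rest,
  so corr(aggregation, expression) = `target_r` exactly on the z-scale and
  chaperone ratios correlate with aggregation at |target_r| — mirroring the
  causal story (misfolding raises aggregation and chaperone engagement,
  depresses expression). Measurement scales (aggregation 45 ± 13 %,
  expression 0.8 ± 0.25, chaperone ratios 12 ± 4) roughly match the real
  panel's ranges while keeping clamping to [0, 100] / [0, ∞) rare
  (< 10⁻³ per point), so the realised correlation stays within ±0.02 of the
  target in calibration; `noise_sd` (default 0) adds further independent
  noise, attenuating r by 1/(1 + noise_sd²).
* **Toy structures** are built atom-by-atom at stated coordinates and
  emitted as PDB text via gemmi, round-tripping to field precision (10⁻³ Å).

What passing the synthetic tests shows: the filter logic, phase logic,
geometry and statistics are correct against independent oracles and planted
truth. What it does not show: robustness to real exome artifacts
(misalignment, allele-balance skew, annotation errors), to real crystal
structures (missing residues, alternate conformers, numbering offsets), or
to measurement error in real biochemistry — the generators deliberately
model none of those.

## Problem sizes

The shipped test suite runs the truth-recovery loop over 100 trio seeds
(~45 planted events each), the calibration check over 200 phenotype
replicates at n = 1000 for four targets, and geometry oracles on models of
up to ~500 atoms; the acceptance script uses 100 trios and 40 calibration
replicates. The whole suite completes in a few seconds.

## Known limitations

* The packaged structure context is synthetic; conclusions about real
  pocket distances require supplying a real model.
* The AMP motif curation is a placeholder; Type 1 calls currently hinge on
  the metal/substrate/linker residues only.
* Truncating variants (frameshifts, nonsense) are out of scope for
  classification even though misfolding plausibly applies to some of them.
* The pocket radius and phenotype cutoffs are calibrated on a 15-mutation
  panel; they are separations observed in that panel, not learned decision
  boundaries with error estimates.
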