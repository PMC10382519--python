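"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the three data domains the pipeline consumes:

* **Trios** — multi-sample variant tables (writable as VCF v4.2 + PED) with
  planted compound-heterozygous pairs in chosen genes, planted single-rule
  filter violators, and background variants whose genotype configurations can
  never satisfy the in-trans rule.  The planted pairs copy the index family's
  configuration: one allele heterozygous in proband and father only, the
  other in proband and mother only.
* **Phenotype tables** — aggregation %, expression ratio and chaperone-binding
  ratios drawn from a shared-latent bivariate model.  A latent "misfolding
  severity" drives all measurements, which mirrors the causal reading of the
  biochemistry (misfolding raises aggregation and chaperone engagement while
  depressing steady-state expression) and makes the clamping to physical
  ranges explicit.  ``target_r`` is the population correlation between
  aggregation and expression; chaperone ratios correlate with aggregation at
  ``|target_r|``.
* **Toy structures** — PDB-format models with residues at stated coordinates
  and designated site residues, for exercising the geometry code without a
  crystal structure.

All randomness flows through ``numpy.random.default_rng(seed)`` (PCG64), so
fixed seeds give byte-identical artifacts across runs.

No distributional detail for any measurement is published; every simulation
distribution here is an artifact choice, documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .errors import SimulationSpecError
from .variant_filtering import FREQ_INFO_KEYS, SequencedVariant

# ---------------------------------------------------------------------------
# Trio generation
# ---------------------------------------------------------------------------

#: filter rules for which a variant can violate that rule and no other
#: (a sole alt-read violation is arithmetically impossible: alt_reads <= 3
#: with VAF in 0.4-0.6 forces depth <= 7, which also breaks the depth rule)
PLANTABLE_RULES = (
    "depth",
    "vaf",
    "unidirectional",
    "indel_in_repeat",
    "synonymous",
    "known_variant",
)

SAMPLES = ("proband", "father", "mother")


@dataclass(frozen=True)
class TrioSimSpec:
    n_genes: int = 20
    n_background: int = 100
    n_comphet: int = 1
    planted_rules: tuple[str, ...] = PLANTABLE_RULES
    comphet_gene_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_comphet > self.n_genes:
            raise SimulationSpecError("more comphet pairs than genes")
        for r in self.planted_rules:
            if r not in PLANTABLE_RULES:
                raise SimulationSpecError(
                    f"rule {r!r} cannot be planted as a sole violation"
                )
        if self.n_background < 0:
            raise SimulationSpecError("n_background must be >= 0")


@dataclass(frozen=True)
class PlantedCompHet:
    gene: str
    paternal_key: tuple
    maternal_key: tuple


@dataclass(frozen=True)
class TrioTruth:
    """Generated per-sample variant tables plus the planted ground truth."""

    samples: dict[str, dict[tuple, SequencedVariant]]
    planted_comphet: list[PlantedCompHet]
    planted_fail: dict[tuple, str]  # proband variant key -> sole failing rule
    spec: TrioSimSpec


_BASES = np.array(list("ACGT"))

# genotype configurations that can never contribute to an in-trans pair
_SAFE_PATTERNS = (
    ("proband", "father", "mother"),  # het in all three
    ("father",),
    ("mother",),
    ("proband",),
)


def generate_trio(spec: TrioSimSpec) -> TrioTruth:
    """Simulate a trio with planted compound hets and planted rule violators."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"GENE{i:04d}" for i in range(1, spec.n_genes + 1)]
    if spec.comphet_gene_names:
        if len(spec.comphet_gene_names) != spec.n_comphet:
            raise SimulationSpecError("comphet_gene_names length != n_comphet")
        comphet_genes = list(spec.comphet_gene_names)
        background_genes = [g for g in genes if g not in comphet_genes] or comphet_genes
    else:
        comphet_genes = genes[: spec.n_comphet]
        background_genes = genes[spec.n_comphet :] or genes[: spec.n_comphet]

    samples: dict[str, dict[tuple, SequencedVariant]] = {s: {} for s in SAMPLES}
    used_pos: set[tuple[str, int]] = set()

    def fresh_locus(gene: str) -> tuple[str, int]:
        chrom = str(1 + (hash(gene) % 22))
        while True:
            pos = int(rng.integers(1_000, 50_000_000))
            if (chrom, pos) not in used_pos:
                used_pos.add((chrom, pos))
                return chrom, pos

    def het_counts() -> tuple[int, int]:
        depth = int(rng.integers(20, 60))
        alt = int(np.clip(round(depth * rng.uniform(0.42, 0.58)), 4, depth))
        return depth, alt

    def snv_alleles() -> tuple[str, str]:
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        return str(ref), str(alt)

    def place(v: SequencedVariant, carriers: tuple[str, ...]) -> None:
        for s in carriers:
            samples[s][v.key] = v

    planted: list[PlantedCompHet] = []
    for gene in comphet_genes:
        keys = []
        for carriers in (("proband", "father"), ("proband", "mother")):
            chrom, pos = fresh_locus(gene)
            ref, alt = snv_alleles()
            depth, alt_reads = het_counts()
            v = SequencedVariant(
                chrom, pos, ref, alt, depth, alt_reads, gene=gene,
                consequence="missense",
            )
            place(v, carriers)
            keys.append(v.key)
        # keep keys ordered paternal-first regardless of genomic position
        planted.append(PlantedCompHet(gene, keys[0], keys[1]))

    planted_fail: dict[tuple, str] = {}
    for rule in spec.planted_rules:
        gene = background_genes[int(rng.integers(len(background_genes)))]
        chrom, pos = fresh_locus(gene)
        ref, alt = snv_alleles()
        kw: dict = dict(gene=gene, consequence="missense")
        if rule == "depth":
            depth, alt_reads = 7, 4
        elif rule == "vaf":
            depth, alt_reads = 30, 9
        elif rule == "unidirectional":
            depth, alt_reads = het_counts()
            kw["bidirectional"] = False
        elif rule == "indel_in_repeat":
            depth, alt_reads = het_counts()
            alt = ref + "T"
            kw["in_simple_repeat"] = True
            kw["consequence"] = "other"
        elif rule == "synonymous":
            depth, alt_reads = het_counts()
            kw["consequence"] = "synonymous"
        else:  # known_variant
            depth, alt_reads = het_counts()
            kw["known_freqs"] = {"AF_EXAC": 0.002}
        v = SequencedVariant(chrom, pos, ref, alt, depth, alt_reads, **kw)
        place(v, ("proband",))
        planted_fail[v.key] = rule

    for _ in range(spec.n_background):
        gene = background_genes[int(rng.integers(len(background_genes)))]
        chrom, pos = fresh_locus(gene)
        ref, alt = snv_alleles()
        depth, alt_reads = het_counts()
        carriers = _SAFE_PATTERNS[int(rng.integers(len(_SAFE_PATTERNS)))]
        v = SequencedVariant(
            chrom, pos, ref, alt, depth, alt_reads, gene=gene,
            consequence="missense",
        )
        place(v, carriers)

    return TrioTruth(samples, planted, planted_fail, spec)


def index_family_trio() -> TrioTruth:
    """The worked example: the index family's FBP1 compound het plus fodder.

    The proband carries c.491G>A (paternal allele) and c.581T>C (maternal
    allele) heterozygously in FBP1; each parent carries exactly one of them.
    Synthetic coordinates place the variants on contig 9 at positions equal to
    their coding-sequence positions.  A handful of filter-fodder variants
    (low depth, synonymous, database-known) ride along so the filter has work
    to do before the pair detection.
    """
    g164d = SequencedVariant("9", 491, "G", "A", 42, 21, gene="FBP1")
    f194s = SequencedVariant("9", 581, "T", "C", 38, 19, gene="FBP1")
    fodder = [
        (SequencedVariant("9", 1200, "C", "T", 7, 4, gene="FBP1"),
         ("proband",)),
        (SequencedVariant("2", 5000, "A", "G", 50, 25, gene="GENEX",
                          consequence="synonymous"),
         ("proband", "father")),
        (SequencedVariant("3", 7000, "G", "C", 60, 30, gene="GENEY",
                          known_freqs={"AF_1KG": 0.01}),
         ("proband", "mother")),
    ]
    samples: dict[str, dict[tuple, SequencedVariant]] = {s: {} for s in SAMPLES}
    for s in ("proband", "father"):
        samples[s][g164d.key] = g164d
    for s in ("proband", "mother"):
        samples[s][f194s.key] = f194s
    for v, carriers in fodder:
        for s in carriers:
            samples[s][v.key] = v
    return TrioTruth(
        samples=samples,
        planted_comphet=[PlantedCompHet("FBP1", g164d.key, f194s.key)],
        planted_fail={fodder[0][0].key: "depth"},
        spec=TrioSimSpec(n_genes=3, n_background=2, n_comphet=1,
                         planted_rules=("depth",), seed=0),
    )


# ---------------------------------------------------------------------------
# VCF / PED emission
# ---------------------------------------------------------------------------


def write_trio_vcf(truth: TrioTruth, vcf_path: str | Path) -> None:
    """Write the trio as one multi-sample VCF v4.2 (FORMAT GT:DP:AD)."""
    Path(vcf_path).write_text(trio_vcf_text(truth))


def trio_vcf_text(truth: TrioTruth) -> str:
    all_variants: dict[tuple, SequencedVariant] = {}
    for table in truth.samples.values():
        all_variants.update(table)
    contigs = sorted({v.chrom for v in all_variants.values()},
                     key=lambda c: (len(c), c))
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Coding consequence">',
        '##INFO=<ID=UNIDIR,Number=0,Type=Flag,Description="Seen only on one strand">',
        '##INFO=<ID=REPEAT,Number=0,Type=Flag,Description="In simple repeat region">',
    ]
    for k in FREQ_INFO_KEYS:
        lines.append(
            f'##INFO=<ID={k},Number=1,Type=Float,Description="Population AF">'
        )
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(SAMPLES))
    for key in sorted(all_variants, key=lambda k: (len(k[0]), k[0], k[1])):
        v = all_variants[key]
        info = [f"GENE={v.gene}"] if v.gene else []
        info.append(f"CSQ={v.consequence}")
        if not v.bidirectional:
            info.append("UNIDIR")
        if v.in_simple_repeat:
            info.append("REPEAT")
        for k in FREQ_INFO_KEYS:
            if k in v.known_freqs:
                info.append(f"{k}={v.known_freqs[k]:g}")
        cols = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", ".",
                ";".join(info), "GT:DP:AD"]
        for s in SAMPLES:
            if key in truth.samples[s]:
                sv = truth.samples[s][key]
                gt = "1/1" if sv.alt_reads == sv.depth else "0/1"
                cols.append(f"{gt}:{sv.depth}:{sv.depth - sv.alt_reads},{sv.alt_reads}")
            else:
                cols.append(f"0/0:{v.depth}:{v.depth},0")
        lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


def write_trio_ped(ped_path: str | Path, family: str = "FAM1") -> None:
    """Matching PED: affected proband with two unaffected parents."""
    Path(ped_path).write_text(
        f"{family}\tfather\t0\t0\t1\t1\n"
        f"{family}\tmother\t0\t0\t2\t1\n"
        f"{family}\tproband\tfather\tmother\t2\t2\n"
    )


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenotypeSimSpec:
    n: int
    target_r: float
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise SimulationSpecError(f"n must be >= 3, got {self.n}")
        if not -1 <= self.target_r <= 1:
            raise SimulationSpecError(f"|target_r| must be <= 1, got {self.target_r}")
        if self.noise_sd < 0:
            raise SimulationSpecError("noise_sd must be >= 0")


# measurement-scale parameters (artifact choices; see docs/methods.md)
AGG_MEAN, AGG_SD = 45.0, 13.0
EXPR_MEAN, EXPR_SD = 0.8, 0.25
HSP_MEAN, HSP_SD = 12.0, 4.0


def generate_phenotypes(spec: PhenotypeSimSpec) -> tuple[pd.DataFrame, dict]:
    """Phenotype table with population correlation ``target_r`` (agg vs expr).

    A latent severity ``m ~ N(0,1)`` enters every measurement with weight
    sqrt(|r|); independent unit-variance residuals carry the remaining
    variance, so on the z-scale corr(agg, expr) = target_r exactly and
    corr(agg, hsp) = |target_r|.  ``noise_sd`` adds further independent
    measurement noise (attenuating realised correlations by
    1/(1+noise_sd^2)).  Aggregation is clamped to [0, 100] and ratios to
    >= 0; the measurement scales keep clamping rare so the realised r stays
    close to the target.
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.target_r
    a = abs(r)
    w_lat, w_res = np.sqrt(a), np.sqrt(1.0 - a)
    m = rng.standard_normal(spec.n)
    eps = rng.standard_normal((6, spec.n))
    z_agg = w_lat * m + w_res * eps[0]
    z_expr = np.sign(r) * w_lat * m + w_res * eps[1] if r != 0 else eps[1]
    z_h70 = w_lat * m + w_res * eps[2]
    z_h90 = w_lat * m + w_res * eps[3]
    if spec.noise_sd > 0:
        z_agg = z_agg + spec.noise_sd * eps[4]
        z_expr = z_expr + spec.noise_sd * eps[5]
    df = pd.DataFrame(
        {
            "mutation": [f"M{i:04d}" for i in range(1, spec.n + 1)],
            "aggregation_pct": np.clip(AGG_MEAN + AGG_SD * z_agg, 0.0, 100.0),
            "expression_ratio": np.clip(EXPR_MEAN + EXPR_SD * z_expr, 0.0, None),
            "hsp70_ratio": np.clip(HSP_MEAN + HSP_SD * z_h70, 0.0, None),
            "hsp90_ratio": np.clip(HSP_MEAN + HSP_SD * z_h90, 0.0, None),
        }
    )
    truth = {
        "target_r": r,
        "hsp_target_r": a,
        "noise_sd": spec.noise_sd,
        "latent_severity": m,
    }
    return df, truth


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyResidue:
    number: int
    atoms: tuple[tuple[str, tuple[float, float, float]], ...]  # (name, xyz)

    @classmethod
    def point(cls, number: int, xyz: tuple[float, float, float]) -> "ToyResidue":
        return cls(number, (("CA", xyz),))


@dataclass(frozen=True)
class ToyStructureSpec:
    residues: tuple[ToyResidue, ...]
    site_residues: dict[str, tuple[int, ...]] = field(default_factory=dict)
    chain: str = "A"

    def __post_init__(self) -> None:
        if not self.residues:
            raise SimulationSpecError("toy structure needs at least one residue")
        nums = [r.number for r in self.residues]
        if len(set(nums)) != len(nums):
            raise SimulationSpecError(f"duplicate residue numbers in {nums}")


def generate_toy_structure(spec: ToyStructureSpec) -> tuple[gemmi.Structure, str]:
    """Build a gemmi model from explicit coordinates and emit PDB text.

    The emitted text round-trips through ``structure_context.parse_structure``
    to the same coordinates at PDB field precision (1e-3 A).
    """
    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model("1")
    chain = gemmi.Chain(spec.chain)
    for tr in sorted(spec.residues, key=lambda r: r.number):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(tr.number, " ")
        for atom_name, (x, y, z) in tr.atoms:
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element(atom_name[0])
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st, st.make_pdb_string()


def linear_strand(n: int, spacing: float = 3.8) -> ToyStructureSpec:
    """n single-atom residues along x at the canonical CA-CA spacing."""
    return ToyStructureSpec(
        residues=tuple(
            ToyResidue.point(i, (spacing * (i - 1), 0.0, 0.0))
            for i in range(1, n + 1)
        ),
        site_residues={"site": (1,)},
    )
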