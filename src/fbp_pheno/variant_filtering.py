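"""Germline candidate-variant filtering and trio compound-het detection.

The filter reproduces the exome adoption/exclusion criteria used to nominate
recessive candidates in the index family: a call is adopted when its depth is
>= 8, it is supported by >= 4 variant reads, and its variant allele fraction
(VAF) is consistent with a germline genotype (0.4-0.6 heterozygous, ~1
homozygous); it is excluded when seen only on one strand, when it is an indel
inside a simple repeat, when it is synonymous, or when any population
database reports it at allele frequency > 0.001.

Compound-heterozygote detection then looks, gene by gene, for a pair of
surviving variants in trans: one heterozygous in proband and father only, the
other heterozygous in proband and mother only — the configuration that
identified c.491G>A (paternal) with c.581T>C (maternal) in FBP1.

Strand support and simple-repeat membership are consumed as precomputed
annotations (INFO flags); recomputing them from alignments is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from .errors import IncompletePedigreeError, UndefinedVafError

CONSEQUENCES = ("synonymous", "missense", "nonsense", "splice", "other")

#: canonical order in which failing rules are reported
RULE_ORDER = (
    "depth",
    "alt_reads",
    "vaf",
    "unidirectional",
    "indel_in_repeat",
    "synonymous",
    "known_variant",
)


@dataclass(frozen=True)
class SequencedVariant:
    """One called variant in one sample (the unit the filter rules act on)."""

    chrom: str
    pos: int  # 1-based (VCF convention)
    ref: str
    alt: str
    depth: int
    alt_reads: int
    bidirectional: bool = True
    in_simple_repeat: bool = False
    consequence: str = "missense"
    known_freqs: Mapping[str, float] = field(default_factory=dict)
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if not 0 <= self.alt_reads <= self.depth:
            raise ValueError(
                f"alt_reads {self.alt_reads} outside [0, depth={self.depth}]"
            )
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass(frozen=True)
class FilterConfig:
    min_depth: int = 8
    min_alt_reads: int = 4
    het_vaf_window: tuple[float, float] = (0.4, 0.6)
    hom_vaf_min: float = 0.95
    max_known_freq: float = 0.001
    apply_vaf_to_parents: bool = True
    exclude_unidirectional: bool = True
    exclude_indel_in_repeat: bool = True
    exclude_synonymous: bool = True
    exclude_known: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.het_vaf_window
        if not (0 <= lo <= hi <= 1):
            raise ValueError(f"het_vaf_window must be ordered within [0,1]: {lo},{hi}")
        if self.min_depth < 0 or self.min_alt_reads < 0 or self.max_known_freq < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class FilterDecision:
    passed: bool
    reasons: tuple[str, ...]  # every failing rule, in RULE_ORDER


@dataclass(frozen=True)
class CompHetCall:
    """A candidate compound heterozygote: two variants in trans in one gene."""

    gene: str
    paternal_variant: SequencedVariant
    maternal_variant: SequencedVariant
    proband_genotypes: tuple[str, str] = ("het", "het")

    def __post_init__(self) -> None:
        pv, mv = self.paternal_variant, self.maternal_variant
        if (pv.chrom, pv.pos) == (mv.chrom, mv.pos):
            raise ValueError("compound het requires two distinct positions")


def vaf(v: SequencedVariant) -> float:
    """Variant allele fraction, alt_reads / depth."""
    if v.depth == 0:
        raise UndefinedVafError(f"VAF undefined at zero depth for {v.key}")
    return v.alt_reads / v.depth


def zygosity(v: SequencedVariant, cfg: FilterConfig = FilterConfig()) -> str:
    """'het', 'hom' or 'ambiguous' from the VAF bands of ``cfg``."""
    f = vaf(v)
    lo, hi = cfg.het_vaf_window
    if lo <= f <= hi:
        return "het"
    if f >= cfg.hom_vaf_min:
        return "hom"
    return "ambiguous"


def passes_germline_filters(
    v: SequencedVariant, cfg: FilterConfig = FilterConfig(), check_vaf: bool = True
) -> FilterDecision:
    """Apply every adoption and exclusion rule; report all failures.

    Reasons are exhaustive (every failing rule, not just the first) and
    ordered by :data:`RULE_ORDER`, which makes planted-violator fixtures easy
    to debug.  ``check_vaf=False`` supports the configurable question of
    whether the VAF band is enforced in the parents.
    """
    failing = set()
    if v.depth < cfg.min_depth:
        failing.add("depth")
    if v.alt_reads < cfg.min_alt_reads:
        failing.add("alt_reads")
    if check_vaf and v.depth > 0:
        lo, hi = cfg.het_vaf_window
        f = vaf(v)
        if not (lo <= f <= hi or f >= cfg.hom_vaf_min):
            failing.add("vaf")
    if cfg.exclude_unidirectional and not v.bidirectional:
        failing.add("unidirectional")
    if cfg.exclude_indel_in_repeat and v.is_indel and v.in_simple_repeat:
        failing.add("indel_in_repeat")
    if cfg.exclude_synonymous and v.consequence == "synonymous":
        failing.add("synonymous")
    if cfg.exclude_known and any(
        f > cfg.max_known_freq for f in v.known_freqs.values()
    ):
        failing.add("known_variant")
    reasons = tuple(r for r in RULE_ORDER if r in failing)
    return FilterDecision(passed=not reasons, reasons=reasons)


def filter_sample(
    variants: Iterable[SequencedVariant],
    cfg: FilterConfig = FilterConfig(),
    is_parent: bool = False,
) -> dict[tuple, SequencedVariant]:
    """Keyed table of the variants that survive all filters in one sample."""
    check_vaf = cfg.apply_vaf_to_parents or not is_parent
    return {
        v.key: v
        for v in variants
        if passes_germline_filters(v, cfg, check_vaf=check_vaf).passed
    }


def detect_compound_het(
    proband: Mapping[tuple, SequencedVariant] | Iterable[SequencedVariant],
    father: Mapping[tuple, SequencedVariant] | Iterable[SequencedVariant] | None,
    mother: Mapping[tuple, SequencedVariant] | Iterable[SequencedVariant] | None,
    cfg: FilterConfig = FilterConfig(),
) -> list[CompHetCall]:
    """Enumerate in-trans heterozygous pairs per gene across a full trio.

    For each gene, every pair (a, b) is reported where ``a`` is heterozygous
    in proband and father and absent from the mother, and ``b`` is
    heterozygous in proband and mother and absent from the father.  Output is
    sorted by gene, then paternal position, then maternal position, and is
    independent of input row order.  Genes in which the proband carries a
    homozygous surviving variant are left to a recessive-homozygous model and
    not reported here.  Both parents are required: there is no silent
    single-parent mode.
    """
    if father is None or mother is None:
        raise IncompletePedigreeError(
            "compound-het detection needs both parental samples"
        )
    prob = _as_table(proband)
    dad = _as_table(father)
    mom = _as_table(mother)

    by_gene: dict[str, list[SequencedVariant]] = {}
    for v in prob.values():
        if v.gene is None:
            warnings.warn(
                f"variant {v.key} has no gene annotation; ignored by comphet",
                stacklevel=2,
            )
            continue
        by_gene.setdefault(v.gene, []).append(v)

    calls: list[CompHetCall] = []
    for gene, variants in by_gene.items():
        if any(zygosity(v, cfg) == "hom" for v in variants):
            continue
        paternal = [
            v
            for v in variants
            if zygosity(v, cfg) == "het"
            and v.key in dad
            and zygosity(dad[v.key], cfg) == "het"
            and v.key not in mom
        ]
        maternal = [
            v
            for v in variants
            if zygosity(v, cfg) == "het"
            and v.key in mom
            and zygosity(mom[v.key], cfg) == "het"
            and v.key not in dad
        ]
        for a in paternal:
            for b in maternal:
                if (a.chrom, a.pos) != (b.chrom, b.pos):
                    calls.append(CompHetCall(gene, a, b))
    calls.sort(
        key=lambda c: (
            c.gene,
            c.paternal_variant.chrom,
            c.paternal_variant.pos,
            c.maternal_variant.chrom,
            c.maternal_variant.pos,
        )
    )
    return calls


def _as_table(x) -> dict[tuple, SequencedVariant]:
    if isinstance(x, Mapping):
        return dict(x)
    return {v.key: v for v in x}


# ---------------------------------------------------------------------------
# VCF / PED ingestion
# ---------------------------------------------------------------------------

#: INFO keys under which population allele frequencies are read
FREQ_INFO_KEYS = ("AF_1KG", "AF_ESP", "AF_HGVD", "AF_EXAC")


def read_trio_vcf(
    vcf_path: str | Path,
) -> dict[str, dict[tuple, SequencedVariant]]:
    """Read a multi-sample VCF into per-sample keyed variant tables.

    Expects FORMAT ``GT:DP:AD`` and the INFO annotations the synthetic
    generator writes (``GENE``, ``CSQ``, ``UNIDIR``/``REPEAT`` flags and the
    :data:`FREQ_INFO_KEYS` frequencies).  Multi-allelic records are decomposed
    so each alt allele becomes an independent :class:`SequencedVariant`.  A
    sample carries a variant when it has at least one supporting read.
    """
    from cyvcf2 import VCF  # deferred: keeps import cost off library users

    reader = VCF(str(vcf_path))
    samples = list(reader.samples)
    tables: dict[str, dict[tuple, SequencedVariant]] = {s: {} for s in samples}
    for rec in reader:
        gene = rec.INFO.get("GENE")
        csq = rec.INFO.get("CSQ") or "other"
        bidir = rec.INFO.get("UNIDIR") is None
        in_repeat = rec.INFO.get("REPEAT") is not None
        # htslib stores INFO floats in single precision; round-trip through
        # %.6g so 0.002 reads back as 0.002, not 0.0020000000949
        freqs = {
            k: float(f"{float(rec.INFO.get(k)):.6g}")
            for k in FREQ_INFO_KEYS
            if rec.INFO.get(k) is not None
        }
        depths = rec.format("DP")
        ad = rec.format("AD")
        for ai, alt in enumerate(rec.ALT):
            for si, sample in enumerate(samples):
                alt_reads = int(ad[si][1 + ai])
                if alt_reads <= 0:
                    continue
                tables[sample][(rec.CHROM, rec.POS, rec.REF, alt)] = SequencedVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    depth=int(depths[si][0] if depths.ndim > 1 else depths[si]),
                    alt_reads=alt_reads,
                    bidirectional=bidir,
                    in_simple_repeat=in_repeat,
                    consequence=csq,
                    known_freqs=freqs,
                    gene=gene,
                )
    return tables


@dataclass(frozen=True)
class Pedigree:
    proband: str
    father: str
    mother: str


def read_ped(ped_path: str | Path) -> Pedigree:
    """Resolve proband/father/mother sample ids from a PED file.

    The proband is the affected individual (phenotype 2) with both parents
    recorded; anything else is an incomplete pedigree.
    """
    rows = []
    for line in Path(ped_path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rows.append(line.split())
    for fam, iid, fid, mid, _sex, pheno in rows:
        if pheno == "2" and fid != "0" and mid != "0":
            return Pedigree(proband=iid, father=fid, mother=mid)
    raise IncompletePedigreeError(
        f"{ped_path}: no affected individual with both parents recorded"
    )


def trio_comphet_from_files(
    vcf_path: str | Path, ped_path: str | Path, cfg: FilterConfig = FilterConfig()
) -> tuple[list[CompHetCall], dict[str, dict[tuple, SequencedVariant]]]:
    """Full file-level pipeline: VCF + PED -> filtered tables -> comphet calls."""
    ped = read_ped(ped_path)
    tables = read_trio_vcf(vcf_path)
    for who in (ped.proband, ped.father, ped.mother):
        if who not in tables:
            raise IncompletePedigreeError(f"sample {who!r} missing from VCF")
    filtered = {
        ped.proband: filter_sample(tables[ped.proband].values(), cfg),
        ped.father: filter_sample(tables[ped.father].values(), cfg, is_parent=True),
        ped.mother: filter_sample(tables[ped.mother].values(), cfg, is_parent=True),
    }
    calls = detect_compound_het(
        filtered[ped.proband], filtered[ped.father], filtered[ped.mother], cfg
    )
    return calls, filtered
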