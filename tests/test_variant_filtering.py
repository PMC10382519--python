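"""Germline filter rules and trio compound-het detection."""

import itertools
import random

import pytest

from fbp_pheno.errors import IncompletePedigreeError, UndefinedVafError
from fbp_pheno.variant_filtering import (
    FilterConfig,
    SequencedVariant,
    detect_compound_het,
    passes_germline_filters,
    read_ped,
    vaf,
    zygosity,
)

CFG = FilterConfig()


def sv(pos=100, depth=30, alt_reads=15, **kw):
    kw.setdefault("chrom", "1")
    kw.setdefault("ref", "A")
    kw.setdefault("alt", "G")
    return SequencedVariant(pos=pos, depth=depth, alt_reads=alt_reads, **kw)


@pytest.mark.parametrize(
    "alt_reads,depth,expected", [(15, 30, 0.5), (30, 30, 1.0), (4, 8, 0.5)]
)
def test_vaf_arithmetic(alt_reads, depth, expected):
    assert vaf(sv(depth=depth, alt_reads=alt_reads)) == expected


def test_vaf_undefined_at_zero_depth():
    with pytest.raises(UndefinedVafError):
        vaf(sv(depth=0, alt_reads=0))


@pytest.mark.parametrize(
    "variant,reasons",
    [
        (sv(depth=7, alt_reads=4), ("depth",)),
        (sv(depth=100, alt_reads=50), ()),
        (sv(consequence="synonymous"), ("synonymous",)),
        (sv(known_freqs={"AF_EXAC": 0.002}), ("known_variant",)),
        (sv(known_freqs={"AF_EXAC": 0.001}), ()),  # boundary: not > 0.001
        (sv(depth=30, alt_reads=9), ("vaf",)),  # 0.30: neither het nor hom band
        (sv(depth=30, alt_reads=25), ("vaf",)),  # 0.83: between the bands
        (sv(depth=30, alt_reads=29), ()),  # 0.97 >= 0.95 counts as homozygous
        (sv(bidirectional=False), ("unidirectional",)),
        (sv(alt="AT", in_simple_repeat=True), ("indel_in_repeat",)),
        (sv(alt="AT", in_simple_repeat=False), ()),  # indel outside repeats kept
    ],
)
def test_filter_reason_codes(variant, reasons):
    d = passes_germline_filters(variant, CFG)
    assert d.reasons == reasons
    assert d.passed == (not reasons)


def test_reasons_are_exhaustive_and_ordered():
    v = sv(depth=7, alt_reads=1, bidirectional=False, consequence="synonymous")
    d = passes_germline_filters(v, CFG)
    assert d.reasons == ("depth", "alt_reads", "vaf", "unidirectional", "synonymous")


def test_filter_monotone_in_depth_and_alt_reads():
    """Scaling up read support at fixed VAF never introduces depth/alt failures."""
    for depth in range(8, 60, 4):
        alt = depth // 2
        d = passes_germline_filters(sv(depth=depth, alt_reads=alt), CFG)
        assert "depth" not in d.reasons and "alt_reads" not in d.reasons


def trio_tables(*variants_with_carriers):
    tables = {"proband": {}, "father": {}, "mother": {}}
    for v, carriers in variants_with_carriers:
        for c in carriers:
            tables[c][v.key] = v
    return tables


def test_trans_configuration_is_called():
    a = sv(pos=100, gene="FBP1")
    b = sv(pos=200, gene="FBP1")
    t = trio_tables((a, ("proband", "father")), (b, ("proband", "mother")))
    calls = detect_compound_het(t["proband"], t["father"], t["mother"])
    assert len(calls) == 1
    assert calls[0].paternal_variant.key == a.key
    assert calls[0].maternal_variant.key == b.key


def test_cis_configuration_is_not_called():
    """Two variants inherited from the same parent violate the trans rule."""
    a = sv(pos=100, gene="FBP1")
    b = sv(pos=200, gene="FBP1")
    t = trio_tables((a, ("proband", "father")), (b, ("proband", "father")))
    assert detect_compound_het(t["proband"], t["father"], t["mother"]) == []


def test_homozygous_proband_gene_not_reported():
    a = sv(pos=100, gene="FBP1")
    b = sv(pos=200, gene="FBP1")
    hom = sv(pos=300, gene="FBP1", depth=30, alt_reads=30)
    t = trio_tables(
        (a, ("proband", "father")), (b, ("proband", "mother")), (hom, ("proband",))
    )
    assert detect_compound_het(t["proband"], t["father"], t["mother"]) == []


def test_missing_parent_raises():
    with pytest.raises(IncompletePedigreeError):
        detect_compound_het({}, None, {})


def test_unannotated_gene_warns_and_is_ignored():
    a = sv(pos=100, gene=None)
    t = trio_tables((a, ("proband", "father")))
    with pytest.warns(UserWarning, match="no gene annotation"):
        assert detect_compound_het(t["proband"], t["father"], t["mother"]) == []


def _comphet_oracle(prob, dad, mom, cfg=CFG):
    """Brute force: test the trans condition over all ordered het pairs per gene."""
    calls = set()
    hom_genes = {
        v.gene for v in prob.values() if zygosity(v, cfg) == "hom" and v.gene
    }
    for a, b in itertools.permutations(prob.values(), 2):
        if a.gene is None or a.gene != b.gene or a.gene in hom_genes:
            continue
        if (a.chrom, a.pos) == (b.chrom, b.pos):
            continue
        if (
            zygosity(a, cfg) == "het"
            and a.key in dad and zygosity(dad[a.key], cfg) == "het"
            and a.key not in mom
            and zygosity(b, cfg) == "het"
            and b.key in mom and zygosity(mom[b.key], cfg) == "het"
            and b.key not in dad
        ):
            calls.add((a.gene, a.key, b.key))
    return calls


def test_matches_bruteforce_oracle_and_order_invariant():
    """Randomised trios: grouped detection equals the all-pairs oracle, and the
    output is independent of input row order."""
    rng = random.Random(42)
    for _ in range(30):
        tables = {"proband": {}, "father": {}, "mother": {}}
        for i in range(rng.randint(5, 60)):
            gene = f"G{rng.randint(1, 6)}"
            depth = rng.randint(10, 50)
            hom = rng.random() < 0.15
            alt = depth if hom else max(4, round(depth * rng.uniform(0.4, 0.6)))
            v = sv(pos=1000 + i, gene=gene, depth=depth, alt_reads=alt)
            carriers = rng.sample(
                ["proband", "father", "mother"], rng.randint(1, 3)
            )
            for c in carriers:
                tables[c][v.key] = v
        calls = detect_compound_het(tables["proband"], tables["father"], tables["mother"])
        got = {(c.gene, c.paternal_variant.key, c.maternal_variant.key) for c in calls}
        want = _comphet_oracle(tables["proband"], tables["father"], tables["mother"])
        assert got == want
        # order invariance: feed shuffled lists instead of dicts
        rows = list(tables["proband"].values())
        rng.shuffle(rows)
        calls2 = detect_compound_het(rows, tables["father"], tables["mother"])
        assert [
            (c.gene, c.paternal_variant.key, c.maternal_variant.key) for c in calls2
        ] == [(c.gene, c.paternal_variant.key, c.maternal_variant.key) for c in calls]


def test_read_ped_resolves_trio(tmp_path):
    p = tmp_path / "fam.ped"
    p.write_text(
        "FAM1\tdad\t0\t0\t1\t1\nFAM1\tmum\t0\t0\t2\t1\nFAM1\tkid\tdad\tmum\t2\t2\n"
    )
    ped = read_ped(p)
    assert (ped.proband, ped.father, ped.mother) == ("kid", "dad", "mum")


def test_read_ped_requires_affected_with_parents(tmp_path):
    p = tmp_path / "fam.ped"
    p.write_text("FAM1\tkid\t0\t0\t2\t2\n")
    with pytest.raises(IncompletePedigreeError):
        read_ped(p)
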