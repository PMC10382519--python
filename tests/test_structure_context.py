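"""Geometry on PDB-format models and the packaged structure-context table."""

import itertools

import numpy as np
import pytest

from fbp_pheno.errors import (
    ContextUnavailableError,
    MissingResidueError,
    StructureParseError,
)
from fbp_pheno.structure_context import (
    build_context,
    context_table_from_structure,
    min_distance,
    parse_structure,
)
from fbp_pheno.synthetic_data import (
    ToyResidue,
    ToyStructureSpec,
    generate_toy_structure,
    linear_strand,
)


def test_toy_structure_round_trips_coordinates():
    spec = ToyStructureSpec(
        residues=(
            ToyResidue.point(1, (0.0, 0.0, 0.0)),
            ToyResidue.point(2, (5.0, 0.0, 0.0)),
            ToyResidue.point(3, (10.0, 0.0, 0.0)),
        )
    )
    st, text = generate_toy_structure(spec)
    st2 = parse_structure(text)
    for res, tr in zip(st2[0]["A"], spec.residues):
        for atom, (_, xyz) in zip(res, tr.atoms):
            assert atom.pos.x == pytest.approx(xyz[0], abs=1e-3)
            assert atom.pos.y == pytest.approx(xyz[1], abs=1e-3)
            assert atom.pos.z == pytest.approx(xyz[2], abs=1e-3)


def test_collinear_toy_distances():
    _, text = generate_toy_structure(
        ToyStructureSpec(
            residues=(
                ToyResidue.point(1, (0, 0, 0)),
                ToyResidue.point(2, (5, 0, 0)),
                ToyResidue.point(3, (10, 0, 0)),
            )
        )
    )
    st = parse_structure(text)
    assert min_distance(st, 1, [2]) == pytest.approx(5.0)
    assert min_distance(st, 1, [3]) == pytest.approx(10.0)


def test_three_four_five_triangle():
    _, text = generate_toy_structure(
        ToyStructureSpec(
            residues=(ToyResidue.point(1, (0, 0, 0)), ToyResidue.point(2, (3, 4, 0)))
        )
    )
    st = parse_structure(text)
    assert min_distance(st, 1, [2]) == pytest.approx(5.0)


def test_self_inclusion_is_zero():
    st, _ = generate_toy_structure(linear_strand(5))
    assert min_distance(st, 2, [2, 4]) == 0.0


def test_strand_distances_monotone_in_sequence_position():
    """With the site at residue 1, distance grows along an ideal strand."""
    st, _ = generate_toy_structure(linear_strand(20))
    d = [min_distance(st, i, [1]) for i in range(2, 21)]
    assert all(b > a for a, b in zip(d, d[1:]))


def test_missing_residue_raises():
    st, _ = generate_toy_structure(linear_strand(3))
    with pytest.raises(MissingResidueError):
        min_distance(st, 99, [1])


def test_truncated_atom_line_raises_with_line_number():
    _, text = generate_toy_structure(linear_strand(2))
    lines = text.splitlines()
    idx = next(i for i, l in enumerate(lines) if l.startswith("ATOM"))
    lines[idx] = lines[idx][:40]
    with pytest.raises(StructureParseError) as exc:
        parse_structure("\n".join(lines))
    assert exc.value.line_number == idx + 1


def test_hetatm_ligand_group_retrievable():
    _, text = generate_toy_structure(linear_strand(3))
    lig = (
        "HETATM   99  P   F6P A 900      10.000   3.000   4.000  1.00  0.00"
        "           P"
    )
    lines = text.splitlines()
    end = next(i for i, l in enumerate(lines) if l.startswith("END"))
    lines.insert(end, lig)
    st = parse_structure("\n".join(lines))
    # residue 3 sits at (7.6, 0, 0); ligand P at (10, 3, 4)
    expect = np.sqrt(2.4**2 + 3**2 + 4**2)
    assert min_distance(st, 3, "F6P") == pytest.approx(expect, abs=1e-3)


def test_min_distance_matches_allpairs_oracle_and_symmetry():
    """Random multi-atom model <= 500 atoms: exhaustive numpy oracle agreement."""
    rng = np.random.default_rng(11)
    residues = []
    coords = {}
    for num in range(1, 41):
        atoms = []
        for j in range(rng.integers(1, 13)):
            xyz = tuple(np.round(rng.uniform(-40, 40, 3), 3))
            atoms.append((f"C{j}" if j else "CA", xyz))
        residues.append(ToyResidue(num, tuple(atoms)))
        coords[num] = np.array([a[1] for a in atoms])
    st, text = generate_toy_structure(ToyStructureSpec(residues=tuple(residues)))
    st = parse_structure(text)

    def oracle(q, targets):
        qa = coords[q]
        ta = np.vstack([coords[t] for t in targets])
        return float(np.min(np.linalg.norm(qa[:, None] - ta[None], axis=2)))

    for q, t in [(1, [40]), (5, [10, 20, 30]), (17, [2]), (33, [4, 8])]:
        assert min_distance(st, q, t) == pytest.approx(oracle(q, t), abs=2e-3)
    # symmetry for singleton target sets
    for a, b in itertools.combinations([1, 9, 25], 2):
        assert min_distance(st, a, [b]) == pytest.approx(
            min_distance(st, b, [a]), abs=1e-9
        )


def test_chain_policy_minimises_over_chains():
    """The all-chain minimum picks up the closer subunit of a dimer."""
    _, text_a = generate_toy_structure(linear_strand(3))
    lines = text_a.splitlines()
    moved = []
    for l in lines:
        if l.startswith("ATOM"):
            # second chain: same residues shifted +2 A in y, chain id B
            y = float(l[38:46]) + 2.0
            moved.append(l[:21] + "B" + l[22:38] + f"{y:8.3f}" + l[46:])
    end = next(i for i, l in enumerate(lines) if l.startswith("END"))
    st = parse_structure("\n".join(lines[:end] + moved + lines[end:]))
    # query residue 3 in chain A vs site residue 1: chain B copy is not closer,
    # but restricting to chain B must differ from the global minimum
    d_all = min_distance(st, 3, [1])
    d_b = min_distance(st, 3, [1], chain="B")
    assert d_all == pytest.approx(7.6, abs=1e-3)
    assert d_b == pytest.approx(7.6, abs=1e-3)  # within-B same geometry
    assert min_distance(st, 1, [3]) == d_all


def test_build_context_pivotal_and_proximity(sites, ctx_table):
    ctx119 = build_context(119, table=ctx_table, sites=sites)
    assert ctx119.pivotal_site == "metal"
    assert ctx119.min_dist_metal == 0.0
    ctx164 = build_context(164, table=ctx_table, sites=sites)
    assert ctx164.pivotal_site is None and ctx164.pocket_proximal
    ctx325 = build_context(325, table=ctx_table, sites=sites)
    assert not ctx325.pocket_proximal
    assert build_context(281, table=ctx_table, sites=sites).secondary_structure == "turn"


def test_build_context_unknown_position_raises(sites, ctx_table):
    with pytest.raises(ContextUnavailableError):
        build_context(999, table=ctx_table, sites=sites)


def test_misfolding_positions_closer_than_distant_positions(panel, ctx_table):
    """Pocket geometry separates the misfolding class from the distant class."""
    t2 = panel[panel.reported_type == 2]
    t3 = panel[panel.reported_type == 3]
    pos = lambda m: int(m[1:-1])
    d2 = [ctx_table.loc[pos(m), "min_dist_substrate"] for m in t2.mutation]
    d3 = [ctx_table.loc[pos(m), "min_dist_substrate"] for m in t3.mutation]
    assert max(d2) < min(d3)


def test_context_table_from_structure_round_trip(sites):
    """Recomputing a context table from a model reproduces direct min_distance."""
    spec = ToyStructureSpec(
        residues=tuple(ToyResidue.point(i, (3.0 * i, 0, 0)) for i in range(115, 130)),
    )
    st, _ = generate_toy_structure(spec)
    table = context_table_from_structure(st, [123, 125], sites=sites)
    assert table.loc[123, "min_dist_substrate"] == pytest.approx(
        min_distance(st, 123, sites.site_positions("substrate"))
    )
    assert table.loc[125, "min_dist_metal"] == pytest.approx(
        min_distance(st, 125, sites.site_positions("metal"))
    )
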