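"""Structural context of mutated residues on the FBPase dimer.

Each polypeptide chain of liver FBPase carries a substrate-binding site, a
divalent-metal site and an allosteric AMP site; the enzyme works as a
homotetramer of two intimate dimers.  The geometric question behind the
mutation categories is how close a mutated residue sits to those motifs: the
catalytic-site class sits *in* them, the misfolding class clusters around the
substrate-binding pocket, and the likely-benign class is distant from
everything.

Two sources can answer it: a coordinate model in PDB format (the published
analysis uses the porcine FBPase dimer, which the human enzyme closely
matches), or the packaged per-position distance table
(``data/fbp1_context_synthetic.tsv``, a synthetic stand-in encoding the same
qualitative geometry for the 15-mutation panel).  Distances are minima over
heavy atoms, by default minimised over all chains so inter-subunit pockets
are captured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import gemmi
import pandas as pd

from .errors import ContextUnavailableError, MissingResidueError, StructureParseError

DEFAULT_POCKET_RADIUS = 16.0  # Angstrom; see docs/methods.md for calibration

SECONDARY_STRUCTURE_LABELS = ("alpha-helix", "beta-strand", "turn", "ND")


@dataclass(frozen=True)
class SiteAnnotation:
    """Functional-motif membership: site name -> sorted residue positions."""

    pivotal_residues: dict[str, tuple[int, ...]]
    linker_residues: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for name, positions in self.pivotal_residues.items():
            if not positions:
                raise ValueError(f"site {name!r} has no residues")
            if list(positions) != sorted(positions):
                raise ValueError(f"site {name!r} positions must be sorted")

    def pivotal_hit(self, position: int) -> str | None:
        """Name of the motif containing ``position`` (linker counts), or None."""
        for name, positions in self.pivotal_residues.items():
            if position in positions:
                return name
        if position in self.linker_residues:
            return "linker"
        return None

    def site_positions(self, name: str) -> tuple[int, ...]:
        return self.pivotal_residues[name]


@dataclass(frozen=True)
class StructureContext:
    """Distance/motif/secondary-structure features of one protein position."""

    position: int
    min_dist_substrate: float
    min_dist_metal: float
    min_dist_amp: float
    pocket_radius: float
    pivotal_site: str | None
    secondary_structure: str = "ND"

    def __post_init__(self) -> None:
        for d in (self.min_dist_substrate, self.min_dist_metal, self.min_dist_amp):
            if d < 0:
                raise ValueError("distances must be >= 0")
        if self.secondary_structure not in SECONDARY_STRUCTURE_LABELS:
            raise ValueError(
                f"unknown secondary structure {self.secondary_structure!r}"
            )

    @property
    def pocket_proximal(self) -> bool:
        return self.min_dist_substrate <= self.pocket_radius

    @property
    def pivotal_site_hit(self) -> bool:
        return self.pivotal_site is not None


def load_site_annotations(path=None) -> SiteAnnotation:
    """Packaged (or user-supplied) site-annotation table."""
    df = _read_packaged_tsv("site_annotations.tsv", path)
    sites: dict[str, list[int]] = {}
    linker: list[int] = []
    for row in df.itertuples():
        if row.site == "linker":
            linker.append(int(row.position))
        else:
            sites.setdefault(row.site, []).append(int(row.position))
    return SiteAnnotation(
        pivotal_residues={k: tuple(sorted(v)) for k, v in sites.items()},
        linker_residues=tuple(sorted(linker)),
    )


def load_context_table(path=None) -> pd.DataFrame:
    """Packaged per-position distance/secondary-structure table, indexed by position."""
    df = _read_packaged_tsv("fbp1_context_synthetic.tsv", path)
    return df.set_index("position")


def _read_packaged_tsv(name: str, path) -> pd.DataFrame:
    if path is None:
        ref = resources.files("fbp_pheno.data") / name
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t", comment="#")
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# PDB-format models
# ---------------------------------------------------------------------------


def parse_structure(source: str | Path) -> gemmi.Structure:
    """Parse PDB-format text (or a file path) into a gemmi structure.

    gemmi itself is permissive, so coordinate records are validated first and
    a malformed ATOM/HETATM line raises :class:`StructureParseError` carrying
    its 1-based line number.
    """
    if isinstance(source, Path) or (
        "\n" not in str(source) and Path(str(source)).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    _validate_coordinate_records(text)
    st = gemmi.read_pdb_string(text)
    st.setup_entities()
    return st


def _validate_coordinate_records(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise StructureParseError(
                f"line {lineno}: truncated coordinate record", lineno
            )
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
            int(line[22:26])
        except ValueError as exc:
            raise StructureParseError(
                f"line {lineno}: unparseable coordinate fields ({exc})", lineno
            ) from None


def _residue_atoms(
    st: gemmi.Structure,
    *,
    positions: set[int] | None = None,
    ligand_name: str | None = None,
    chain: str | None = None,
) -> list[gemmi.Atom]:
    atoms = []
    model = st[0]
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            if positions is not None and res.seqid.num not in positions:
                continue
            if ligand_name is not None and res.name != ligand_name:
                continue
            for atom in res:
                if not atom.is_hydrogen():
                    atoms.append(atom)
    return atoms


def min_distance(
    st: gemmi.Structure,
    query_position: int,
    target: list[int] | tuple[int, ...] | set[int] | str,
    chain: str | None = None,
) -> float:
    """Minimum heavy-atom distance (A) from a residue to a site or ligand.

    ``target`` is either a collection of residue positions or a ligand residue
    name (HETATM group).  ``chain=None`` minimises over all chains, capturing
    inter-subunit pockets in the dimer.  By convention a query residue that is
    itself part of the target set is at distance 0.
    """
    if isinstance(target, str):
        target_atoms = _residue_atoms(st, ligand_name=target, chain=chain)
    else:
        tset = set(int(p) for p in target)
        if query_position in tset:
            return 0.0
        target_atoms = _residue_atoms(st, positions=tset, chain=chain)
    query_atoms = _residue_atoms(st, positions={query_position}, chain=chain)
    if not query_atoms:
        raise MissingResidueError(
            f"residue {query_position} not found in structure"
            + (f" chain {chain}" if chain else "")
        )
    if not target_atoms:
        raise MissingResidueError(f"target {target!r} not found in structure")
    best = math.inf
    for qa in query_atoms:
        for ta in target_atoms:
            d = qa.pos.dist(ta.pos)
            if d < best:
                best = d
    return best


def build_context(
    position: int,
    *,
    model: gemmi.Structure | None = None,
    table: pd.DataFrame | None = None,
    sites: SiteAnnotation | None = None,
    radius: float = DEFAULT_POCKET_RADIUS,
    numbering_offset: int = 0,
) -> StructureContext:
    """Assemble the :class:`StructureContext` for one protein position.

    Distances come from ``model`` when given, else from ``table`` (defaulting
    to the packaged synthetic table).  ``numbering_offset`` shifts protein
    numbering onto the model's residue numbering (model position =
    protein position + offset).
    """
    sites = sites or load_site_annotations()
    pivotal = sites.pivotal_hit(position)
    if model is not None:
        mpos = position + numbering_offset
        if not _residue_atoms(model, positions={mpos}):
            raise MissingResidueError(f"residue {mpos} not found in structure")
        dists = {}
        for site in ("substrate", "metal", "amp"):
            site_pos = [
                p + numbering_offset for p in sites.pivotal_residues.get(site, ())
            ]
            # a motif entirely absent from the model (e.g. a fragment) is
            # infinitely far, not an error; a missing query residue still raises
            if site_pos and _residue_atoms(model, positions=set(site_pos)):
                dists[site] = min_distance(model, mpos, site_pos)
            else:
                dists[site] = math.inf
        sec = "ND"
        if table is not None and position in table.index:
            sec = str(table.loc[position, "secondary_structure"])
    else:
        if table is None:
            table = load_context_table()
        if position not in table.index:
            raise ContextUnavailableError(
                f"position {position} absent from both model and context table"
            )
        row = table.loc[position]
        dists = {
            "substrate": float(row["min_dist_substrate"]),
            "metal": float(row["min_dist_metal"]),
            "amp": float(row["min_dist_amp"]),
        }
        sec = str(row["secondary_structure"])
    return StructureContext(
        position=position,
        min_dist_substrate=dists["substrate"],
        min_dist_metal=dists["metal"],
        min_dist_amp=dists["amp"],
        pocket_radius=radius,
        pivotal_site=pivotal,
        secondary_structure=sec,
    )


def context_table_from_structure(
    st: gemmi.Structure,
    positions: list[int],
    sites: SiteAnnotation | None = None,
    numbering_offset: int = 0,
) -> pd.DataFrame:
    """Recompute the packaged-style context table from a coordinate model."""
    sites = sites or load_site_annotations()
    rows = []
    for pos in positions:
        ctx = build_context(
            pos, model=st, sites=sites, numbering_offset=numbering_offset
        )
        rows.append(
            {
                "position": pos,
                "min_dist_substrate": ctx.min_dist_substrate,
                "min_dist_metal": ctx.min_dist_metal,
                "min_dist_amp": ctx.min_dist_amp,
                "secondary_structure": ctx.secondary_structure,
            }
        )
    return pd.DataFrame(rows).set_index("position")
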