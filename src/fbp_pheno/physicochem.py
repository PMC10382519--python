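"""Kyte-Doolittle hydropathy lookups and the hydrophobicity-change predicate.

A substitution "changes hydrophobicity" when it either flips the residue
between the hydrophobic and hydrophilic classes (e.g. G164D,
aliphatic -> acidic) or, within one polarity class, shifts the hydropathy
index by at least ``theta`` (default 3.0).  The second branch exists for
substitutions like G294V: glycine (-0.4) and valine (4.2) are both
hydrophobic, yet the 4.6-unit hydropathy jump is treated as a change because
it plausibly perturbs folding.  The predicate is symmetric in wild-type and
mutant, matching how hydrophilic->hydrophobic substitutions (R158W) are
counted as changes.

The scale and class labels ship as a versioned TSV (``data/kyte_doolittle.tsv``)
and are injectable for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd


@dataclass(frozen=True)
class AminoAcidProperties:
    one_letter: str
    hydropathy: float
    class_label: str

    @property
    def is_hydrophobic(self) -> bool:
        return self.class_label.startswith("hydrophobic")


@dataclass(frozen=True)
class HydropathyChange:
    """All hydropathy-derived features of one substitution."""

    wt: AminoAcidProperties
    mut: AminoAcidProperties
    theta: float

    @property
    def delta(self) -> float:
        """mut index minus wt index (exact difference of scale values)."""
        return self.mut.hydropathy - self.wt.hydropathy

    @property
    def polarity_flip(self) -> bool:
        """True when the substitution crosses the hydrophobic/hydrophilic divide."""
        return self.wt.is_hydrophobic != self.mut.is_hydrophobic

    @property
    def is_change(self) -> bool:
        return self.polarity_flip or abs(self.delta) >= self.theta

    def describe(self) -> str:
        return (
            f"{self.wt.one_letter}({self.wt.hydropathy:+.1f},{self.wt.class_label})"
            f"->{self.mut.one_letter}({self.mut.hydropathy:+.1f},{self.mut.class_label})"
            f" delta={self.delta:+.1f}"
            f" flip={self.polarity_flip} change={self.is_change}"
        )


DEFAULT_THETA = 3.0


def load_scale(path=None) -> dict[str, AminoAcidProperties]:
    """Load the packaged (or a user-supplied) hydropathy/class table."""
    if path is None:
        ref = resources.files("fbp_pheno.data") / "kyte_doolittle.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    scale = {
        row.aa: AminoAcidProperties(row.aa, float(row.hydropathy), row.class_label)
        for row in df.itertuples()
    }
    if len(scale) != 20:
        raise ValueError(f"scale table must cover the 20 standard residues, got {len(scale)}")
    return scale


_SCALE: dict[str, AminoAcidProperties] | None = None


def _default_scale() -> dict[str, AminoAcidProperties]:
    global _SCALE
    if _SCALE is None:
        _SCALE = load_scale()
    return _SCALE


def properties(aa: str, scale=None) -> AminoAcidProperties:
    scale = scale or _default_scale()
    try:
        return scale[aa.upper()]
    except KeyError:
        raise KeyError(f"unknown amino acid code {aa!r}") from None


def hydropathy(aa: str, scale=None) -> float:
    """Kyte-Doolittle index of a one-letter amino-acid code."""
    return properties(aa, scale).hydropathy


def hydrophobicity_change(
    wt: str, mut: str, theta: float = DEFAULT_THETA, scale=None
) -> HydropathyChange:
    """Hydropathy features of a wt->mut substitution (see module docstring)."""
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    return HydropathyChange(properties(wt, scale), properties(mut, scale), theta)
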