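"""Correlation statistics over the mutation panel and the FBPase activity utility.

Two relationships anchor the misfolding story and are recomputed here from
the panel measurements: protein expression falls as the fraction of cells
with FBP1 aggregates rises (strong negative correlation), and chaperone
binding (HSP70, HSP90) rises with aggregation (positive correlations).
p-values come from the exact t transform of Pearson's r; no multiple-testing
correction is applied to these two planned tests.

The activity utility converts an NADPH A340 time course into a specific
FBPase activity via Beer-Lambert: slope(A/min) / (epsilon * l) is the molar
NADPH production rate, scaled by reaction volume and normalised to protein
mass.  Defaults match the published assay (300 uL mixture, 40 ug protein,
epsilon(NADPH, 340 nm) = 6220 /M/cm, 1 cm path).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int

    @property
    def r_squared(self) -> float:
        return self.r * self.r


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided exact-t p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise DegenerateInputError(f"need at least 3 points, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in an input vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=n)


def aggregation_expression_correlation(panel: pd.DataFrame) -> CorrelationResult:
    """Aggregation %% vs expression ratio across the mutation panel."""
    return pearson(panel["aggregation_pct"], panel["expression_ratio"])


def hsp_correlations(panel: pd.DataFrame) -> dict[str, CorrelationResult]:
    """HSP70 and HSP90 binding ratios vs aggregation %%, one result each."""
    return {
        "hsp70": pearson(panel["hsp70_ratio"], panel["aggregation_pct"]),
        "hsp90": pearson(panel["hsp90_ratio"], panel["aggregation_pct"]),
    }


def load_panel(path=None) -> pd.DataFrame:
    """The packaged mutation-panel measurement table (or a user-supplied one)."""
    if path is None:
        ref = resources.files("fbp_pheno.data") / "table1_panel.tsv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t", comment="#")
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# FBPase activity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivityMeasurement:
    """One NADP-coupled spectrophotometric time course."""

    times_min: tuple[float, ...]
    a340: tuple[float, ...]
    path_length_cm: float = 1.0
    reaction_volume_l: float = 300e-6
    protein_mass_mg: float = 0.040
    extinction_coefficient: float = 6220.0  # NADPH at 340 nm, /M/cm

    def __post_init__(self) -> None:
        if len(self.times_min) < 2 or len(self.times_min) != len(self.a340):
            raise ValueError("need >= 2 matched (time, A340) points")
        if any(b <= a for a, b in zip(self.times_min, self.times_min[1:])):
            raise ValueError("times must be strictly increasing")
        for name in ("path_length_cm", "reaction_volume_l", "protein_mass_mg",
                     "extinction_coefficient"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ActivityResult:
    activity_mmol_min_mg: float
    slope_a_per_min: float
    clamped_negative: bool


def fbpase_activity(m: ActivityMeasurement) -> ActivityResult:
    """Specific FBPase activity (mmol NADPH / min / mg protein).

    The A340 series is fitted by least squares; a negative fitted slope is
    physically meaningless for this coupled assay and is reported as zero
    activity with a warning flag.
    """
    t = np.asarray(m.times_min, dtype=float)
    a = np.asarray(m.a340, dtype=float)
    design = np.column_stack([t, np.ones_like(t)])
    (slope, _), *_ = np.linalg.lstsq(design, a, rcond=None)
    slope = float(slope)
    clamped = slope < 0
    if clamped:
        warnings.warn("negative A340 slope clamped to zero activity", stacklevel=2)
        eff = 0.0
    else:
        eff = slope
    molar_rate = eff / (m.extinction_coefficient * m.path_length_cm)  # mol/L/min
    mol_per_min = molar_rate * m.reaction_volume_l
    mmol_per_min_mg = mol_per_min * 1e3 / m.protein_mass_mg
    return ActivityResult(
        activity_mmol_min_mg=mmol_per_min_mg,
        slope_a_per_min=slope,
        clamped_negative=clamped,
    )
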