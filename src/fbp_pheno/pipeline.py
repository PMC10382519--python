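"""End-to-end orchestration: panel classification, statistics, provenance.

`run_panel` stitches the stages together the way the study's results section
does: parse each panel mutation, build its hydropathy and structure-context
features, classify it with the genotype cascade, classify its biochemical
record against the phenotype signatures, then score concordance and recompute
the two correlation analyses.  Outputs are deterministic for a given config
and carry a provenance manifest (config hash, input hashes, per-stage row
counts).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classifier import (
    PhenotypeRecord,
    PhenotypeThresholds,
    TypeAssignment,
    classify_genotype,
    classify_phenotype,
    concordance,
)
from .coordinate_mapping import parse_hgvs
from .phenotype_stats import (
    aggregation_expression_correlation,
    hsp_correlations,
    load_panel,
)
from .physicochem import DEFAULT_THETA, hydrophobicity_change, load_scale
from .structure_context import (
    DEFAULT_POCKET_RADIUS,
    build_context,
    load_context_table,
    load_site_annotations,
)


@dataclass(frozen=True)
class RunConfig:
    panel_path: str | None = None  # None -> packaged panel
    context_path: str | None = None
    sites_path: str | None = None
    scale_path: str | None = None
    theta: float = DEFAULT_THETA
    pocket_radius: float = DEFAULT_POCKET_RADIUS
    numbering_offset: int = 0
    thresholds: PhenotypeThresholds = field(default_factory=PhenotypeThresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thr = raw.get("phenotype", {})
        return cls(
            theta=raw.get("hydropathy", {}).get("theta", DEFAULT_THETA),
            pocket_radius=raw.get("structure", {}).get(
                "pocket_radius", DEFAULT_POCKET_RADIUS
            ),
            numbering_offset=raw.get("structure", {}).get("numbering_offset", 0),
            thresholds=PhenotypeThresholds(
                expression_decreased_below=thr.get("expression_decreased_below", 0.7),
                aggregated_pct_min=thr.get("aggregated_pct_min", 40.0),
                hsp_elevated_min=thr.get("hsp_elevated_min", 3.0),
            ),
        )

    def digest(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PanelResult:
    assignments: list[TypeAssignment]
    report: pd.DataFrame
    concordance: float
    correlations: dict[str, dict]
    manifest: dict


def classify_panel(config: RunConfig = RunConfig()) -> PanelResult:
    """Classify every panel mutation on both sides and score agreement."""
    panel = load_panel(config.panel_path)
    sites = load_site_annotations(config.sites_path)
    ctx_table = load_context_table(config.context_path)
    scale = load_scale(config.scale_path)

    pairs = []
    for row in panel.itertuples():
        m = parse_hgvs(f"p.{row.mutation}")
        hc = hydrophobicity_change(m.wt_aa, m.mut_aa, config.theta, scale)
        ctx = build_context(
            m.position,
            table=ctx_table,
            sites=sites,
            radius=config.pocket_radius,
            numbering_offset=config.numbering_offset,
        )
        assignment = classify_genotype(m, sites, ctx, hc)
        record = PhenotypeRecord(
            mutation=row.mutation,
            activity_call=row.activity_call,
            expression_ratio=float(row.expression_ratio),
            localization=row.localization,
            aggregation_pct=float(row.aggregation_pct),
            hsp70_ratio=float(row.hsp70_ratio),
            hsp90_ratio=float(row.hsp90_ratio),
        )
        pairs.append((assignment, classify_phenotype(record, config.thresholds)))

    frac, report = concordance(pairs)

    agg_expr = aggregation_expression_correlation(panel)
    hsp = hsp_correlations(panel)
    correlations = {
        "aggregation_vs_expression": _corr_dict(agg_expr),
        "hsp70_vs_aggregation": _corr_dict(hsp["hsp70"]),
        "hsp90_vs_aggregation": _corr_dict(hsp["hsp90"]),
    }

    manifest = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "inputs": {
            "panel": _input_hash(config.panel_path, "table1_panel.tsv"),
            "context": _input_hash(config.context_path, "fbp1_context_synthetic.tsv"),
            "sites": _input_hash(config.sites_path, "site_annotations.tsv"),
            "scale": _input_hash(config.scale_path, "kyte_doolittle.tsv"),
        },
        "row_counts": {
            "panel_mutations": int(len(panel)),
            "assignments": len(pairs),
            "concordant": int(report["concordant"].sum()),
        },
    }
    return PanelResult(
        assignments=[a for a, _ in pairs],
        report=report,
        concordance=frac,
        correlations=correlations,
        manifest=manifest,
    )


def run_panel(config: RunConfig, out_dir: str | Path) -> PanelResult:
    """`classify_panel` plus report files under ``out_dir``."""
    result = classify_panel(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.report.to_csv(out / "classification.tsv", sep="\t", index=False)
    (out / "statistics.json").write_text(
        json.dumps(result.correlations, indent=2, sort_keys=True) + "\n"
    )
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
    )
    rationale = []
    for a in result.assignments:
        rationale.append(f"{a.mutation.label} -> Type {a.category}")
        rationale.extend(f"  {line}" for line in a.rationale)
    (out / "rationale.txt").write_text("\n".join(rationale) + "\n")
    return result


def _corr_dict(c) -> dict:
    return {"r": c.r, "r_squared": c.r_squared, "p_value": c.p_value, "n": c.n}


def _input_hash(path: str | None, packaged_name: str) -> dict:
    if path is None:
        ref = resources.files("fbp_pheno.data") / packaged_name
        data = ref.read_bytes()
        name = f"packaged:{packaged_name}"
    else:
        data = Path(path).read_bytes()
        name = str(path)
    return {"source": name, "sha256": hashlib.sha256(data).hexdigest()[:16]}
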