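"""Summary tables, bubble-grid figure data, and the end-to-end pipeline.

The bubble grid mirrors the conventional presentation of stratified rule
results: one row per risk factor, one column per stratum, circle size
encoding confidence and colour intensity encoding lift (blue for the
absence->stable direction, red for presence->worsening), with
non-significant (lift <= 1) or undefined cells greyed out.  The figure is
a convenience; the tidy CSV carrying every cell -- defined or not -- is
the contract-stable output.

``run_pipeline`` wires the whole analysis together:

    simulate (or read CSV) -> assemble -> outcomes -> thresholds ->
    binarize -> staging -> mine -> report

writing the eligibility report, thresholds, exposure table, outcome table,
rules CSV, optional figures, and a manifest (config hash, seed, package
versions) into the output directory.  Given the same config and seed the
run is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .association_rules import RULES, mine_all
from .ckd_staging import SCHEMES, add_staging_columns, stratum_labels
from .cohort_assembly import assemble, baseline_frame
from .errors import ConfigError, PipelineError
from .renal_metrics import outcome_table
from .risk_binarization import (
    binarize,
    compute_thresholds,
    default_factor_specs,
)
from .synthetic_cohort import (
    ANALYTE_COLUMNS,
    CohortProfile,
    read_cohort_csv,
    simulate_cohort,
    write_cohort_csv,
)

logger = logging.getLogger("dkd_arules")

_CATEGORICAL_SUMMARY = (
    ("sex_male", lambda df: df["sex"] == "male"),
    ("urine_protein_ge1plus", lambda df: df["dipstick_protein"].isin(("1+", "2+", "3+"))),
    ("retinopathy", lambda df: df["retinopathy"].map(lambda v: bool(v) if not pd.isna(v) else np.nan)),
)


def baseline_table(baseline: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD per continuous variable and percentages for categoricals.

    One row per variable with columns variable, kind, n, mean, sd, percent;
    the mean/sd columns are NaN for categorical rows and vice versa.  SD is
    reported as NaN for a single subject and the table is empty-but-typed
    for an empty cohort.
    """
    rows: List[dict] = []
    n = len(baseline)
    rows.append({"variable": "n_subjects", "kind": "count", "n": n,
                 "mean": np.nan, "sd": np.nan, "percent": np.nan})
    if n > 0:
        continuous = ["age", "baseline_egfr"] + [
            c for c in ANALYTE_COLUMNS if c != "serum_creatinine"
        ]
        for col in continuous:
            if col not in baseline.columns:
                continue
            vals = baseline[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            rows.append(
                {
                    "variable": col,
                    "kind": "continuous",
                    "n": int(vals.size),
                    "mean": float(np.mean(vals)) if vals.size else np.nan,
                    "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
                    "percent": np.nan,
                }
            )
        for name, fn in _CATEGORICAL_SUMMARY:
            try:
                vals = fn(baseline)
            except KeyError:
                continue
            known = vals.notna()
            count = int(vals[known].astype(bool).sum())
            rows.append(
                {
                    "variable": name,
                    "kind": "categorical",
                    "n": int(known.sum()),
                    "mean": np.nan,
                    "sd": np.nan,
                    "percent": 100.0 * count / known.sum() if known.any() else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["variable", "kind", "n", "mean", "sd", "percent"])


def tidy_bubble_cells(results: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """Per-cell bubble attributes for one scheme (every cell, incl. undefined)."""
    if scheme not in SCHEMES:
        raise ConfigError(f"unknown stratification scheme {scheme!r}")
    sub = results[results["scheme"] == scheme].copy()
    sub["defined"] = np.isfinite(sub["confidence"].to_numpy(dtype=float))
    sub["grayed"] = ~sub["significant"].to_numpy(dtype=bool)
    sub["size"] = sub["confidence"]
    sub["color_intensity"] = sub["lift"]
    return sub.reset_index(drop=True)


def render_bubble_grid(
    results: pd.DataFrame,
    scheme: str,
    figure_path: Optional[Path] = None,
    csv_path: Optional[Path] = None,
) -> pd.DataFrame:
    """Write the bubble-grid figure and/or its tidy CSV for one scheme.

    Returns the tidy cell frame.  The figure has one panel per rule
    direction; circle area tracks confidence, colour intensity tracks
    lift, and cells with lift <= 1 (or undefined) are greyed out.
    """
    cells = tidy_bubble_cells(results, scheme)
    if csv_path is not None:
        cells.to_csv(csv_path, index=False)
    if figure_path is not None:
        _draw_bubble_grid(cells, scheme, figure_path)
    return cells


def _draw_bubble_grid(cells: pd.DataFrame, scheme: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    strata = stratum_labels(scheme)
    factors = list(dict.fromkeys(cells["factor"]))
    fig, axes = plt.subplots(
        1, 2, figsize=(2.0 + 1.1 * len(strata) * 2, 1.0 + 0.33 * len(factors)),
        sharey=True,
    )
    palettes = {RULES[0]: plt.cm.Blues, RULES[1]: plt.cm.Reds}
    for ax, rule in zip(np.atleast_1d(axes), RULES):
        sub = cells[cells["rule"] == rule]
        for _, row in sub.iterrows():
            if not row["defined"]:
                continue
            x = strata.index(row["stratum"])
            y = factors.index(row["factor"])
            lift = row["lift"]
            if row["grayed"]:
                color = (0.75, 0.75, 0.75, 0.8)
            else:
                color = palettes[rule](min(1.0, 0.3 + 0.35 * (lift - 1.0)))
            ax.scatter(x, y, s=40 + 900 * row["confidence"] ** 2, c=[color],
                       edgecolors="none")
        ax.set_xticks(range(len(strata)))
        ax.set_xticklabels(strata, rotation=45, ha="right", fontsize=7)
        ax.set_xlim(-0.7, len(strata) - 0.3)
        ax.set_title(rule, fontsize=9)
        ax.invert_yaxis() if not ax.yaxis_inverted() else None
    ax0 = np.atleast_1d(axes)[0]
    ax0.set_yticks(range(len(factors)))
    ax0.set_yticklabels(factors, fontsize=7)
    fig.suptitle(f"Association rules by {scheme}", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


DEFAULT_CONFIG: Dict = {
    "cohort": {"kind": "general", "source": "simulate", "profile": {}, "csv_path": None},
    "followup_years": 5,
    "percentile": 20,
    "schemes": list(SCHEMES),
    "seed": 0,
    "output_dir": "dkd_arules_out",
    "figures": False,
    "write_cohort": False,
    "bootstrap_ci": False,
}


def load_config(source) -> Dict:
    """Merge a YAML path / mapping over the documented defaults."""
    if source is None:
        user: Mapping = {}
    elif isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source)
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if key not in cfg:
            raise ConfigError(f"unknown config key {key!r}")
        if key == "cohort":
            for ck, cv in value.items():
                if ck not in cfg["cohort"]:
                    raise ConfigError(f"unknown cohort config key {ck!r}")
                cfg["cohort"][ck] = cv
        else:
            cfg[key] = value
    if cfg["percentile"] not in (10, 20):
        raise ConfigError("percentile must be 10 or 20")
    for scheme in cfg["schemes"]:
        if scheme not in SCHEMES:
            raise ConfigError(f"unknown stratification scheme {scheme!r}")
    return cfg


def _config_hash(cfg: Mapping) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _load_cohort(cfg: Dict) -> pd.DataFrame:
    cc = cfg["cohort"]
    if cc["source"] == "csv":
        if not cc.get("csv_path"):
            raise ConfigError("cohort.source is 'csv' but cohort.csv_path is unset")
        return read_cohort_csv(cc["csv_path"])
    if cc["source"] != "simulate":
        raise ConfigError(f"unknown cohort source {cc['source']!r}")
    kind = cc.get("kind", "general")
    overrides = dict(cc.get("profile") or {})
    overrides.setdefault("seed", cfg["seed"])
    overrides.setdefault("followup_years", cfg["followup_years"])
    if kind == "worker":
        profile = CohortProfile.worker(**overrides)
    elif kind == "general":
        profile = CohortProfile.general(**overrides)
    else:
        raise ConfigError(f"unknown cohort kind {kind!r}")
    return simulate_cohort(profile)


def run_pipeline(config=None, seed: Optional[int] = None) -> Dict:
    """Run the full analysis described by ``config`` (dict or YAML path).

    Returns the manifest dict (also written as ``manifest.json``).  On any
    stage failure the partially written outputs are removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def _write_csv(frame: pd.DataFrame, name: str) -> None:
        path = outdir / name
        frame.to_csv(path, index=False)
        written.append(path)

    stage = "setup"
    try:
        stage = "load_cohort"
        visits = _load_cohort(cfg)
        logger.info("%s: %d visit rows", stage, len(visits))
        if cfg["write_cohort"] and cfg["cohort"]["source"] == "simulate":
            path = outdir / "cohort.csv"
            write_cohort_csv(visits, path)
            written.append(path)

        stage = "assemble"
        kind = cfg["cohort"].get("kind", "general")
        series, report = assemble(visits, kind, cfg["followup_years"])
        logger.info("%s: %d -> %d subjects", stage, report.n_input_subjects, report.n_final)
        path = outdir / "eligibility.json"
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        written.append(path)

        stage = "outcomes"
        outcomes = outcome_table(series, kind, cfg["followup_years"])
        _write_csv(outcomes, "outcomes.csv")

        stage = "baseline"
        base = baseline_frame(series)
        _write_csv(baseline_table(base), "baseline_table.csv")

        stage = "thresholds"
        specs = default_factor_specs(cfg["percentile"])
        thresholds = compute_thresholds(base, specs, cfg["percentile"])
        _write_csv(thresholds, "thresholds.csv")

        stage = "binarize"
        flags = binarize(base, thresholds, specs)
        exposure = base[["subject_id", "sex", "dipstick_protein", "retinopathy",
                         "baseline_egfr"]].merge(flags, on="subject_id")
        exposure = exposure.merge(
            outcomes[["subject_id", "outcome", "worst_pct_change",
                      "egfr_2y_change_pct", "slope_stratum"]],
            on="subject_id",
        )
        stage = "staging"
        exposure = add_staging_columns(exposure)
        _write_csv(exposure, "exposure.csv")

        stage = "mine"
        rules = mine_all(exposure, specs, cfg["schemes"])
        _write_csv(rules, "rules.csv")

        stage = "report"
        for scheme in cfg["schemes"]:
            csv_path = outdir / f"bubble_{scheme}.csv"
            fig_path = outdir / f"bubble_{scheme}.png" if cfg["figures"] else None
            render_bubble_grid(rules, scheme, fig_path, csv_path)
            written.append(csv_path)
            if fig_path is not None:
                written.append(fig_path)

        stage = "manifest"
        manifest = {
            "config": cfg,
            "config_sha256": _config_hash(cfg),
            "seed": cfg["seed"],
            "package_version": __version__,
            "versions": {"numpy": np.__version__, "pandas": pd.__version__},
            "n_final": report.n_final,
            "outputs": sorted(str(p.name) for p in written),
        }
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
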