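"""Modified KDIGO CKD risk categories and analysis stratification schemes.

The KDIGO heat map crosses GFR grades (G1..G5) with albuminuria grades; in
screening data without quantitative albuminuria the dipstick urine-protein
grade stands in, dichotomized as negative/trace vs >= 1+.  The default
category grid therefore has two columns: negative/trace follows the KDIGO
A1 column and >= 1+ the A2 column, with G3b..G5 saturating at very high
risk.  The grid is an explicit mapping and can be overridden (e.g. for
users who want >= 1+ to behave like A3).

Stratification schemes used by the rule mining:

* ``overall`` -- one stratum;
* ``risk4`` -- the four risk categories;
* ``risk2_retinopathy`` -- low/moderate vs high/very-high crossed with
  retinopathy status;
* ``risk2_retinopathy_slope`` -- the above crossed with the 2-year eGFR
  change bins.

Subjects missing a label a scheme needs (retinopathy, slope) are left
unassigned and drop out of that scheme only.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError
from .renal_metrics import SLOPE_STRATA

GFR_GRADES = ("G1", "G2", "G3a", "G3b", "G4", "G5")
# lower bound of each grade (mL/min/1.73 m^2), lower-inclusive
_GRADE_LOWER = {"G1": 90.0, "G2": 60.0, "G3a": 45.0, "G3b": 30.0, "G4": 15.0, "G5": 0.0}

PROTEINURIA_CLASSES = ("neg_trace", "ge1plus")

RISK_CATEGORIES = ("low", "moderate", "high", "very_high")

#: default category per (gfr_grade, proteinuria_class)
DEFAULT_RISK_MAP: Dict[Tuple[str, str], str] = {
    ("G1", "neg_trace"): "low",
    ("G2", "neg_trace"): "low",
    ("G3a", "neg_trace"): "moderate",
    ("G3b", "neg_trace"): "high",
    ("G4", "neg_trace"): "very_high",
    ("G5", "neg_trace"): "very_high",
    ("G1", "ge1plus"): "moderate",
    ("G2", "ge1plus"): "moderate",
    ("G3a", "ge1plus"): "high",
    ("G3b", "ge1plus"): "very_high",
    ("G4", "ge1plus"): "very_high",
    ("G5", "ge1plus"): "very_high",
}

SCHEMES = ("overall", "risk4", "risk2_retinopathy", "risk2_retinopathy_slope")

_RISK2 = {"low": "low_moderate", "moderate": "low_moderate",
          "high": "high_veryhigh", "very_high": "high_veryhigh"}
_RETINOPATHY_LABELS = ("no_retinopathy", "retinopathy")


def gfr_grade(egfr) -> str:
    """KDIGO GFR grade; bins are lower-inclusive (60 -> G2, 59.99 -> G3a)."""
    eg = np.asarray(egfr, dtype=float)
    if np.any(eg[np.isfinite(eg)] <= 0):
        raise ValueError("eGFR must be > 0")
    scalar = eg.ndim == 0
    eg = np.atleast_1d(eg)
    out = np.empty(eg.shape, dtype=object)
    out[:] = None
    # assign from G5 upward so the highest applicable lower bound wins
    for grade in reversed(GFR_GRADES):
        out[np.isfinite(eg) & (eg >= _GRADE_LOWER[grade])] = grade
    if scalar:
        return out[0]
    return out


def proteinuria_class(dipstick) -> str:
    """Dichotomize a dipstick grade: negative/trace vs >= 1+."""
    arr = np.asarray(dipstick, dtype=object)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.where(
        pd.isna(arr), None,
        np.where(np.isin(arr, ("negative", "trace")), "neg_trace", "ge1plus"),
    )
    if scalar:
        return out[0]
    return out


def risk_category(
    grade: str,
    pclass: str,
    risk_map: Optional[Mapping[Tuple[str, str], str]] = None,
) -> str:
    """CKD risk category for one (GFR grade, proteinuria class) cell."""
    risk_map = DEFAULT_RISK_MAP if risk_map is None else risk_map
    try:
        return risk_map[(grade, pclass)]
    except KeyError:
        raise ConfigError(f"risk map has no cell for ({grade!r}, {pclass!r})")


def collapse_risk2(category: str) -> str:
    """Merge the four risk categories into low/moderate vs high/very-high."""
    return _RISK2[category]


def add_staging_columns(
    exposure: pd.DataFrame,
    risk_map: Optional[Mapping[Tuple[str, str], str]] = None,
) -> pd.DataFrame:
    """Derive gfr_grade, proteinuria_class and risk_category columns."""
    out = exposure.copy()
    grades = gfr_grade(out["baseline_egfr"].to_numpy(dtype=float))
    pclasses = proteinuria_class(out["dipstick_protein"].to_numpy(dtype=object))
    out["gfr_grade"] = grades
    out["proteinuria_class"] = pclasses
    out["risk_category"] = [
        risk_category(g, p, risk_map) if g is not None and p is not None else None
        for g, p in zip(grades, pclasses)
    ]
    return out


def stratum_labels(scheme: str) -> List[str]:
    """Canonical ordered stratum labels of a scheme."""
    if scheme == "overall":
        return ["all"]
    if scheme == "risk4":
        return list(RISK_CATEGORIES)
    if scheme == "risk2_retinopathy":
        return [
            f"{r2}|{ret}"
            for r2 in ("low_moderate", "high_veryhigh")
            for ret in _RETINOPATHY_LABELS
        ]
    if scheme == "risk2_retinopathy_slope":
        return [
            f"{r2}|{ret}|{sl}"
            for r2 in ("low_moderate", "high_veryhigh")
            for ret in _RETINOPATHY_LABELS
            for sl in SLOPE_STRATA
        ]
    raise ConfigError(f"unknown stratification scheme {scheme!r}")


def assign_strata(exposure: pd.DataFrame, scheme: str) -> pd.Series:
    """Per-subject stratum label under a scheme (NA where unassignable).

    ``exposure`` must carry ``risk_category`` (schemes beyond overall),
    ``retinopathy`` (retinopathy schemes) and ``slope_stratum`` (slope
    scheme).  Missing retinopathy or slope leaves the subject unassigned
    in that scheme only.
    """
    n = len(exposure)
    if scheme == "overall":
        return pd.Series(["all"] * n, index=exposure.index, dtype=object)
    if scheme not in SCHEMES:
        raise ConfigError(f"unknown stratification scheme {scheme!r}")
    cat = exposure["risk_category"]
    labels = pd.Series([None] * n, index=exposure.index, dtype=object)
    if scheme == "risk4":
        ok = cat.notna()
        labels[ok] = cat[ok]
        return labels
    ret = exposure["retinopathy"]
    ret_label = ret.map(
        lambda v: None if pd.isna(v) else ("retinopathy" if bool(v) else "no_retinopathy")
    )
    base_ok = cat.notna() & ret_label.notna()
    r2 = cat.map(lambda v: _RISK2.get(v))
    if scheme == "risk2_retinopathy":
        labels[base_ok] = r2[base_ok] + "|" + ret_label[base_ok]
        return labels
    slope = exposure["slope_stratum"].map(
        lambda v: None if pd.isna(v) or v == "missing" else v
    )
    ok = base_ok & slope.notna()
    labels[ok] = r2[ok] + "|" + ret_label[ok] + "|" + slope[ok]
    return labels
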