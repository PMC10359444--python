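"""Sex-stratified percentile binarization of continuous risk factors.

Each continuous factor is dichotomized at the upper or lower 20 % (or 10 %
under the sensitivity setting) of the baseline distribution of that sex:
"presence of risk" means a value STRICTLY beyond the threshold (strictly
above for high-is-risk factors, strictly below for low-is-risk ones), so a
value tied with the threshold counts as absence.  Percentiles are estimated
by linear interpolation between order statistics (the numpy default).

Categorical factors follow fixed rules instead: dipstick urine protein is a
risk when >= 1+ (negative/trace is no risk), and retinopathy when present.
Retinopathy and the 2-year eGFR decline are stratifiers by default, not
rule factors.

Missing analytes yield a missing presence flag for that factor only, so a
subject drops out of the counts of rules involving that factor but no
others (per-factor complete case).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ThresholdError, ValidationError

HIGH_IS_RISK = "high_is_risk"
LOW_IS_RISK = "low_is_risk"
CATEGORICAL = "categorical"

RULE_DIPSTICK_GE_1PLUS = "dipstick_ge_1plus"
RULE_BOOLEAN_TRUE = "boolean_true"

DIPSTICK_RISK_GRADES = ("1+", "2+", "3+")

SEXES = ("male", "female")


@dataclass(frozen=True)
class RiskFactorSpec:
    """How one risk factor is turned into a presence/absence flag."""

    name: str
    source_field: str
    direction: str  # high_is_risk | low_is_risk | categorical
    percentile: Optional[int] = 20  # tail size in percent (continuous only)
    categorical_rule: Optional[str] = None
    is_stratifier: bool = False

    def __post_init__(self) -> None:
        if self.direction not in (HIGH_IS_RISK, LOW_IS_RISK, CATEGORICAL):
            raise ValidationError(f"{self.name}: unknown direction {self.direction!r}")
        if self.direction == CATEGORICAL:
            if self.categorical_rule is None and not self.is_stratifier:
                raise ValidationError(f"{self.name}: categorical factor needs a rule")
            if self.percentile is not None:
                raise ValidationError(f"{self.name}: categorical factor has no percentile")
        elif self.percentile not in (10, 20):
            raise ValidationError(f"{self.name}: percentile must be 10 or 20")


def default_factor_specs(percentile: int = 20) -> List[RiskFactorSpec]:
    """The default 17 risk-factor specs.

    High values are risky for the glycemic, hepatic, lipid (except HDL),
    blood-pressure and adiposity factors; low values are risky for eGFR,
    hemoglobin (anemia) and HDL cholesterol.  Urine protein is categorical
    (>= 1+ is risk).  Retinopathy and the 2-year eGFR decline are carried
    as stratifiers, not rule factors.
    """
    p = percentile

    def cont(name: str, field: str, direction: str) -> RiskFactorSpec:
        return RiskFactorSpec(name, field, direction, percentile=p)

    return [
        cont("egfr", "baseline_egfr", LOW_IS_RISK),
        RiskFactorSpec(
            "urine_protein",
            "dipstick_protein",
            CATEGORICAL,
            percentile=None,
            categorical_rule=RULE_DIPSTICK_GE_1PLUS,
        ),
        cont("hba1c", "hba1c", HIGH_IS_RISK),
        cont("fasting_glucose", "fasting_glucose", HIGH_IS_RISK),
        cont("hemoglobin", "hemoglobin", LOW_IS_RISK),
        cont("ast", "ast", HIGH_IS_RISK),
        cont("alt", "alt", HIGH_IS_RISK),
        cont("ggt", "ggt", HIGH_IS_RISK),
        cont("total_chol", "total_chol", HIGH_IS_RISK),
        cont("triglyceride", "triglyceride", HIGH_IS_RISK),
        cont("hdl", "hdl", LOW_IS_RISK),
        cont("ldl", "ldl", HIGH_IS_RISK),
        cont("sbp", "sbp", HIGH_IS_RISK),
        cont("dbp", "dbp", HIGH_IS_RISK),
        cont("bmi", "bmi", HIGH_IS_RISK),
        RiskFactorSpec(
            "retinopathy",
            "retinopathy",
            CATEGORICAL,
            percentile=None,
            categorical_rule=RULE_BOOLEAN_TRUE,
            is_stratifier=True,
        ),
        RiskFactorSpec(
            "egfr_2y_decline",
            "slope_stratum",
            CATEGORICAL,
            percentile=None,
            is_stratifier=True,
        ),
    ]


def rule_factors(specs: Sequence[RiskFactorSpec]) -> List[RiskFactorSpec]:
    """The specs used as rule antecedents (stratifiers excluded)."""
    return [s for s in specs if not s.is_stratifier]


def get_spec(specs: Sequence[RiskFactorSpec], name: str) -> RiskFactorSpec:
    for s in specs:
        if s.name == name:
            return s
    raise KeyError(name)


def compute_thresholds(
    baseline: pd.DataFrame,
    specs: Optional[Sequence[RiskFactorSpec]] = None,
    percentile: Optional[int] = None,
) -> pd.DataFrame:
    """Sex-specific percentile thresholds for every continuous factor.

    For a high-is-risk factor the threshold is the (100 - percentile)-th
    percentile of that sex's non-missing baseline values; for a low-is-risk
    factor it is the percentile-th percentile.  Returns a tidy frame with
    columns factor, sex, direction, percentile, threshold.

    Raises :class:`ThresholdError` when a (factor, sex) cell present in the
    data has no non-missing value.
    """
    specs = default_factor_specs() if specs is None else list(specs)
    rows = []
    sexes = [s for s in SEXES if (baseline["sex"] == s).any()]
    for spec in specs:
        if spec.direction == CATEGORICAL:
            continue
        p = percentile if percentile is not None else spec.percentile
        q = 100 - p if spec.direction == HIGH_IS_RISK else p
        for sex in sexes:
            vals = baseline.loc[baseline["sex"] == sex, spec.source_field]
            vals = vals.to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise ThresholdError(
                    f"no non-missing {spec.name!r} values for sex {sex!r}"
                )
            rows.append(
                {
                    "factor": spec.name,
                    "sex": sex,
                    "direction": spec.direction,
                    "percentile": p,
                    "threshold": float(np.percentile(vals, q)),
                }
            )
    return pd.DataFrame(rows, columns=["factor", "sex", "direction", "percentile", "threshold"])


def binarize(
    baseline: pd.DataFrame,
    thresholds: pd.DataFrame,
    specs: Optional[Sequence[RiskFactorSpec]] = None,
) -> pd.DataFrame:
    """Presence/absence flags per subject and rule factor.

    Returns a frame with ``subject_id`` plus one nullable-boolean
    ``flag_<factor>`` column per rule factor; a missing analyte gives a
    missing flag for that factor only.
    """
    specs = default_factor_specs() if specs is None else list(specs)
    lut = {
        (r.factor, r.sex): r.threshold for r in thresholds.itertuples(index=False)
    }
    sex = baseline["sex"].to_numpy()
    out = pd.DataFrame({"subject_id": baseline["subject_id"].to_numpy()})
    for spec in rule_factors(specs):
        if spec.direction == CATEGORICAL:
            flags = _categorical_flags(baseline, spec)
        else:
            vals = baseline[spec.source_field].to_numpy(dtype=float)
            thr = np.array([lut[(spec.name, s)] for s in sex])
            if spec.direction == HIGH_IS_RISK:
                present = vals > thr
            else:
                present = vals < thr
            flags = pd.array(present, dtype="boolean")
            flags[~np.isfinite(vals)] = pd.NA
        out[f"flag_{spec.name}"] = flags
    return out


def _categorical_flags(baseline: pd.DataFrame, spec: RiskFactorSpec) -> pd.array:
    col = baseline[spec.source_field]
    if spec.categorical_rule == RULE_DIPSTICK_GE_1PLUS:
        present = col.isin(DIPSTICK_RISK_GRADES).to_numpy()
        missing = col.isna().to_numpy()
    elif spec.categorical_rule == RULE_BOOLEAN_TRUE:
        missing = col.isna().to_numpy()
        present = np.array(
            [bool(v) if not pd.isna(v) else False for v in col.to_numpy(dtype=object)]
        )
    else:
        raise ValidationError(f"{spec.name}: unknown categorical rule {spec.categorical_rule!r}")
    flags = pd.array(present, dtype="boolean")
    flags[missing] = pd.NA
    return flags
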