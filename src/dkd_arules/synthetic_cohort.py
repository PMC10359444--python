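"""Synthetic longitudinal diabetic-cohort generator and cohort CSV I/O.

The real health-examination cohorts this analysis was designed for are
private, so the generator produces data with the same schema and the
statistical structure the downstream analysis assumes:

* each subject has a baseline visit plus annual follow-up visits;
* every continuous analyte has a truncated-normal marginal whose mean/SD
  default to typical general- and worker-cohort baseline characteristics;
* each subject carries latent binary risk states (one per factor); the
  analyte for a "risky" subject is drawn from the tail of its marginal
  beyond the intended percentile cut, and from the body otherwise, so
  downstream percentile binarization re-identifies the latent state;
* the probability of the worsening-kidney-function trajectory is
  ``worsening_base_rate x prod(effect_map[f] for present factors)``,
  capped at 1;
* worsening subjects follow a linear relative eGFR decline that crosses
  the -30 % boundary at a uniformly random whole year in [1, 5]; stable
  subjects fluctuate by i.i.d. +/- 3 % measurement noise;
* visit creatinine is back-computed from the target eGFR via the Japanese
  equation, so recomputing eGFR downstream reproduces the designed
  trajectory exactly.

All randomness flows through a single ``numpy.random.Generator`` seeded
from the profile, so equal seeds give byte-identical cohorts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .errors import SchemaError, ValidationError
from .renal_metrics import creatinine_from_egfr

DIPSTICK_LEVELS = ("negative", "trace", "1+", "2+", "3+")

#: analyte columns of the cohort CSV, in schema order
ANALYTE_COLUMNS = (
    "serum_creatinine",
    "hba1c",
    "fasting_glucose",
    "hemoglobin",
    "ast",
    "alt",
    "ggt",
    "total_chol",
    "triglyceride",
    "hdl",
    "ldl",
    "sbp",
    "dbp",
    "bmi",
)

COHORT_COLUMNS = (
    "subject_id",
    "year",
    "age",
    "sex",
    "serum_creatinine",
    "dipstick_protein",
    "hba1c",
    "fasting_glucose",
    "hemoglobin",
    "ast",
    "alt",
    "ggt",
    "total_chol",
    "triglyceride",
    "hdl",
    "ldl",
    "sbp",
    "dbp",
    "bmi",
    "retinopathy",
    "on_dm_treatment",
    "eskd_event",
)

#: factors whose risk tail is the LOW end of the marginal
LOW_TAIL_FACTORS = ("egfr", "hemoglobin", "hdl")

# (mean, SD) marginals for a general diabetic screening population
GENERAL_MARGINALS: Dict[str, Tuple[float, float]] = {
    "egfr": (75.0, 18.3),
    "hba1c": (7.4, 1.3),
    "fasting_glucose": (7.7, 2.4),
    "hemoglobin": (13.9, 1.5),
    "ast": (28.1, 15.7),
    "alt": (28.9, 22.6),
    "ggt": (50.2, 67.4),
    "total_chol": (208.2, 37.4),
    "triglyceride": (150.6, 93.1),
    "hdl": (57.8, 15.8),
    "ldl": (120.3, 34.1),
    "sbp": (135.1, 17.7),
    "dbp": (78.3, 10.8),
    "bmi": (24.1, 3.4),
}

# (mean, SD) marginals for a working-age diabetic population
WORKER_MARGINALS: Dict[str, Tuple[float, float]] = {
    "egfr": (80.1, 16.1),
    "hba1c": (7.3, 1.4),
    "fasting_glucose": (8.2, 2.4),
    "hemoglobin": (15.3, 1.3),
    "ast": (30.5, 18.9),
    "alt": (41.7, 32.1),
    "ggt": (72.7, 75.1),
    "total_chol": (214.7, 39.5),
    "triglyceride": (179.4, 144.1),
    "hdl": (53.4, 13.1),
    "ldl": (130.6, 32.4),
    "sbp": (130.2, 16.9),
    "dbp": (83.5, 11.9),
    "bmi": (26.7, 4.0),
}

# relative risks of worsening given factor presence; chosen to give the
# glycemic, proteinuria, anemia, blood-pressure and adiposity factors a
# visible positive association while leaving the rest near-null
DEFAULT_EFFECT_MAP: Dict[str, float] = {
    "hba1c": 2.0,
    "fasting_glucose": 2.0,
    "urine_protein": 2.5,
    "hemoglobin": 1.8,
    "egfr": 1.8,
    "sbp": 1.5,
    "dbp": 1.3,
    "bmi": 1.4,
    "triglyceride": 1.4,
    "ggt": 1.3,
    "hdl": 1.3,
}

_LAB_NOISE_FRACTION = 0.02  # +/- relative noise on follow-up analytes
_STABLE_EGFR_NOISE = 0.03  # +/- relative noise on stable eGFR trajectories
_WORSENING_TOTAL_DECLINE = 0.31  # relative decline reached at the crossing year


@dataclass
class CohortProfile:
    """Parameters of one simulated cohort.

    ``worsening_base_rate`` is the worsening probability for a subject with
    no risk factor present; per-factor relative risks live in
    ``effect_map`` (factors absent from the map have relative risk 1).
    ``risk_tail_fraction`` is the latent prevalence of each continuous risk
    state and matches the percentile binarization applied downstream.
    """

    cohort_kind: str = "general"
    n_subjects: int = 1000
    baseline_year: int = 2005
    followup_years: int = 5
    age_mean: float = 66.7
    age_sd: float = 7.7
    prop_female: float = 0.469
    marginal_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(GENERAL_MARGINALS)
    )
    prop_proteinuria: float = 0.116
    prop_retinopathy: float = 0.20
    prop_retinopathy_missing: float = 0.0
    prop_dm_treatment: float = 0.5
    eskd_event_rate: float = 0.0
    worsening_base_rate: float = 0.05
    effect_map: Dict[str, float] = field(default_factory=dict)
    risk_tail_fraction: float = 0.20
    higher_dipstick_grades: bool = False
    seed: int = 0

    @classmethod
    def general(cls, **overrides) -> "CohortProfile":
        """A general (older, community screening) diabetic cohort.

        Unless overridden, the base rate is calibrated so the marginal
        5-year worsening rate is ~4.8 % under the default effect map.
        """
        prof = cls(effect_map=dict(DEFAULT_EFFECT_MAP))
        prof = _replace(prof, **overrides)
        if "worsening_base_rate" not in overrides:
            prof.worsening_base_rate = base_rate_for_marginal(0.048, prof)
        return prof

    @classmethod
    def worker(cls, **overrides) -> "CohortProfile":
        """A working-age (younger, mostly male) diabetic cohort.

        Unless overridden, the base rate is calibrated so the marginal
        5-year worsening rate is ~5.1 % under the default effect map.
        """
        prof = cls(
            cohort_kind="worker",
            baseline_year=2010,
            age_mean=47.8,
            age_sd=5.5,
            prop_female=0.038,
            marginal_params=dict(WORKER_MARGINALS),
            prop_proteinuria=0.291,
            eskd_event_rate=0.002,
            effect_map=dict(DEFAULT_EFFECT_MAP),
        )
        prof = _replace(prof, **overrides)
        if "worsening_base_rate" not in overrides:
            prof.worsening_base_rate = base_rate_for_marginal(0.051, prof)
        return prof

    def validate(self) -> None:
        if self.cohort_kind not in ("general", "worker"):
            raise ValidationError(f"cohort_kind: unknown kind {self.cohort_kind!r}")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects: must be >= 1")
        if self.followup_years < 1:
            raise ValidationError("followup_years: must be >= 1")
        for name in (
            "prop_female",
            "prop_proteinuria",
            "prop_retinopathy",
            "prop_retinopathy_missing",
            "prop_dm_treatment",
            "eskd_event_rate",
            "worsening_base_rate",
            "risk_tail_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}: fraction {v} not in [0, 1]")
        if not 0.0 < self.risk_tail_fraction < 1.0:
            raise ValidationError("risk_tail_fraction: must be in (0, 1)")
        if self.age_mean <= 0 or self.age_sd <= 0:
            raise ValidationError("age_mean/age_sd: must be > 0")
        for name, (mean, sd) in self.marginal_params.items():
            if mean <= 0 or sd <= 0:
                raise ValidationError(f"marginal_params[{name!r}]: mean/SD must be > 0")
        known = set(self.marginal_params) | {"urine_protein", "retinopathy"}
        for name, eff in self.effect_map.items():
            if eff <= 0:
                raise ValidationError(f"effect_map[{name!r}]: relative risk must be > 0")
            if name not in known:
                raise ValidationError(f"effect_map[{name!r}]: unknown factor")


def _replace(profile: CohortProfile, **overrides) -> CohortProfile:
    valid = {f.name for f in fields(CohortProfile)}
    for key in overrides:
        if key not in valid:
            raise ValidationError(f"{key}: unknown CohortProfile field")
        setattr(profile, key, overrides[key])
    return profile


def _truncated_normal(rng, mean, sd, lower, upper, size):
    """Inverse-CDF sampling from N(mean, sd) truncated to (lower, upper)."""
    a = ndtr((lower - mean) / sd)
    b = ndtr((upper - mean) / sd)
    u = rng.uniform(a, b, size=size)
    return mean + sd * ndtri(u)


def _latent_prevalence(profile: CohortProfile, factor: str) -> float:
    if factor == "urine_protein":
        return profile.prop_proteinuria
    if factor == "retinopathy":
        return profile.prop_retinopathy
    return profile.risk_tail_fraction


def expected_effect_multiplier(profile: CohortProfile) -> float:
    """E[prod of effect_map over present factors] under latent independence."""
    m = 1.0
    for fname, eff in profile.effect_map.items():
        q = _latent_prevalence(profile, fname)
        m *= 1.0 + q * (eff - 1.0)
    return m


def base_rate_for_marginal(target: float, profile: CohortProfile) -> float:
    """The no-factor base rate giving a target marginal worsening rate.

    Uses the independence identity E[base x prod effects] = base x
    prod_f (1 + q_f (e_f - 1)); ignores the cap at 1, which only binds for
    vanishingly rare factor combinations at realistic rates.
    """
    return target / expected_effect_multiplier(profile)


def analytic_worsening_probability(
    profile: CohortProfile,
    given_present: Tuple[str, ...] = (),
    given_absent: Tuple[str, ...] = (),
) -> float:
    """Closed-form P(worsening), optionally conditioned on latent states.

    Brute-force enumeration over the joint states of every factor with a
    non-unit relative risk; serves as the generator's own oracle in the
    parameter-recovery checks.
    """
    profile.validate()
    active = sorted(
        f
        for f, e in profile.effect_map.items()
        if e != 1.0 and f not in given_present and f not in given_absent
    )
    base = profile.worsening_base_rate
    fixed = 1.0
    for f in given_present:
        fixed *= profile.effect_map.get(f, 1.0)
    total = 0.0
    for states in itertools.product((0, 1), repeat=len(active)):
        weight, rel = 1.0, fixed
        for f, s in zip(active, states):
            q = _latent_prevalence(profile, f)
            weight *= q if s else 1.0 - q
            if s:
                rel *= profile.effect_map[f]
        total += weight * min(1.0, base * rel)
    return total


def simulate_cohort(
    profile: CohortProfile,
    return_latent: bool = False,
):
    """Simulate one longitudinal cohort.

    Returns a visit-level ``pandas.DataFrame`` with the documented cohort
    schema (one row per subject-visit, years ``baseline_year ..
    baseline_year + followup_years``).  With ``return_latent=True`` also
    returns a per-subject frame of the latent risk states and the drawn
    worsening indicator, for parameter-recovery testing.
    """
    profile.validate()
    rng = np.random.default_rng(profile.seed)
    n = profile.n_subjects
    t_span = profile.followup_years

    female = rng.random(n) < profile.prop_female
    sex = np.where(female, "female", "male")
    age0 = _truncated_normal(rng, profile.age_mean, profile.age_sd, 21.0, 95.0, n)

    q = profile.risk_tail_fraction
    latent: Dict[str, np.ndarray] = {}
    values: Dict[str, np.ndarray] = {}
    for name in sorted(profile.marginal_params):
        mean, sd = profile.marginal_params[name]
        risky = rng.random(n) < q
        latent[name] = risky
        lo = 1e-6
        if name in LOW_TAIL_FACTORS:
            cut = mean + sd * ndtri(q)
            tail, body = (lo, cut), (cut, np.inf)
        else:
            cut = mean + sd * ndtri(1.0 - q)
            tail, body = (cut, np.inf), (lo, cut)
        v = np.empty(n)
        v[risky] = _truncated_normal(rng, mean, sd, *tail, int(risky.sum()))
        v[~risky] = _truncated_normal(rng, mean, sd, *body, int((~risky).sum()))
        values[name] = v

    proteinuric = rng.random(n) < profile.prop_proteinuria
    latent["urine_protein"] = proteinuric
    trace = rng.random(n) < 0.2
    if profile.higher_dipstick_grades:
        grade = rng.choice(["1+", "2+", "3+"], size=n, p=[0.7, 0.2, 0.1])
    else:
        grade = np.full(n, "1+")
    dipstick = np.where(proteinuric, grade, np.where(trace, "trace", "negative"))

    retinopathy = rng.random(n) < profile.prop_retinopathy
    latent["retinopathy"] = retinopathy
    ret_missing = rng.random(n) < profile.prop_retinopathy_missing

    treated = rng.random(n) < profile.prop_dm_treatment
    # every simulated subject is diabetic: those below both lab criteria are
    # diagnosed-and-treated cases
    treated |= (values["hba1c"] < 6.5) & (values["fasting_glucose"] < 7.0)

    p = np.full(n, profile.worsening_base_rate)
    for fname, eff in profile.effect_map.items():
        p *= np.where(latent[fname], eff, 1.0)
    p = np.minimum(p, 1.0)
    worsen = rng.random(n) < p
    cross_year = rng.integers(1, min(5, t_span) + 1, size=n)

    eskd_subject = np.zeros(n, dtype=bool)
    eskd_year_offset = np.zeros(n, dtype=int)
    if profile.cohort_kind == "worker" and profile.eskd_event_rate > 0:
        eskd_subject = rng.random(n) < profile.eskd_event_rate
        eskd_year_offset = rng.integers(1, t_span + 1, size=n)

    # relative eGFR trajectory, visits t = 0 .. t_span
    t_grid = np.arange(t_span + 1)
    ratio = np.ones((n, t_span + 1))
    noise = rng.uniform(-_STABLE_EGFR_NOISE, _STABLE_EGFR_NOISE, size=(n, t_span))
    ratio[:, 1:] += noise
    decline = 1.0 - _WORSENING_TOTAL_DECLINE * (
        t_grid[None, :] / cross_year[:, None]
    )
    ratio[worsen] = np.maximum(decline[worsen], 0.2)

    egfr_t = values["egfr"][:, None] * ratio
    age_t = age0[:, None] + t_grid[None, :]
    sex_rep = np.repeat(sex, t_span + 1)
    creat = creatinine_from_egfr(egfr_t.ravel(), age_t.ravel(), sex_rep)

    ids = np.array([f"S{i:06d}" for i in range(n)])
    n_visits = t_span + 1
    frame = pd.DataFrame(
        {
            "subject_id": np.repeat(ids, n_visits),
            "year": np.tile(profile.baseline_year + t_grid, n),
            "age": age_t.ravel(),
            "sex": sex_rep,
            "serum_creatinine": creat,
        }
    )
    frame["dipstick_protein"] = np.repeat(dipstick, n_visits)
    for name in ANALYTE_COLUMNS:
        if name == "serum_creatinine":
            continue
        v0 = values[name][:, None]
        lab_noise = np.ones((n, n_visits))
        lab_noise[:, 1:] += rng.uniform(
            -_LAB_NOISE_FRACTION, _LAB_NOISE_FRACTION, size=(n, t_span)
        )
        frame[name] = (v0 * lab_noise).ravel()
    ret_col = retinopathy.astype(object)
    ret_col[ret_missing] = pd.NA
    frame["retinopathy"] = np.repeat(ret_col, n_visits)
    frame["on_dm_treatment"] = np.repeat(treated, n_visits)
    eskd_col = np.zeros((n, n_visits), dtype=bool)
    if eskd_subject.any():
        eskd_col[np.arange(n)[eskd_subject], eskd_year_offset[eskd_subject]] = True
    frame["eskd_event"] = eskd_col.ravel()
    frame = frame[list(COHORT_COLUMNS)]

    if return_latent:
        latent_frame = pd.DataFrame({"subject_id": ids})
        for fname in sorted(latent):
            latent_frame[f"latent_{fname}"] = latent[fname]
        latent_frame["worsening_prob"] = p
        latent_frame["worsening_drawn"] = worsen
        return frame, latent_frame
    return frame


# ---------------------------------------------------------------------------
# cohort CSV I/O
# ---------------------------------------------------------------------------

_BOOL_COLUMNS = ("retinopathy", "on_dm_treatment", "eskd_event")
_NUMERIC_COLUMNS = ("age",) + ANALYTE_COLUMNS
_POSITIVE_COLUMNS = _NUMERIC_COLUMNS  # all labs/vitals are positive quantities


def write_cohort_csv(frame: pd.DataFrame, path) -> None:
    """Write a visit frame to UTF-8 CSV; missing values become empty cells."""
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing columns: {', '.join(missing)}")
    out = frame[list(COHORT_COLUMNS)].copy()
    for col in _BOOL_COLUMNS:
        out[col] = out[col].map(
            lambda v: "" if pd.isna(v) else ("True" if bool(v) else "False")
        )
    out.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV, returning the canonical visit frame.

    Raises :class:`SchemaError` naming the offending row (1-based data row)
    and column for unknown columns, unparseable or non-positive numerics,
    invalid dipstick grades and duplicate (subject, year) pairs.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in raw.columns if c not in COHORT_COLUMNS]
    if unknown:
        raise SchemaError(f"unknown column(s): {', '.join(unknown)}")
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    frame = pd.DataFrame({"subject_id": raw["subject_id"]})

    def _bad(col: str, mask: np.ndarray, why: str):
        row = int(np.flatnonzero(mask)[0]) + 1
        return SchemaError(f"row {row}, column {col!r}: {why}")

    year = pd.to_numeric(raw["year"], errors="coerce")
    if year.isna().any():
        raise _bad("year", year.isna().to_numpy(), "unparseable year")
    frame["year"] = year.astype(int)

    for col in _NUMERIC_COLUMNS:
        empty = raw[col].str.strip() == ""
        num = pd.to_numeric(raw[col].where(~empty), errors="coerce")
        bad = num.isna() & ~empty
        if bad.any():
            raise _bad(col, bad.to_numpy(), f"unparseable value {raw[col][bad.idxmax()]!r}")
        nonpos = num <= 0
        if nonpos.any():
            raise _bad(col, nonpos.to_numpy(), "value must be > 0")
        frame[col] = num

    sex_ok = raw["sex"].isin(["male", "female"])
    if not sex_ok.all():
        raise _bad("sex", (~sex_ok).to_numpy(), "sex must be 'male' or 'female'")
    frame["sex"] = raw["sex"]

    dip_ok = raw["dipstick_protein"].isin(DIPSTICK_LEVELS)
    if not dip_ok.all():
        raise _bad("dipstick_protein", (~dip_ok).to_numpy(), "unknown dipstick grade")
    frame["dipstick_protein"] = raw["dipstick_protein"]

    for col in _BOOL_COLUMNS:
        empty = raw[col].str.strip() == ""
        ok = raw[col].isin(["True", "False"]) | empty
        if not ok.all():
            raise _bad(col, (~ok).to_numpy(), "expected True/False or empty")
        frame[col] = raw[col].map({"True": True, "False": False}).astype(object)
        frame.loc[empty, col] = pd.NA

    dup = frame.duplicated(subset=["subject_id", "year"])
    if dup.any():
        raise _bad("year", dup.to_numpy(), "duplicate (subject, year) visit")
    return frame[list(COHORT_COLUMNS)]
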