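"""Kidney-function metrics: eGFR, outcome classification and 2-year slope strata.

eGFR is estimated from serum creatinine with the Japanese three-variable
equation (Matsuo et al.):

    eGFR = 194 x Cr^-1.094 x age^-0.287   [x 0.739 if female]

in mL/min/1.73 m^2, with creatinine in mg/dL (enzymatic method) and age in
years.  The binary kidney outcome over a fixed follow-up window is

* ``worsening`` -- any in-window follow-up eGFR that is >= 30 % below the
  baseline eGFR (i.e. follow-up / baseline <= 0.70), or, in worker cohorts,
  any in-window ESKD / dialysis-initiation / transplant event;
* ``stable`` -- the complement.

The ">= 30 % decrease" is evaluated at any single follow-up visit, without a
confirmation requirement, and eGFR is carried at full float precision (no
intermediate rounding) so the -30 % boundary is not blurred by rounding
artifacts.

An auxiliary 2-year stratum bins the percent eGFR change at the follow-up
visit nearest to baseline + 2 years (within +/- 1 year; ties broken toward
the earlier visit) into >= 0 %, [-30 %, 0) and < -30 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ClassificationError

EGFR_COEFFICIENT = 194.0
EGFR_CREATININE_EXPONENT = -1.094
EGFR_AGE_EXPONENT = -0.287
EGFR_FEMALE_FACTOR = 0.739

#: percent eGFR decline that defines the worsening outcome
WORSENING_DECLINE_PCT = 30.0

SLOPE_STRATA = ("ge0", "minus30to0", "lt_minus30")


def egfr_japanese(creatinine, age, sex):
    """Estimated GFR (mL/min/1.73 m^2) from the Japanese creatinine equation.

    Parameters
    ----------
    creatinine : float or array-like
        Serum creatinine in mg/dL; must be strictly positive.
    age : float or array-like
        Age in years; must be strictly positive.
    sex : str or array-like of str
        ``"male"`` or ``"female"``.

    Vectorized over numpy arrays / pandas Series.  NaN inputs propagate to
    NaN outputs; non-positive finite inputs raise ``ValueError``.
    """
    cr = np.asarray(creatinine, dtype=float)
    ag = np.asarray(age, dtype=float)
    if np.any(cr[np.isfinite(cr)] <= 0):
        raise ValueError("serum creatinine must be > 0 mg/dL")
    if np.any(ag[np.isfinite(ag)] <= 0):
        raise ValueError("age must be > 0 years")
    sx = np.asarray(sex)
    female = sx == "female"
    out = (
        EGFR_COEFFICIENT
        * np.power(cr, EGFR_CREATININE_EXPONENT)
        * np.power(ag, EGFR_AGE_EXPONENT)
        * np.where(female, EGFR_FEMALE_FACTOR, 1.0)
    )
    if out.ndim == 0:
        return float(out)
    return out


def creatinine_from_egfr(egfr, age, sex):
    """Invert :func:`egfr_japanese`: the creatinine giving a target eGFR."""
    eg = np.asarray(egfr, dtype=float)
    ag = np.asarray(age, dtype=float)
    female = np.asarray(sex) == "female"
    base = EGFR_COEFFICIENT * np.power(ag, EGFR_AGE_EXPONENT)
    base = base * np.where(female, EGFR_FEMALE_FACTOR, 1.0)
    return np.power(eg / base, 1.0 / EGFR_CREATININE_EXPONENT)


@dataclass
class SubjectSeries:
    """Year-ordered visit series for one subject.

    ``egfr`` holds NaN where creatinine was not measured at that visit.
    ``row_positions`` (optional) points back into the assembled visit frame
    so baseline analytes can be recovered without copying rows around.
    """

    subject_id: str
    years: np.ndarray
    egfr: np.ndarray
    sex: str = "male"
    eskd: Optional[np.ndarray] = None
    creatinine: Optional[np.ndarray] = None
    row_positions: Optional[np.ndarray] = None
    frame: Optional[pd.DataFrame] = field(default=None, repr=False)
    baseline_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.egfr = np.asarray(self.egfr, dtype=float)
        if self.eskd is None:
            self.eskd = np.zeros(self.years.size, dtype=bool)
        else:
            self.eskd = np.asarray(self.eskd, dtype=bool)
        if np.any(np.diff(self.years) <= 0):
            raise ValueError(
                f"subject {self.subject_id!r}: visit years must be strictly increasing"
            )

    @classmethod
    def from_values(
        cls,
        subject_id: str,
        years: Sequence[int],
        egfr: Sequence[float],
        sex: str = "male",
        eskd: Optional[Sequence[bool]] = None,
        baseline_index: Optional[int] = None,
    ) -> "SubjectSeries":
        """Convenience constructor from explicit eGFR values."""
        return cls(
            subject_id=subject_id,
            years=np.asarray(years),
            egfr=np.asarray(egfr, dtype=float),
            sex=sex,
            eskd=None if eskd is None else np.asarray(eskd),
            baseline_index=baseline_index,
        )

    @property
    def measured(self) -> np.ndarray:
        """Boolean mask of visits with an eGFR measurement."""
        return np.isfinite(self.egfr)

    @property
    def baseline_year(self) -> int:
        if self.baseline_index is None:
            raise ValueError(f"subject {self.subject_id!r}: baseline not set")
        return int(self.years[self.baseline_index])

    @property
    def baseline_egfr(self) -> float:
        if self.baseline_index is None:
            raise ValueError(f"subject {self.subject_id!r}: baseline not set")
        return float(self.egfr[self.baseline_index])


@dataclass
class RenalOutcome:
    """Classified kidney outcome for one subject."""

    subject_id: str
    baseline_egfr: float
    worst_pct_change: float
    outcome: str  # "stable" | "worsening"
    egfr_2y_change_pct: float  # NaN when no visit near the 2-year mark
    slope_stratum: str  # "ge0" | "minus30to0" | "lt_minus30" | "missing"


def _followup_mask(series: SubjectSeries, followup_years: int) -> np.ndarray:
    by = series.baseline_year
    return (
        (series.years > by)
        & (series.years <= by + followup_years)
        & series.measured
    )


def classify_outcome(
    series: SubjectSeries,
    cohort_kind: str = "general",
    followup_years: int = 5,
) -> RenalOutcome:
    """Classify a subject as stable vs worsening kidney function.

    Worsening iff any in-window follow-up eGFR is <= 0.70 x baseline eGFR,
    or (worker cohort) any in-window ESKD-type event.  ``worst_pct_change``
    is the minimum signed percent change over in-window follow-ups.
    """
    if series.baseline_index is None:
        raise ClassificationError(f"subject {series.subject_id!r}: baseline not set")
    mask = _followup_mask(series, followup_years)
    if not mask.any():
        raise ClassificationError(
            f"subject {series.subject_id!r}: no follow-up eGFR within "
            f"{followup_years} years of baseline"
        )
    base = series.baseline_egfr
    pct = (series.egfr[mask] / base - 1.0) * 100.0
    worst = float(pct.min())
    by = series.baseline_year
    window = (series.years > by) & (series.years <= by + followup_years)
    eskd_hit = cohort_kind == "worker" and bool(series.eskd[window].any())
    worsening = worst <= -WORSENING_DECLINE_PCT or eskd_hit
    two_y = two_year_change_pct(series)
    return RenalOutcome(
        subject_id=series.subject_id,
        baseline_egfr=base,
        worst_pct_change=worst,
        outcome="worsening" if worsening else "stable",
        egfr_2y_change_pct=two_y,
        slope_stratum=_slope_bin(two_y),
    )


def two_year_change_pct(series: SubjectSeries) -> float:
    """Percent eGFR change at the visit nearest baseline + 2 years (+/- 1 y).

    Returns NaN when no measured visit falls within [baseline+1, baseline+3].
    Among equally distant candidates the earlier visit wins.
    """
    if series.baseline_index is None:
        raise ClassificationError(f"subject {series.subject_id!r}: baseline not set")
    by = series.baseline_year
    cand = (series.years >= by + 1) & (series.years <= by + 3) & series.measured
    if not cand.any():
        return float("nan")
    years = series.years[cand]
    egfr = series.egfr[cand]
    # argmin returns the first minimum; years are ascending, so ties at equal
    # distance resolve toward the earlier visit
    pick = int(np.argmin(np.abs(years - (by + 2))))
    return float((egfr[pick] / series.baseline_egfr - 1.0) * 100.0)


def _slope_bin(change_pct: float) -> str:
    if not np.isfinite(change_pct):
        return "missing"
    if change_pct >= 0.0:
        return "ge0"
    if change_pct >= -WORSENING_DECLINE_PCT:
        return "minus30to0"
    return "lt_minus30"


def two_year_stratum(series: SubjectSeries) -> str:
    """Bin the 2-year eGFR change: 'ge0', 'minus30to0', 'lt_minus30', 'missing'."""
    return _slope_bin(two_year_change_pct(series))


def outcome_table(
    series_list: Iterable[SubjectSeries],
    cohort_kind: str = "general",
    followup_years: int = 5,
) -> pd.DataFrame:
    """One classified-outcome row per subject (see :class:`RenalOutcome`)."""
    rows = [
        classify_outcome(s, cohort_kind=cohort_kind, followup_years=followup_years)
        for s in series_list
    ]
    if not rows:
        return pd.DataFrame(
            columns=[
                "subject_id",
                "baseline_egfr",
                "worst_pct_change",
                "outcome",
                "egfr_2y_change_pct",
                "slope_stratum",
            ]
        )
    return pd.DataFrame([r.__dict__ for r in rows])
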