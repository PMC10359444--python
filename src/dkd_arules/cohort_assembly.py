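"""Eligibility filtering and baseline selection for diabetic cohorts.

A subject enters the analysis when

1. they are diabetic at baseline (HbA1c >= 6.5 %, fasting plasma glucose
   >= 7.0 mmol/L, or treatment of diabetes; missing criteria count as not
   met),
2. a baseline exists: the oldest visit with a creatinine/eGFR measurement
   that is followed by at least one later visit and whose span to the last
   visit covers the follow-up horizon, and
3. at least one creatinine-bearing follow-up visit falls strictly after
   baseline and within ``followup_years`` of it.

Exclusion reasons are attributed first-failing-rule-wins in the order
not diabetic -> no baseline eGFR -> insufficient follow-up; the order only
affects attribution, never the final count.

Diabetes status is anchored at the baseline visit; when every diabetes
criterion is missing there, the earliest earlier visit carrying any
criterion is consulted instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import IndeterminateError
from .renal_metrics import SubjectSeries, egfr_japanese

REASON_NOT_DIABETIC = "not_diabetic"
REASON_NO_BASELINE = "no_baseline_egfr"
REASON_FOLLOWUP = "insufficient_followup"

HBA1C_CUTOFF = 6.5  # %
GLUCOSE_CUTOFF = 7.0  # mmol/L


@dataclass
class EligibilityReport:
    """Counts along the eligibility cascade plus per-subject reasons."""

    n_input_subjects: int = 0
    n_diabetes: int = 0
    n_with_baseline: int = 0
    n_followed: int = 0
    n_final: int = 0
    exclusion_reasons: Dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input_subjects": self.n_input_subjects,
            "n_diabetes": self.n_diabetes,
            "n_with_baseline": self.n_with_baseline,
            "n_followed": self.n_followed,
            "n_final": self.n_final,
            "exclusion_reasons": dict(self.exclusion_reasons),
        }


def _field(visit, name):
    try:
        return visit[name]
    except (KeyError, IndexError, TypeError):
        return getattr(visit, name, None)


def is_diabetic(visit) -> bool:
    """Diabetes at one visit: HbA1c >= 6.5, glucose >= 7.0 mmol/L, or treatment.

    ``visit`` is any mapping/namespace with ``hba1c``, ``fasting_glucose``
    and ``on_dm_treatment`` fields.  Missing criteria are treated as not
    met; if all three are missing the status is indeterminate.
    """
    hba1c = _field(visit, "hba1c")
    glucose = _field(visit, "fasting_glucose")
    treated = _field(visit, "on_dm_treatment")
    has_hba1c = hba1c is not None and not pd.isna(hba1c)
    has_glucose = glucose is not None and not pd.isna(glucose)
    has_treated = treated is not None and not pd.isna(treated)
    if not (has_hba1c or has_glucose or has_treated):
        raise IndeterminateError("all diabetes criteria missing at this visit")
    if has_hba1c and hba1c >= HBA1C_CUTOFF:
        return True
    if has_glucose and glucose >= GLUCOSE_CUTOFF:
        return True
    return bool(has_treated and treated)


def select_baseline(series: SubjectSeries, followup_years: int = 5) -> SubjectSeries:
    """Set ``baseline_index`` to the oldest qualifying measured visit.

    A visit qualifies when creatinine/eGFR is measured there, at least one
    later visit exists, and the span from it to the subject's last visit is
    >= ``followup_years``.  ``baseline_index`` stays ``None`` when no visit
    qualifies.
    """
    series.baseline_index = None
    last_year = int(series.years[-1])
    for i in range(series.years.size):
        if not series.measured[i]:
            continue
        if i == series.years.size - 1:
            break  # no later visit exists
        if last_year - int(series.years[i]) >= followup_years:
            series.baseline_index = i
        break  # only the oldest measured visit can maximize the span
    return series


def build_series(frame: pd.DataFrame) -> Tuple[List[SubjectSeries], pd.DataFrame]:
    """Split a visit frame into per-subject series (sorted by subject, year).

    Returns the series list and the sorted frame (with a derived ``egfr``
    column) that the series' ``row_positions`` index into.
    """
    sframe = frame.sort_values(["subject_id", "year"], kind="mergesort").reset_index(
        drop=True
    )
    cr = sframe["serum_creatinine"].to_numpy(dtype=float)
    sframe["egfr"] = egfr_japanese(cr, sframe["age"].to_numpy(dtype=float), sframe["sex"].to_numpy())
    years = sframe["year"].to_numpy(dtype=int)
    egfr = sframe["egfr"].to_numpy(dtype=float)
    sex = sframe["sex"].to_numpy()
    eskd = (
        sframe["eskd_event"].astype("boolean").fillna(False).to_numpy(dtype=bool)
        if "eskd_event" in sframe.columns
        else np.zeros(len(sframe), dtype=bool)
    )
    out: List[SubjectSeries] = []
    for sid, ix in sframe.groupby("subject_id", sort=True).indices.items():
        out.append(
            SubjectSeries(
                subject_id=str(sid),
                years=years[ix],
                egfr=egfr[ix],
                sex=str(sex[ix[0]]),
                eskd=eskd[ix],
                row_positions=np.asarray(ix),
                frame=sframe,
            )
        )
    return out, sframe


def _row_diabetes_flags(sframe: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized per-row (diabetic, any-criterion-present) flags.

    Equivalent to calling :func:`is_diabetic` on every row, with the
    indeterminate case reported through the second array.
    """
    hba1c = sframe["hba1c"].to_numpy(dtype=float)
    glucose = sframe["fasting_glucose"].to_numpy(dtype=float)
    treated_raw = sframe["on_dm_treatment"].to_numpy(dtype=object)
    treated_known = np.array([not pd.isna(v) for v in treated_raw])
    treated = np.array([bool(v) if not pd.isna(v) else False for v in treated_raw])
    has_info = np.isfinite(hba1c) | np.isfinite(glucose) | treated_known
    diabetic = (
        (np.isfinite(hba1c) & (hba1c >= HBA1C_CUTOFF))
        | (np.isfinite(glucose) & (glucose >= GLUCOSE_CUTOFF))
        | treated
    )
    return diabetic, has_info


def _diabetic_at_anchor(
    series: SubjectSeries, diabetic: np.ndarray, has_info: np.ndarray
) -> bool:
    """Diabetes evaluated at baseline, falling back to earlier visits."""
    if series.baseline_index is not None:
        order = [series.baseline_index] + list(range(series.baseline_index))
    else:
        order = list(range(series.years.size))
    for i in order:
        pos = int(series.row_positions[i])
        if has_info[pos]:
            return bool(diabetic[pos])
    return False


def _has_followup(series: SubjectSeries, followup_years: int) -> bool:
    by = series.baseline_year
    mask = (series.years > by) & (series.years <= by + followup_years)
    return bool((mask & series.measured).any())


def assemble(
    frame: pd.DataFrame,
    cohort_kind: str = "general",
    followup_years: int = 5,
) -> Tuple[List[SubjectSeries], EligibilityReport]:
    """Apply the eligibility cascade to a visit frame.

    Returns the eligible subjects (with baselines set) and an
    :class:`EligibilityReport`.  ``cohort_kind`` is carried for symmetry
    with the downstream outcome definition; the cascade itself is shared.
    """
    report = EligibilityReport()
    if frame.empty:
        return [], report
    all_series, sframe = build_series(frame)
    report.n_input_subjects = len(all_series)
    diabetic, has_info = _row_diabetes_flags(sframe)
    eligible: List[SubjectSeries] = []
    for series in all_series:
        select_baseline(series, followup_years)
        if not _diabetic_at_anchor(series, diabetic, has_info):
            report.exclusion_reasons[series.subject_id] = REASON_NOT_DIABETIC
            continue
        report.n_diabetes += 1
        has_candidate = (
            series.measured[:-1].any() if series.years.size > 1 else False
        )
        if not has_candidate:
            report.exclusion_reasons[series.subject_id] = REASON_NO_BASELINE
            continue
        report.n_with_baseline += 1
        if series.baseline_index is None or not _has_followup(series, followup_years):
            report.exclusion_reasons[series.subject_id] = REASON_FOLLOWUP
            continue
        report.n_followed += 1
        eligible.append(series)
    report.n_final = len(eligible)
    return eligible, report


def baseline_frame(series_list: List[SubjectSeries]) -> pd.DataFrame:
    """Baseline-visit rows for eligible subjects, with ``baseline_egfr``.

    One row per subject carrying every analyte at the baseline visit; this
    is the table percentile thresholds and risk flags are computed from.
    """
    if not series_list:
        return pd.DataFrame(columns=["subject_id", "baseline_egfr"])
    source = series_list[0].frame
    positions = np.array(
        [int(s.row_positions[s.baseline_index]) for s in series_list]
    )
    out = source.iloc[positions].reset_index(drop=True).copy()
    out = out.rename(columns={"egfr": "baseline_egfr"})
    return out


def subset_frame(frame: pd.DataFrame, series_list: List[SubjectSeries]) -> pd.DataFrame:
    """All visits of the given subjects, in canonical order."""
    keep = {s.subject_id for s in series_list}
    out = frame[frame["subject_id"].isin(keep)]
    return out.sort_values(["subject_id", "year"], kind="mergesort").reset_index(
        drop=True
    )
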