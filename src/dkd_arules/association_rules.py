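"""Single-antecedent association rules between risk factors and outcomes.

Two rule directions are mined per factor and stratum:

* ``absence->stable``: antecedent = factor absent, consequent = stable
  kidney function;
* ``presence->worsening``: antecedent = factor present, consequent =
  worsening kidney function.

With n_all the subjects in the stratum that have a non-missing factor flag
and an outcome,

    confidence = n_joint / n_antecedent
    lift       = confidence / (n_consequent / n_all)

and a rule is called significant when lift > 1.0 strictly.  An empty
antecedent leaves confidence (and hence lift) undefined -- reported as NaN,
never as 0 -- and undefined cells are never significant.  Subjects with a
missing flag are excluded from all four counts of that factor's rules only
(per-factor complete case), so n_all can differ between factors within one
stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import ckd_staging
from .risk_binarization import RiskFactorSpec, default_factor_specs, rule_factors

RULE_ABSENCE_STABLE = "absence->stable"
RULE_PRESENCE_WORSENING = "presence->worsening"
RULES = (RULE_ABSENCE_STABLE, RULE_PRESENCE_WORSENING)

RESULT_COLUMNS = (
    "scheme",
    "stratum",
    "factor",
    "rule",
    "n_all",
    "n_antecedent",
    "n_joint",
    "n_consequent",
    "confidence",
    "lift",
    "significant",
)


@dataclass(frozen=True)
class RuleCounts:
    """The four counts behind one rule cell."""

    n_all: int
    n_antecedent: int
    n_joint: int
    n_consequent: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.n_joint <= self.n_antecedent <= self.n_all
            and 0 <= self.n_consequent <= self.n_all
        )
        if not ok:
            raise ValueError(f"inconsistent rule counts: {self}")


@dataclass(frozen=True)
class RuleResult:
    """One (stratum, factor, rule-direction) cell."""

    scheme: str
    stratum: str
    factor: str
    rule: str
    counts: RuleCounts
    confidence: float  # NaN when undefined
    lift: float  # NaN when undefined
    significant: bool


def _counts_from_arrays(
    present: np.ndarray, worsening: np.ndarray, rule: str
) -> RuleCounts:
    if rule == RULE_PRESENCE_WORSENING:
        antecedent, consequent = present, worsening
    elif rule == RULE_ABSENCE_STABLE:
        antecedent, consequent = ~present, ~worsening
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return RuleCounts(
        n_all=int(present.size),
        n_antecedent=int(antecedent.sum()),
        n_joint=int((antecedent & consequent).sum()),
        n_consequent=int(consequent.sum()),
    )


def count_rule(stratum_rows: pd.DataFrame, factor: str, rule: str) -> RuleCounts:
    """Exact integer counts for one rule over the rows of one stratum.

    ``stratum_rows`` needs a nullable-boolean ``flag_<factor>`` column and
    an ``outcome`` column; rows with a missing flag or outcome are dropped
    from all four counts.
    """
    flags = stratum_rows[f"flag_{factor}"]
    outcome = stratum_rows["outcome"]
    keep = flags.notna().to_numpy() & outcome.notna().to_numpy()
    present = flags.fillna(False).to_numpy(dtype=bool)[keep]
    worsening = (outcome == "worsening").to_numpy()[keep]
    return _counts_from_arrays(present, worsening, rule)


def score_rule(counts: RuleCounts) -> Tuple[float, float, bool]:
    """(confidence, lift, significant) from one cell's counts.

    Undefined quantities come back as NaN; significance requires a defined
    lift strictly greater than 1.
    """
    if counts.n_antecedent > 0:
        confidence = counts.n_joint / counts.n_antecedent
    else:
        confidence = float("nan")
    base = counts.n_consequent / counts.n_all if counts.n_all > 0 else float("nan")
    if np.isfinite(confidence) and np.isfinite(base) and base > 0:
        lift = confidence / base
    else:
        lift = float("nan")
    significant = bool(np.isfinite(lift) and lift > 1.0 and np.isfinite(confidence))
    return confidence, lift, significant


def mine_all(
    exposure: pd.DataFrame,
    specs: Optional[Sequence[RiskFactorSpec]] = None,
    schemes: Sequence[str] = ("overall",),
) -> pd.DataFrame:
    """Mine every (scheme, stratum, factor, rule-direction) cell.

    ``exposure`` is the per-subject table with ``flag_*`` columns, the
    ``outcome`` column, and whatever labels the requested schemes need
    (``risk_category``, ``retinopathy``, ``slope_stratum``).  The output is
    a long-format frame in bit-stable (scheme, stratum, factor, rule)
    order, one row per cell of the complete cross-product -- empty strata
    and undefined cells included.
    """
    specs = default_factor_specs() if specs is None else list(specs)
    factors = [s for s in rule_factors(specs) if f"flag_{s.name}" in exposure.columns]
    outcome_known = exposure["outcome"].notna().to_numpy()
    worsening_all = (exposure["outcome"] == "worsening").to_numpy()
    flag_data = {}
    for spec in factors:
        col = exposure[f"flag_{spec.name}"]
        flag_data[spec.name] = (
            col.notna().to_numpy() & outcome_known,
            col.fillna(False).to_numpy(dtype=bool),
        )
    rows = []
    for scheme in schemes:
        labels = ckd_staging.assign_strata(exposure, scheme).to_numpy(dtype=object)
        for stratum in ckd_staging.stratum_labels(scheme):
            in_stratum = labels == stratum
            for spec in factors:
                keep, present_full = flag_data[spec.name]
                sel = in_stratum & keep
                present = present_full[sel]
                worsening = worsening_all[sel]
                for rule in RULES:
                    counts = _counts_from_arrays(present, worsening, rule)
                    confidence, lift, significant = score_rule(counts)
                    rows.append(
                        (
                            scheme,
                            stratum,
                            spec.name,
                            rule,
                            counts.n_all,
                            counts.n_antecedent,
                            counts.n_joint,
                            counts.n_consequent,
                            confidence,
                            lift,
                            significant,
                        )
                    )
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def bootstrap_confidence_interval(
    stratum_rows: pd.DataFrame,
    factor: str,
    rule: str,
    n_boot: int = 200,
    level: float = 0.95,
    seed: int = 0,
) -> Tuple[float, float]:
    """Optional percentile-bootstrap interval for one rule's confidence.

    An extension beyond the lift>1 significance rule, off by default in the
    pipeline; resamples subjects with replacement within the stratum.
    """
    rng = np.random.default_rng(seed)
    flags = stratum_rows[f"flag_{factor}"]
    keep = flags.notna().to_numpy() & stratum_rows["outcome"].notna().to_numpy()
    present = flags.fillna(False).to_numpy(dtype=bool)[keep]
    worsening = (stratum_rows["outcome"] == "worsening").to_numpy()[keep]
    n = present.size
    if n == 0:
        return float("nan"), float("nan")
    stats = np.full(n_boot, np.nan)
    for b in range(n_boot):
        ix = rng.integers(0, n, size=n)
        counts = _counts_from_arrays(present[ix], worsening[ix], rule)
        stats[b], _, _ = score_rule(counts)
    stats = stats[np.isfinite(stats)]
    if stats.size == 0:
        return float("nan"), float("nan")
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(stats, alpha)), float(np.quantile(stats, 1.0 - alpha))
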