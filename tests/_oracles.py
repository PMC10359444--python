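"""Independent brute-force oracles and small data builders for the tests.

The rule-counting oracle enumerates rows one by one in pure Python and
never touches the package's counting code, so it can arbitrate it.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


def brute_force_rule(
    flags: Sequence[Optional[bool]],
    outcomes: Sequence[Optional[str]],
    rule: str,
) -> Tuple[int, int, int, int, float, float, bool]:
    """Row-by-row enumeration of one rule's counts, confidence and lift."""
    n_all = n_ant = n_joint = n_cons = 0
    for flag, outcome in zip(flags, outcomes):
        if flag is None or outcome is None:
            continue
        n_all += 1
        if rule == "presence->worsening":
            ant = bool(flag)
            cons = outcome == "worsening"
        elif rule == "absence->stable":
            ant = not bool(flag)
            cons = outcome == "stable"
        else:
            raise ValueError(rule)
        if ant:
            n_ant += 1
            if cons:
                n_joint += 1
        if cons:
            n_cons += 1
    confidence = n_joint / n_ant if n_ant > 0 else math.nan
    base = n_cons / n_all if n_all > 0 else math.nan
    lift = confidence / base if n_ant > 0 and n_all > 0 and base > 0 else math.nan
    significant = not math.isnan(lift) and lift > 1.0
    return n_all, n_ant, n_joint, n_cons, confidence, lift, significant


def random_exposure_table(
    rng: np.random.Generator, max_rows: int = 20
) -> Tuple[pd.DataFrame, List[Optional[bool]], List[str]]:
    """A random small exposure table with missing flags sprinkled in."""
    n = int(rng.integers(0, max_rows + 1))
    flags: List[Optional[bool]] = []
    for _ in range(n):
        u = rng.random()
        flags.append(None if u < 0.15 else bool(u < 0.55))
    outcomes = [
        "worsening" if rng.random() < 0.3 else "stable" for _ in range(n)
    ]
    frame = pd.DataFrame(
        {
            "flag_x": pd.array(flags, dtype="boolean"),
            "outcome": outcomes,
        }
    )
    return frame, flags, outcomes


def make_visits(rows: Sequence[dict]) -> pd.DataFrame:
    """Build a schema-complete visit frame from sparse row dicts.

    Every row gets diabetic-by-treatment defaults so eligibility tests can
    focus on whichever rule they exercise.
    """
    from dkd_arules.synthetic_cohort import COHORT_COLUMNS

    defaults = {
        "subject_id": "S1",
        "year": 2000,
        "age": 60.0,
        "sex": "male",
        "serum_creatinine": np.nan,
        "dipstick_protein": "negative",
        "hba1c": 7.5,
        "fasting_glucose": 8.0,
        "hemoglobin": 14.0,
        "ast": 25.0,
        "alt": 25.0,
        "ggt": 40.0,
        "total_chol": 200.0,
        "triglyceride": 140.0,
        "hdl": 55.0,
        "ldl": 120.0,
        "sbp": 130.0,
        "dbp": 80.0,
        "bmi": 24.0,
        "retinopathy": False,
        "on_dm_treatment": True,
        "eskd_event": False,
    }
    full = [{**defaults, **row} for row in rows]
    return pd.DataFrame(full, columns=list(COHORT_COLUMNS))
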