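"""Rule counting and scoring against a brute-force enumeration oracle."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from dkd_arules import (
    RULE_ABSENCE_STABLE,
    RULE_PRESENCE_WORSENING,
    RULES,
    RiskFactorSpec,
    RuleCounts,
    count_rule,
    default_factor_specs,
    mine_all,
    score_rule,
)

from _oracles import brute_force_rule, random_exposure_table


def _ten_row_frame():
    """10 rows, 4 factor-present of which 2 worsen, 3 worsening overall."""
    flags = [True, True, True, True, False, False, False, False, False, False]
    outcomes = [
        "worsening", "worsening", "stable", "stable",
        "worsening", "stable", "stable", "stable", "stable", "stable",
    ]
    return pd.DataFrame(
        {"flag_x": pd.array(flags, dtype="boolean"), "outcome": outcomes}
    )


class TestCountRule:
    def test_presence_worsening_counts(self):
        c = count_rule(_ten_row_frame(), "x", RULE_PRESENCE_WORSENING)
        assert (c.n_all, c.n_antecedent, c.n_joint, c.n_consequent) == (10, 4, 2, 3)

    def test_absence_stable_counts_by_complement(self):
        c = count_rule(_ten_row_frame(), "x", RULE_ABSENCE_STABLE)
        assert (c.n_all, c.n_antecedent, c.n_joint, c.n_consequent) == (10, 6, 5, 7)

    def test_empty_stratum_all_zero(self):
        frame = _ten_row_frame().iloc[0:0]
        c = count_rule(frame, "x", RULE_PRESENCE_WORSENING)
        assert (c.n_all, c.n_antecedent, c.n_joint, c.n_consequent) == (0, 0, 0, 0)

    def test_missing_flags_drop_from_all_counts(self):
        frame = _ten_row_frame()
        frame.loc[0, "flag_x"] = pd.NA  # was present & worsening
        c = count_rule(frame, "x", RULE_PRESENCE_WORSENING)
        assert (c.n_all, c.n_antecedent, c.n_joint, c.n_consequent) == (9, 3, 1, 2)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            RuleCounts(n_all=5, n_antecedent=6, n_joint=0, n_consequent=0)
        with pytest.raises(ValueError):
            RuleCounts(n_all=5, n_antecedent=2, n_joint=3, n_consequent=0)


class TestScoreRule:
    def test_worked_example(self):
        conf, lift, sig = score_rule(RuleCounts(10, 4, 2, 3))
        assert conf == pytest.approx(0.5)
        assert lift == pytest.approx(0.5 / 0.3)
        assert sig is True

    def test_lift_exactly_one_not_significant(self):
        conf, lift, sig = score_rule(RuleCounts(10, 4, 4, 10))
        assert conf == 1.0 and lift == 1.0 and sig is False

    def test_empty_antecedent_undefined_not_zero(self):
        conf, lift, sig = score_rule(RuleCounts(10, 0, 0, 3))
        assert np.isnan(conf) and np.isnan(lift) and sig is False

    def test_zero_base_rate_undefined_lift(self):
        conf, lift, sig = score_rule(RuleCounts(10, 4, 0, 0))
        assert conf == 0.0 and np.isnan(lift) and sig is False


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(50):
            frame, flags, outcomes = random_exposure_table(rng)
            for rule in RULES:
                c = count_rule(frame, "x", rule)
                conf, lift, sig = score_rule(c)
                e = brute_force_rule(flags, outcomes, rule)
                assert (c.n_all, c.n_antecedent, c.n_joint, c.n_consequent) == e[:4]
                assert conf == e[4] or (np.isnan(conf) and np.isnan(e[4]))
                assert lift == e[5] or (np.isnan(lift) and np.isnan(e[5]))
                assert sig == e[6]


class TestAlgebraicIdentities:
    def test_antecedents_partition_complete_cases(self, rng):
        for _ in range(20):
            frame, _, _ = random_exposure_table(rng)
            a = count_rule(frame, "x", RULE_ABSENCE_STABLE)
            p = count_rule(frame, "x", RULE_PRESENCE_WORSENING)
            assert a.n_antecedent + p.n_antecedent == a.n_all == p.n_all

    def test_stable_confidence_complements_worsening_fraction(self, rng):
        """conf(absence->stable) + P(worsen | absence) = 1, exactly."""
        for _ in range(20):
            frame, _, _ = random_exposure_table(rng)
            a = count_rule(frame, "x", RULE_ABSENCE_STABLE)
            if a.n_antecedent == 0:
                continue
            conf = Fraction(a.n_joint, a.n_antecedent)
            worsen_given_absent = Fraction(a.n_antecedent - a.n_joint, a.n_antecedent)
            assert conf + worsen_given_absent == 1

    def test_lift_is_symmetric_under_antecedent_consequent_swap(self, rng):
        for _ in range(20):
            frame, flags, outcomes = random_exposure_table(rng)
            c = count_rule(frame, "x", RULE_PRESENCE_WORSENING)
            if c.n_antecedent == 0 or c.n_consequent == 0:
                continue
            lift = Fraction(c.n_joint, c.n_antecedent) / Fraction(c.n_consequent, c.n_all)
            swapped = Fraction(c.n_joint, c.n_consequent) / Fraction(c.n_antecedent, c.n_all)
            assert lift == swapped

    def test_weighted_confidence_aggregates_across_strata(self, mined_run):
        """Sum of n_antecedent x confidence over risk4 strata = joint total."""
        rules = mined_run["rules"]
        risk4 = rules[rules["scheme"] == "risk4"]
        for (factor, rule), grp in risk4.groupby(["factor", "rule"]):
            defined = grp[grp["n_antecedent"] > 0]
            lhs = (defined["n_antecedent"] * defined["confidence"]).sum()
            assert lhs == pytest.approx(defined["n_joint"].sum())


class TestMineAll:
    def test_cross_product_size_with_16_rule_factors(self, mined_run):
        """1 scheme x 4 strata x 16 factors x 2 rules = 128 cells."""
        exposure = mined_run["exposure"].copy()
        # add retinopathy as a 16th rule factor alongside the default 15
        exposure["flag_retinopathy"] = pd.array(
            exposure["retinopathy"].astype("boolean")
        )
        specs = [
            s if s.name != "retinopathy"
            else RiskFactorSpec("retinopathy", "retinopathy", "categorical",
                                percentile=None, categorical_rule="boolean_true")
            for s in default_factor_specs()
        ]
        results = mine_all(exposure, specs, schemes=("risk4",))
        assert len(results) == 128

    def test_complete_cross_product_with_undefined_cells(self, mined_run):
        rules = mined_run["rules"]
        # 15 factors x 2 rules x (1 + 4 + 4 + 12) strata = 630 cells
        assert len(rules) == 630
        counts = rules.groupby("scheme").size()
        assert counts["overall"] == 30
        assert counts["risk2_retinopathy_slope"] == 360
        # undefined cells are retained, flagged non-significant
        undefined = rules[rules["confidence"].isna()]
        assert (~undefined["significant"]).all()

    def test_bit_stable_ordering(self, mined_run):
        rules = mined_run["rules"]
        first = rules.iloc[0]
        assert (first["scheme"], first["stratum"], first["rule"]) == (
            "overall", "all", RULE_ABSENCE_STABLE,
        )
        assert list(rules["rule"][:2]) == [RULE_ABSENCE_STABLE, RULE_PRESENCE_WORSENING]

    def test_mined_cells_match_direct_counting(self, mined_run):
        """Spot-check mined cells against count_rule on the same rows."""
        rules = mined_run["rules"]
        exposure = mined_run["exposure"].copy()
        exposure["flag_hba1c"] = exposure["flag_hba1c"].astype("boolean")
        overall = rules[(rules["scheme"] == "overall") & (rules["factor"] == "hba1c")]
        for _, row in overall.iterrows():
            c = count_rule(exposure, "hba1c", row["rule"])
            assert row["n_antecedent"] == c.n_antecedent
            assert row["n_joint"] == c.n_joint
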