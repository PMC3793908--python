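"""Univariate Cox screening, direction consistency and the exact
proportion-vs-chance interval."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from dmbscreen.simulate import SimConfig, SimTruth, simulate_survival
from dmbscreen.survival import (
    DegenerateCovariateError,
    NoEventsError,
    SurvivalCohort,
    direction_consistency,
    fit_cox_univariate,
    proportion_ci_exact,
    screen_genes,
)


def toy_truth(survival_genes=None):
    return SimTruth(
        de_genes_human={"G1", "G2"},
        de_genes_mouse={"G1", "G2"},
        concordant_genes={"G1": 1, "G2": -1},
        proliferation_genes=set(),
        survival_genes=survival_genes or {},
    )


def random_cohort(rng, n=30, n_genes=1, tie_prob=0.3):
    """Small cohort with mixed censoring and deliberate ties."""
    times = rng.exponential(5, size=n).round(1)  # rounding forces ties
    if tie_prob:
        dup = rng.random(n) < tie_prob
        times[dup] = times[0]
    event = (rng.random(n) < 0.7).astype(int)
    data = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "time": times,
            "event": event,
            "arm": ["CHOP" if i % 2 else "R-CHOP" for i in range(n)],
        }
    )
    for j in range(n_genes):
        data[f"G{j}"] = rng.standard_normal(n)
    return SurvivalCohort(data)


class TestCoxFit:
    def test_constant_covariate_raises(self):
        rng = np.random.default_rng(0)
        cohort = random_cohort(rng)
        cohort.data["G0"] = 1.0
        with pytest.raises(DegenerateCovariateError):
            fit_cox_univariate(cohort, "G0", "CHOP")

    def test_all_censored_raises_no_events(self):
        rng = np.random.default_rng(0)
        cohort = random_cohort(rng)
        cohort.data["event"] = 0
        with pytest.raises(NoEventsError):
            fit_cox_univariate(cohort, "G0", "CHOP")

    def test_matches_lifelines_efron_with_ties(self):
        """Oracle: lifelines (Efron ties) on the same data, |Δbeta| < 1e-4."""
        rng = np.random.default_rng(42)
        for _ in range(15):
            cohort = random_cohort(rng, n=30)
            for arm in ("CHOP", "R-CHOP"):
                fit = fit_cox_univariate(cohort, "G0", arm, ties="efron")
                ref = CoxPHFitter()
                frame = cohort.arm_frame(arm)[["time", "event", "G0"]]
                ref.fit(
                    frame,
                    duration_col="time",
                    event_col="event",
                    fit_options={"precision": 1e-9},
                )
                assert abs(fit.beta - ref.params_["G0"]) < 1e-4
                assert fit.se == pytest.approx(
                    ref.standard_errors_["G0"], rel=1e-3
                )

    def test_matches_frozen_r_survival_values(self):
        """Oracle values computed once with R survival::coxph on this exact
        dataset (mixed censoring, tied event times), both tie conventions."""
        data = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(15)],
                "time": [5, 5, 3, 8, 2, 2, 9, 1, 7, 5, 4, 6, 2, 10, 3],
                "event": [1, 1, 0, 1, 1, 0, 1, 1, 0, 1, 1, 1, 1, 0, 1],
                "arm": ["CHOP"] * 15,
                "G0": [0.2, -1.1, 0.5, -0.3, 1.4, 0.8, -2.0, 1.1, 0.0,
                       0.6, -0.7, 0.3, 1.9, -1.2, 0.4],
            }
        )
        cohort = SurvivalCohort(data)
        expected = {
            "breslow": (1.2199735242, 0.5133717614),
            "efron": (1.3234628518, 0.5309479279),
        }
        for ties, (beta, se) in expected.items():
            fit = fit_cox_univariate(cohort, "G0", "CHOP", ties=ties)
            assert fit.beta == pytest.approx(beta, abs=1e-8)
            assert fit.se == pytest.approx(se, abs=1e-8)

    def test_breslow_equals_efron_without_ties(self):
        rng = np.random.default_rng(7)
        cohort = random_cohort(rng, n=25, tie_prob=0.0)
        cohort.data["time"] = rng.exponential(5, size=25)  # continuous, no ties
        b = fit_cox_univariate(cohort, "G0", "CHOP", ties="breslow")
        e = fit_cox_univariate(cohort, "G0", "CHOP", ties="efron")
        assert b.beta == pytest.approx(e.beta, abs=1e-10)

    def test_parameter_recovery_within_two_se(self):
        truth = toy_truth({"G1": 1.0})
        cohort = simulate_survival(["G1"], truth, 400, SimConfig(seed=9))
        for arm in ("CHOP", "R-CHOP"):
            fit = fit_cox_univariate(cohort, "G1", arm)
            assert abs(fit.beta - 1.0) < 2 * fit.se

    def test_null_coverage(self):
        """|beta| < 2·se in ≈95% of null simulations."""
        hits = 0
        trials = 0
        for seed in range(40):
            cohort = simulate_survival(
                ["G1"], toy_truth(), 50, SimConfig(seed=500 + seed)
            )
            fit = fit_cox_univariate(cohort, "G1", "CHOP")
            trials += 1
            hits += abs(fit.beta) < 2 * fit.se
        assert hits / trials > 0.85

    def test_covariate_scaling_leaves_z_invariant(self):
        rng = np.random.default_rng(3)
        cohort = random_cohort(rng, n=40)
        base = fit_cox_univariate(cohort, "G0", "CHOP")
        cohort.data["G0"] *= 10
        scaled = fit_cox_univariate(cohort, "G0", "CHOP")
        assert scaled.beta == pytest.approx(base.beta / 10, rel=1e-4)
        assert scaled.p_value == pytest.approx(base.p_value, rel=1e-6)

    def test_significance_by_ci_and_p_agree(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            cohort = random_cohort(rng, n=40)
            fit = fit_cox_univariate(cohort, "G0", "CHOP")
            by_ci = fit.ci_low > 1 or fit.ci_high < 1
            assert by_ci == (fit.p_value < 0.05)

    def test_monotone_likelihood_flagged_not_raised(self):
        # perfectly separated risk: expression orders the event times
        data = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(8)],
                "time": [1, 2, 3, 4, 5, 6, 7, 8],
                "event": [1] * 8,
                "arm": ["CHOP"] * 8,
                "G0": [8, 7, 6, 5, 4, 3, 2, 1],
            }
        )
        fit = fit_cox_univariate(SurvivalCohort(data), "G0", "CHOP")
        assert not fit.converged
        assert fit.ci_high == np.inf


class TestScreen:
    def test_planted_gene_detected_in_both_arms(self):
        truth = toy_truth({"G1": 1.0})
        cohort = simulate_survival(["G1", "G2"], truth, 400, SimConfig(seed=2))
        table, sig = screen_genes(cohort)
        assert "G1" in sig
        g1 = table[table["gene_symbol"] == "G1"]
        assert g1["significant"].all()

    def test_failed_fits_excluded_not_fatal(self):
        truth = toy_truth()
        cohort = simulate_survival(["G1", "G2"], truth, 40, SimConfig(seed=3))
        cohort.data["G2"] = 1.0  # degenerate everywhere
        table, sig = screen_genes(cohort)
        assert set(table["gene_symbol"]) == {"G1"}
        assert "G2" not in sig

    def test_arm_difference_p_reported(self):
        truth = toy_truth({"G1": 0.8})
        cohort = simulate_survival(["G1"], truth, 200, SimConfig(seed=4))
        table, _ = screen_genes(cohort)
        assert table["p_arm_diff"].notna().all()
        assert ((table["p_arm_diff"] >= 0) & (table["p_arm_diff"] <= 1)).all()

    def test_degenerate_censoring_raises_no_events(self):
        truth = toy_truth()
        cohort = simulate_survival(
            ["G1"], truth, 40, SimConfig(seed=5, censor_time=1e-9)
        )
        assert cohort.data["event"].sum() == 0
        with pytest.raises(NoEventsError):
            fit_cox_univariate(cohort, "G1", "CHOP")


class TestDirectionConsistency:
    @pytest.mark.parametrize(
        "hr,direction,expected",
        [
            (1.451, 1, True),   # up gene, risk rises with expression
            (0.736, -1, True),  # down gene, risk falls with expression
            (0.9, 1, False),
            (1.2, -1, False),
            (1.0, 1, False),    # boundary: strict inequality
            (1.0, -1, False),
        ],
    )
    def test_rule(self, hr, direction, expected):
        assert direction_consistency(hr, direction) is expected

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValueError):
            direction_consistency(1.5, 0)


class TestProportionCI:
    def test_published_eight_of_sixty(self):
        lo, hi, excludes = proportion_ci_exact(8, 60)
        assert round(lo, 2) == 0.06
        assert round(hi, 2) == 0.25
        assert excludes

    def test_zero_successes_closed_form(self):
        lo, hi, _ = proportion_ci_exact(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10))

    def test_all_successes_upper_is_one(self):
        _, hi, _ = proportion_ci_exact(10, 10)
        assert hi == 1.0

    def test_intervals_nest_with_level(self):
        for k, n in [(3, 20), (8, 60), (0, 5), (7, 7)]:
            lo95, hi95, _ = proportion_ci_exact(k, n, level=0.95)
            lo99, hi99, _ = proportion_ci_exact(k, n, level=0.99)
            assert lo99 <= lo95 and hi99 >= hi95

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            proportion_ci_exact(5, 3)
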