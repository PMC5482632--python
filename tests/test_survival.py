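"""KM/RFS, log-rank, competing-risks CIF, Gray-type test, Cox, backward elimination."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import rbescreen as r
from rbescreen.errors import ConvergenceError, DataError

from conftest import make_records


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        fit = r.km_fit(make_records([3, 5, 8], ["censored"] * 3))
        assert fit.predict(10.0) == 1.0

    def test_hand_product_limit(self):
        # censored at 1, events at 2 and 3: S(2) = 1 * (1 - 1/2) = 0.5, S(3) = 0
        fit = r.km_fit(make_records([1, 2, 3], ["censored", "relapse", "relapse"]))
        assert fit.predict(2.0) == pytest.approx(0.5)
        assert fit.predict(3.0) == pytest.approx(0.0)

    def test_two_distinct_events_step_to_zero(self):
        fit = r.km_fit(make_records([4, 9], ["relapse", "death"]))
        assert fit.predict(4.0) == pytest.approx(0.5)
        assert fit.predict(9.0) == pytest.approx(0.0)

    def test_rfs_event_definition_is_configurable(self):
        rec = make_records([2, 5], ["death", "censored"])
        both = r.km_fit(rec)  # default: relapse or death in remission
        relapse_only = r.km_fit(rec, events=("relapse",))
        assert both.predict(5.0) == pytest.approx(0.5)
        assert relapse_only.predict(5.0) == 1.0

    def test_order_invariance(self, rng):
        rec = r.gen_cohort(r.CohortSimSpec(n_subjects=60, seed=3))
        shuffled = rec.sample(frac=1, random_state=1)
        a, b = r.km_fit(rec), r.km_fit(shuffled)
        pd.testing.assert_series_equal(a.survival, b.survival)


class TestLogrank:
    def test_identical_groups_null(self):
        base = make_records([1, 2, 3, 4], ["relapse", "censored", "relapse", "relapse"])
        rec = pd.concat(
            [base.assign(group="a"), base.assign(group="b")], ignore_index=True
        )
        chi2, p = r.logrank(rec, "group")
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_manual_risk_table(self):
        # groups a: events at 1, 3; b: event at 5, censored at 2, 4, 6
        rec = make_records(
            [1, 3, 2, 4, 5, 6],
            ["relapse", "relapse", "censored", "censored", "relapse", "censored"],
            group=["a", "a", "b", "b", "b", "b"],
        )
        # manual observed-minus-expected for group a over event times 1, 3, 5:
        # t=1: n=6 (na=2), d=1, E=1/3, V=(2/6)(4/6)=8/36
        # t=3: n=4 (na=1: a's t=3; b's t=4,5,6), d=1, E=1/4, V=(1/4)(3/4)=3/16
        # t=5: n=2 (na=0), d=1, E=0, V=0
        # O-E = 2 - 7/12 = 17/12
        v = 8 / 36 + 3 / 16
        expected_chi2 = (17.0 / 12.0) ** 2 / v
        chi2, _ = r.logrank(rec, "group", events=("relapse",))
        assert chi2 == pytest.approx(expected_chi2, rel=1e-9)

    def test_single_group_rejected(self):
        rec = make_records([1, 2], ["relapse", "relapse"], group=["a", "a"])
        with pytest.raises(DataError):
            r.logrank(rec, "group")


class TestCIF:
    def test_reduces_to_one_minus_km_without_competing_cause(self):
        rec = r.gen_cohort(
            r.CohortSimSpec(n_subjects=80, death_hazard=0.0, seed=11)
        )
        cif = r.cif_fit(rec)
        km = r.km_fit(rec, events=("relapse",))
        for t in [5.0, 20.0, 50.0, 80.0]:
            assert cif.predict(t) == pytest.approx(1.0 - km.predict(t), abs=1e-12)

    def test_simultaneous_relapse_jumps_to_one(self):
        cif = r.cif_fit(make_records([7, 7, 7], ["relapse"] * 3))
        assert cif.predict(6.9) == 0.0
        assert cif.predict(7.0) == 1.0

    def test_hand_aalen_johansen_table(self):
        # t=1 relapse (n=5), t=2 death (n=4), t=3 censored, t=4 relapse (n=2), t=5 censored
        rec = make_records(
            [1, 2, 3, 4, 5], ["relapse", "death", "censored", "relapse", "censored"]
        )
        cif = r.cif_fit(rec)
        # S(0)=1: CIF_r(1)=1/5, S=4/5; CIF_d(2)=1/4*4/5=1/5, S=3/5;
        # t=4: risk set 2, CIF_r += 3/5 * 1/2 = 3/10 -> 1/2
        assert cif.predict(1) == pytest.approx(0.2)
        assert cif.predict(2, cause="death") == pytest.approx(0.2)
        assert cif.predict(4) == pytest.approx(0.5)
        assert cif.event_free[-1] == pytest.approx(0.3)

    def test_identity_cif_plus_eventfree_is_one(self):
        rec = r.gen_cohort(r.CohortSimSpec(n_subjects=120, seed=4))
        cif = r.cif_fit(rec)
        total = cif.cif_relapse + cif.cif_death + cif.event_free
        assert np.abs(total - 1.0).max() < 1e-9

    def test_order_invariance(self):
        rec = r.gen_cohort(r.CohortSimSpec(n_subjects=60, seed=9))
        a = r.cif_fit(rec)
        b = r.cif_fit(rec.sample(frac=1, random_state=2))
        np.testing.assert_allclose(a.cif_relapse, b.cif_relapse, atol=0)


class TestGrayTest:
    def test_identical_groups_p_one(self):
        base = make_records(
            [1, 2, 3, 4, 5], ["relapse", "death", "relapse", "censored", "relapse"]
        )
        rec = pd.concat(
            [base.assign(group="a"), base.assign(group="b")], ignore_index=True
        )
        stat, p = r.gray_test(rec, "group", n_permutations=200, seed=0)
        assert stat == pytest.approx(0.0, abs=1e-18)
        assert p == 1.0

    def test_single_group_rejected(self):
        rec = make_records([1, 2], ["relapse", "relapse"], group=["a", "a"])
        with pytest.raises(DataError):
            r.gray_test(rec, "group")

    def test_agrees_with_logrank_without_competing_cause(self):
        """With no competing deaths the Gray score is the log-rank numerator,
        so the permutation p tracks the asymptotic log-rank p."""
        diffs = []
        for seed in range(25):
            rec = r.gen_cohort(
                r.CohortSimSpec(n_subjects=100, death_hazard=0.0, seed=seed)
            )
            _, p_gray = r.gray_test(rec, "high_level", n_permutations=400, seed=seed)
            _, p_lr = r.logrank(rec, "high_level", events=("relapse",))
            diffs.append(p_gray - p_lr)
        assert np.mean(np.abs(diffs)) < 0.05

    def test_null_calibration(self):
        """Permutation p-values are calibrated: rejection near nominal alpha."""
        rejections = 0
        for seed in range(100):
            rec = r.gen_cohort(r.CohortSimSpec(n_subjects=80, seed=1000 + seed))
            _, p = r.gray_test(rec, "high_level", n_permutations=199, seed=seed)
            rejections += p <= 0.05
        assert 1 <= rejections <= 12  # binomial(100, 0.05), generous band

    def test_power_under_strong_group_effect(self):
        small_ps = 0
        for seed in range(20):
            rec = r.gen_cohort(
                r.CohortSimSpec(
                    n_subjects=400, log_hr={"high_level": np.log(5.0)}, seed=seed
                )
            )
            _, p = r.gray_test(rec, "high_level", n_permutations=1999, seed=seed)
            small_ps += p < 0.001
        assert small_ps >= 19  # >= 95% of replicates


class TestCox:
    def test_matches_grid_search_oracle_tiny(self):
        rec = make_records(
            [2, 4, 6, 8], ["relapse"] * 4, x=[1, 0, 1, 0]
        )
        fit = r.cox_fit(rec, ["x"])

        def nll(beta):  # partial likelihood written out; distinct times, no ties
            times = [2, 4, 6, 8]
            xs = [1, 0, 1, 0]
            ll = 0.0
            for i, t in enumerate(times):
                risk = [np.exp(beta * xs[j]) for j in range(4) if times[j] >= t]
                ll += beta * xs[i] - np.log(sum(risk))
            return -ll

        grid = np.linspace(-3, 3, 60001)
        beta_star = grid[np.argmin([nll(b) for b in grid])]
        assert fit.summary["coef"].iloc[0] == pytest.approx(beta_star, abs=1e-4)

    def test_matches_lifelines_efron(self):
        from lifelines import CoxPHFitter

        rec = r.gen_cohort(
            r.CohortSimSpec(
                n_subjects=250,
                covariates=[
                    r.CovariateSpec("trt", "binary", 0.4),
                    r.CovariateSpec("age", "continuous", mean=35, sd=10),
                ],
                log_hr={"trt": 0.8, "age": 0.02},
                seed=17,
            )
        )
        rec["time"] = np.ceil(rec["time"]).clip(lower=1.0)  # induce ties
        fit = r.cox_fit(rec, ["trt", "age"])
        d = rec.assign(E=(rec.event == "relapse").astype(int))[["time", "E", "trt", "age"]]
        cph = CoxPHFitter().fit(d, "time", "E")
        np.testing.assert_allclose(fit.summary["coef"], cph.params_, atol=1e-5)
        np.testing.assert_allclose(fit.summary["se"], cph.standard_errors_, atol=1e-5)

    def test_efron_equals_breslow_without_ties(self):
        rec = r.gen_cohort(r.CohortSimSpec(n_subjects=150, log_hr={"high_level": 0.7}, seed=23))
        assert rec["time"].nunique() == len(rec)  # continuous times: no ties
        a = r.cox_fit(rec, ["high_level"], ties="efron")
        b = r.cox_fit(rec, ["high_level"], ties="breslow")
        assert a.summary["coef"].iloc[0] == pytest.approx(b.summary["coef"].iloc[0], abs=1e-9)

    def test_loglik_at_estimate_beats_null(self):
        rec = r.gen_cohort(r.CohortSimSpec(n_subjects=100, log_hr={"high_level": 1.0}, seed=2))
        fit = r.cox_fit(rec, ["high_level"])
        assert fit.loglik >= fit.loglik_null

    def test_null_wald_p_uniform_over_seeds(self):
        """Randomly permuted covariate: Wald p should be U(0,1) across seeds."""
        ps = []
        for seed in range(150):
            rec = r.gen_cohort(r.CohortSimSpec(n_subjects=120, seed=seed))
            fit = r.cox_fit(rec, ["high_level"])
            ps.append(fit.summary["p"].iloc[0])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_constant_covariate_named_in_error(self):
        rec = make_records([1, 2, 3], ["relapse"] * 3, flat=[1, 1, 1])
        with pytest.raises(DataError, match="flat"):
            r.cox_fit(rec, ["flat"])

    def test_perfect_separation_flagged(self):
        # covariate perfectly orders event times -> monotone likelihood
        rec = make_records(
            [1, 2, 3, 4, 10, 11, 12, 13],
            ["relapse"] * 4 + ["censored"] * 4,
            x=[1, 1, 1, 1, 0, 0, 0, 0],
        )
        with pytest.raises(ConvergenceError):
            r.cox_fit(rec, ["x"])

    def test_no_events_rejected(self):
        rec = make_records([1, 2], ["censored", "censored"], x=[0, 1])
        with pytest.raises(DataError):
            r.cox_fit(rec, ["x"])


class TestBackwardElimination:
    def test_strong_covariates_retained_untouched(self):
        rec = r.gen_cohort(
            r.CohortSimSpec(n_subjects=500, log_hr={"high_level": 1.5}, seed=5)
        )
        res = r.backward_eliminate(rec, ["high_level"])
        assert res.trace == []
        assert res.kept == ["high_level"]

    def test_noise_covariate_removed_strong_kept(self):
        rec = r.gen_cohort(
            r.CohortSimSpec(
                n_subjects=400,
                covariates=[
                    r.CovariateSpec("strong", "binary", 0.5),
                    r.CovariateSpec("noise", "continuous"),
                ],
                log_hr={"strong": 1.6},
                seed=31,
            )
        )
        res = r.backward_eliminate(rec, ["strong", "noise"])
        assert res.kept == ["strong"]
        assert [t["covariate"] for t in res.trace] == ["noise"]

    def test_all_noise_usually_empties_the_model(self):
        # With two pure-noise covariates the model ends empty in most
        # replicates.  The per-replicate rate is ~0.7, not 0.9^2: the
        # covariate surviving step 1 is the one with the *smaller* p-value,
        # so its refit p-value is stochastically small.
        removed_all = 0
        for seed in range(100):
            rec = r.gen_cohort(
                r.CohortSimSpec(
                    n_subjects=300,
                    covariates=[
                        r.CovariateSpec("n1", "continuous"),
                        r.CovariateSpec("n2", "binary", 0.5),
                    ],
                    seed=seed,
                )
            )
            res = r.backward_eliminate(rec, ["n1", "n2"])
            removed_all += res.final is None
        assert removed_all >= 58  # ~2.7 sd below the expected ~71


class TestPointEstimates:
    def test_no_events_survival_one_cif_zero(self):
        rec = make_records([10, 20], ["censored", "censored"])
        km = r.km_fit(rec)
        assert r.point_estimate_at(km, 15.0).value == 1.0
        cif = r.cif_fit(make_records([10, 20, 30], ["censored", "censored", "relapse"]))
        assert r.point_estimate_at(cif, 15.0, n_boot=10).value == 0.0

    def test_single_event_half(self):
        rec = make_records([10, 80], ["relapse", "censored"])
        km = r.km_fit(rec)
        est = r.point_estimate_at(km, 60.0)
        assert est.value == pytest.approx(0.5)
        assert est.lower <= 0.5 <= est.upper

    def test_carry_forward_warns_beyond_last_time(self):
        km = r.km_fit(make_records([5], ["relapse"]))
        with pytest.warns(UserWarning, match="carrying forward"):
            est = r.point_estimate_at(km, 60.0)
        assert est.value == 0.0

    def test_cif_matches_closed_form_exponential(self):
        """CIF_r(t) = lr/(lr+ld) * (1 - exp(-(lr+ld) t)) for exponential causes."""
        lr, ld = 0.02, 0.01
        values = []
        for seed in range(10):
            rec = r.gen_cohort(
                r.CohortSimSpec(
                    n_subjects=2000,
                    baseline_relapse_hazard=lr,
                    death_hazard=ld,
                    censoring_window=None,
                    log_hr={},
                    seed=seed,
                )
            )
            values.append(r.cif_fit(rec).predict(60.0))
        closed = lr / (lr + ld) * (1 - np.exp(-(lr + ld) * 60.0))
        assert np.mean(values) == pytest.approx(closed, abs=0.01)

    def test_cif_bootstrap_ci_brackets_value(self):
        rec = r.gen_cohort(r.CohortSimSpec(n_subjects=150, seed=8))
        cif = r.cif_fit(rec)
        est = r.point_estimate_at(cif, 60.0, n_boot=100, seed=1)
        assert est.lower <= est.value <= est.upper
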