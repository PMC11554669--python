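import numpy as np
import pandas as pd
import pytest

from immunove import (
    CoxPH,
    DesignSpec,
    FineGray,
    StudyTable,
    build_design,
    estimate_cif,
    fit_cause_specific,
    model_tests,
    ph_test,
)
from immunove.survival import ConvergenceWarning


# ---------------------------------------------------------------------------
# independent oracles (hand-coded, no ties assumed)
# ---------------------------------------------------------------------------


def cox_partial_loglik(beta, x, time, event):
    """Hand-coded partial likelihood for one covariate and distinct times."""
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def grid_maximize(fun, lo=-4.0, hi=4.0, step=1e-4):
    grid = np.arange(lo, hi + step, step)
    values = np.array([fun(b) for b in grid])
    return grid[np.argmax(values)]


def finegray_partial_loglik_uncensored(gamma, x, time, cause, target):
    """Weighted pseudo-likelihood with no independent censoring: competing
    failures stay in the risk set forever with weight 1."""
    ll = 0.0
    competing = (cause >= 1) & (cause != target)
    for i in range(len(time)):
        if cause[i] == target:
            risk = (time >= time[i]) | (competing & (time < time[i]))
            ll += gamma * x[i] - np.log(np.sum(np.exp(gamma * x[risk])))
    return ll


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


class TestBuildDesign:
    def _table(self, **cols):
        base = dict(
            subject_id=[f"s{i}" for i in range(len(next(iter(cols.values()))))],
        )
        df = pd.DataFrame({**base, **cols})
        return df

    def test_quadratic_expansion(self):
        df = self._table(arm=["vaccine", "control"], time=[1.0, 2.0],
                         cause=[1, 0], T=[1.0, 2.0])
        X, names = build_design(df, DesignSpec("T", "quadratic"))
        np.testing.assert_allclose(X, [[1, 1], [2, 4]])
        assert names == ["T", "T^2"]

    def test_interaction_column(self):
        df = self._table(arm=["vaccine", "control", "vaccine"],
                         time=[1.0, 2.0, 3.0], cause=[1, 0, 1],
                         T=[1.0, 2.0, 3.0], X=[0.0, 1.0, 1.0])
        X, names = build_design(
            df, DesignSpec("T", "linear", covariates=["X"], interactions=[("T", "X")])
        )
        assert names == ["T", "X", "T:X"]
        np.testing.assert_allclose(X[:, 2], X[:, 0] * X[:, 1])

    def test_sqrt_domain_error(self):
        df = self._table(arm=["vaccine"], time=[1.0], cause=[1], T=[-1.0])
        with pytest.raises(ValueError, match="positive"):
            build_design(df, DesignSpec("T", "sqrt"))

    def test_vaccination_column_last(self):
        df = self._table(arm=["vaccine", "control"], time=[1.0, 2.0],
                         cause=[1, 0], T=[1.0, 2.0])
        X, names = build_design(df, DesignSpec("T", include_vaccination=True))
        assert names == ["T", "vaccination"]
        np.testing.assert_allclose(X[:, 1], [1.0, 0.0])


# ---------------------------------------------------------------------------
# Cox fitting
# ---------------------------------------------------------------------------


class TestCoxPH:
    def test_label_symmetric_data_gives_zero(self):
        # each event time has one subject from each group: swapping groups
        # leaves the data law invariant, so the estimate must vanish
        t = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        res = CoxPH(t, np.ones(6), x[:, None], names=["x"]).fit()
        assert abs(res.params["x"]) < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 9)
        x = rng.standard_normal(n).round(2)
        t = np.sort(rng.uniform(1, 100, n))  # distinct times
        e = rng.random(n) < 0.8
        e[np.argmax(t)] = True  # ensure an event
        res = CoxPH(t, e.astype(float), x[:, None], names=["x"]).fit()
        if not res.converged:
            pytest.skip("monotone-likelihood draw")
        oracle = grid_maximize(lambda b: cox_partial_loglik(b, x, t, e))
        assert abs(res.params["x"] - oracle) <= 1e-4

    def test_all_events_one_group_flags_divergence(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        e = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        with pytest.warns(ConvergenceWarning):
            res = CoxPH(t, e, x[:, None], names=["x"]).fit()
        assert res.diverged and not res.converged

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            CoxPH([1.0, 2.0], [0.0, 0.0], np.zeros((2, 1)))

    def test_aic_identity_and_psd_covariance(self, medium_trial):
        _, table = medium_trial
        res = CoxPH.from_study_table(table, DesignSpec("titer")).fit()
        assert res.aic == 2 * res.df_model - 2 * res.llf
        cov = res.cov_params.to_numpy()
        np.testing.assert_allclose(cov, cov.T, atol=1e-10)
        assert np.linalg.eigvalsh(cov).min() >= -1e-10

    def test_matches_lifelines_with_ties(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 250
        x = rng.standard_normal(n)
        z = rng.integers(0, 2, n).astype(float)
        t = np.round(rng.exponential(1 / np.exp(0.4 * x - 0.3 * z)), 1) + 0.05
        e = (rng.random(n) < 0.7).astype(float)
        df = pd.DataFrame({"t": t, "e": e, "x": x, "z": z})
        theirs = lifelines.CoxPHFitter().fit(df, "t", "e", formula="x + z")
        ours = CoxPH(t, e, np.column_stack([x, z]), names=["x", "z"]).fit()
        np.testing.assert_allclose(ours.params, theirs.params_.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(ours.bse, theirs.standard_errors_.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(ours.llf, theirs.log_likelihood_, atol=1e-8)

    def test_summary_mentions_key_quantities(self, medium_trial):
        _, table = medium_trial
        res = CoxPH.from_study_table(table, DesignSpec("titer")).fit()
        text = res.summary()
        assert "AIC" in text and "titer" in text and "events" in text


class TestCauseSpecific:
    def _two_cause_table(self, seed=3, n=150):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        t1 = rng.exponential(1 / (0.02 * np.exp(-0.5 * x)))
        t2 = rng.exponential(1 / 0.015, n)
        cens = rng.uniform(20, 120, n)
        t = np.minimum.reduce([t1, t2, cens])
        cause = np.select([t == t1, t == t2], [1, 2], default=0)
        return StudyTable(
            pd.DataFrame({
                "subject_id": [f"s{i}" for i in range(n)],
                "arm": np.where(rng.random(n) < 0.5, "vaccine", "control"),
                "time": t, "cause": cause, "titer": x,
            }),
            biomarkers=["titer"],
        )

    def test_single_cause_equals_composite(self, medium_trial):
        _, table = medium_trial
        single = table.subset(np.isin(table.data["cause"], [0, 1]))
        a = CoxPH.from_study_table(single, DesignSpec("titer")).fit()
        b = fit_cause_specific(single, DesignSpec("titer"), target_cause=1)
        np.testing.assert_allclose(a.params, b.params, atol=1e-12)
        assert b.cause == 1

    def test_equals_recoded_composite(self):
        table = self._two_cause_table()
        cs = fit_cause_specific(table, DesignSpec("titer"), target_cause=1)
        df = table.data
        recoded = CoxPH(
            df["time"].to_numpy(), (df["cause"] == 1).astype(float),
            df[["titer"]].to_numpy(), names=["titer"],
        ).fit()
        np.testing.assert_allclose(cs.params, recoded.params, atol=1e-12)

    def test_relabeling_invariance(self):
        table = self._two_cause_table()
        swapped = table.data.copy()
        swapped["cause"] = swapped["cause"].map({0: 0, 1: 2, 2: 1})
        table2 = StudyTable(swapped, biomarkers=["titer"])
        a = fit_cause_specific(table, DesignSpec("titer"), target_cause=1)
        b = fit_cause_specific(table2, DesignSpec("titer"), target_cause=2)
        np.testing.assert_allclose(a.params, b.params, atol=0)

    def test_absent_cause_rejected(self, medium_trial):
        _, table = medium_trial
        with pytest.raises(ValueError, match="absent"):
            fit_cause_specific(table, DesignSpec("titer"), target_cause=9)


class TestFineGray:
    def test_reduces_to_cox_without_competitors(self, medium_trial):
        _, table = medium_trial
        single = table.subset(np.isin(table.data["cause"], [0, 1]))
        df = single.data
        cox = CoxPH(df["time"].to_numpy(), (df["cause"] == 1).astype(float),
                    df[["titer"]].to_numpy(), names=["titer"]).fit()
        fg = FineGray(df["time"].to_numpy(), df["cause"].to_numpy(),
                      df[["titer"]].to_numpy(), 1, names=["titer"]).fit()
        np.testing.assert_allclose(fg.params, cox.params, atol=1e-6)

    def test_matches_weighted_grid_oracle_no_censoring(self):
        rng = np.random.default_rng(9)
        n = 40
        x = rng.standard_normal(n).round(2)
        t = np.sort(rng.uniform(1, 500, n))  # distinct, everyone fails
        cause = rng.integers(1, 3, n)
        cause[0] = 1
        fg = FineGray(t, cause, x[:, None], 1, names=["x"]).fit()
        oracle = grid_maximize(
            lambda g: finegray_partial_loglik_uncensored(g, x, t, cause, 1)
        )
        assert abs(fg.params["x"] - oracle) <= 1e-4

    def test_sign_agrees_with_cif_contrast(self):
        # protective binary covariate for cause 1: its group CIF at horizon
        # must be lower, and the subdistribution coefficient negative
        rng = np.random.default_rng(21)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        t1 = rng.exponential(1 / (0.002 * np.exp(-1.0 * x)))
        t2 = rng.exponential(1 / 0.002, n)
        t = np.minimum(np.minimum(t1, t2), 1000.0)
        cause = np.select([t == t1, t == t2], [1, 2], default=0)
        fg = FineGray(t, cause, x[:, None], 1, names=["x"]).fit()
        cif0 = estimate_cif(t, cause, mask=x == 0).at(1, 999.0)
        cif1 = estimate_cif(t, cause, mask=x == 1).at(1, 999.0)
        assert cif1 < cif0
        assert fg.params["x"] < 0

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            FineGray([1.0, 2.0], [0, 0], np.zeros((2, 1)), 1)


class TestCIF:
    def test_everyone_fails_reaches_one(self):
        t = np.arange(1.0, 9.0)
        cif = estimate_cif(t, np.ones(8, dtype=int))
        np.testing.assert_allclose(cif.cif[1][-1], 1.0, atol=1e-12)

    def test_five_subject_worked_table(self):
        # hand arithmetic: increments S(t_{j-1}) * d_cj / n_j
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        cause = np.array([1, 2, 0, 1, 0])
        cif = estimate_cif(t, cause)
        np.testing.assert_allclose(cif.at(1, 1.0), 0.2)
        np.testing.assert_allclose(cif.at(2, 2.0), 0.2)
        np.testing.assert_allclose(cif.at(1, 4.5), 0.5)
        np.testing.assert_allclose(cif.survival[-1], 0.3)

    def test_additivity_invariant(self, medium_trial):
        _, table = medium_trial
        df = table.data
        cif = estimate_cif(df["time"].to_numpy(), df["cause"].to_numpy())
        total = cif.survival + np.sum([cif.cif[k] for k in cif.cif], axis=0)
        np.testing.assert_allclose(total, 1.0, atol=1e-10)

    def test_monotone_steps(self, medium_trial):
        _, table = medium_trial
        df = table.data
        cif = estimate_cif(df["time"].to_numpy(), df["cause"].to_numpy())
        assert np.all(np.diff(cif.survival) <= 1e-15)
        for k in cif.cif:
            assert np.all(np.diff(cif.cif[k]) >= -1e-15)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            estimate_cif([1.0], [1], mask=[False])


class TestPHDiagnostic:
    def test_p_values_in_unit_interval(self, medium_trial):
        _, table = medium_trial
        res = CoxPH.from_study_table(table, DesignSpec("titer")).fit()
        diag = ph_test(res)
        assert ((diag.p_values >= 0) & (diag.p_values <= 1)).all()

    def test_detects_reversing_effect(self):
        # hazard ratio reverses mid-study: the slope test should fire often
        rng = np.random.default_rng(11)
        hits = 0
        reps = 40
        for _ in range(reps):
            n = 300
            x = rng.standard_normal(n)
            t_break = 1.0
            t1 = rng.exponential(1 / np.exp(1.2 * x))
            t = np.where(t1 < t_break, t1,
                         t_break + rng.exponential(1 / np.exp(-1.2 * x)))
            e = np.ones(n)
            res = CoxPH(t, e, x[:, None], names=["x"]).fit()
            if res.converged and ph_test(res).p_values["x"] < 0.05:
                hits += 1
        assert hits >= 0.8 * reps

    def test_too_few_events_rejected(self):
        res = CoxPH(np.array([1.0, 2.0, 3.0]), np.array([1.0, 0.0, 0.0]),
                    np.array([[0.1], [0.2], [-0.1]]), names=["x"]).fit()
        with pytest.raises(ValueError, match="events"):
            ph_test(res)


class TestModelTests:
    def test_identical_models_give_p_one(self, medium_trial):
        _, table = medium_trial
        res = CoxPH.from_study_table(table, DesignSpec("titer")).fit()
        lrt_p, _ = model_tests(res, res)
        assert lrt_p == 1.0

    def test_non_nested_rejected(self, medium_trial):
        _, table = medium_trial
        a = CoxPH.from_study_table(table, DesignSpec("titer")).fit()
        b = CoxPH.from_study_table(
            table, DesignSpec("titer", covariates=["subgroup"])
        ).fit()
        c_df = table.data
        other = CoxPH(c_df["time"].to_numpy(), (c_df["cause"] >= 1).astype(float),
                      c_df[["subgroup"]].to_numpy(dtype=float), names=["subgroup"]).fit()
        lrt_p, wald = model_tests(a, b)
        assert 0 <= lrt_p <= 1 and len(wald) == 2
        with pytest.raises(ValueError, match="nested"):
            model_tests(other, a)

    def test_strong_predictor_detected(self, medium_trial):
        _, table = medium_trial
        df = table.data
        null_fit = CoxPH(df["time"].to_numpy(), (df["cause"] >= 1).astype(float),
                         df[["subgroup"]].to_numpy(dtype=float), names=["subgroup"]).fit()
        full = CoxPH(df["time"].to_numpy(), (df["cause"] >= 1).astype(float),
                     df[["subgroup", "titer"]].to_numpy(dtype=float),
                     names=["subgroup", "titer"]).fit()
        lrt_p, _ = model_tests(null_fit, full)
        assert lrt_p < 1e-6
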