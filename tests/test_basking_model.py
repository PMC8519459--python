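import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import expit

from terrapin.basking_model import (
    ModelFit,
    SeparationError,
    StandardizationError,
    aggregate_weather_daily,
    backward_aic,
    build_design,
    fit_binomial,
    standardize,
)


def _sim_design(n, slopes, intercept=0.0, seed=0, n_individuals=1):
    """Bernoulli responses from a logistic model on standard-normal
    predictors."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "individual": np.repeat(
            [f"T{i}" for i in range(n_individuals)],
            int(np.ceil(n / n_individuals)))[:n],
    })
    logit = np.full(n, float(intercept))
    for term, beta in slopes.items():
        x = rng.normal(0, 1, n)
        df[term] = standardize(x)
        logit = logit + beta * df[term].to_numpy()
    df["response"] = rng.uniform(size=n) < expit(logit)
    df["response"] = df["response"].astype(int)
    return df


class TestStandardize:
    def test_closed_form(self):
        assert np.allclose(standardize([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_idempotent_with_unit_moments(self, seed):
        x = np.random.default_rng(seed).normal(3.0, 7.0, 100)
        z = standardize(x)
        assert abs(z.mean()) < 1e-10
        assert abs(np.var(z, ddof=1) - 1.0) < 1e-10
        assert np.allclose(standardize(z), z, atol=1e-10)

    def test_constant_raises(self):
        with pytest.raises(StandardizationError):
            standardize(np.full(10, 2.0))


class TestFitBinomial:
    def test_intercept_only_on_balanced_response_closed_form(self):
        n = 200
        df = pd.DataFrame({
            "individual": "T1",
            "response": np.tile([0, 1], n // 2),
        })
        fit = fit_binomial(df, terms=())
        assert fit.params["intercept"] == pytest.approx(0.0, abs=1e-8)
        assert fit.aic == pytest.approx(2.0 + 2.0 * n * np.log(2.0),
                                        rel=1e-10)

    def test_slope_recovered_within_two_se(self):
        df = _sim_design(1000, {"cloud": -2.5}, intercept=0.3, seed=11)
        fit = fit_binomial(df, terms=("cloud",))
        assert abs(fit.params["cloud"] - (-2.5)) <= 2 * fit.se["cloud"]

    def test_matches_direct_likelihood_maximisation(self):
        df = _sim_design(50, {"a": 1.0, "b": -0.8}, seed=5)
        fit = fit_binomial(df, terms=("a", "b"))
        X = np.column_stack([np.ones(50), df["a"], df["b"]])
        y = df["response"].to_numpy(dtype=float)

        def nll(beta):
            eta = X @ beta
            return np.sum(np.logaddexp(0.0, eta)) - float(y @ eta)

        res = minimize(nll, np.zeros(3), method="BFGS",
                       options={"gtol": 1e-10})
        oracle = dict(zip(("intercept", "a", "b"), res.x))
        for k, v in oracle.items():
            assert fit.params[k] == pytest.approx(v, abs=1e-6)
        assert fit.llf == pytest.approx(-res.fun, abs=1e-8)

    def test_per_individual_intercepts_absorb_identity(self):
        df = _sim_design(400, {"cloud": -1.5}, seed=3, n_individuals=4)
        fit = fit_binomial(df, terms=("cloud",))
        assert fit.individual_intercepts
        assert sum(k.startswith("intercept[") for k in fit.params) == 4
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.llf)

    def test_perfect_separation_names_the_term(self):
        df = pd.DataFrame({
            "individual": "T1",
            "response": [0] * 10 + [1] * 10,
            "sep": standardize(np.arange(20.0)),
        })
        with pytest.raises(SeparationError, match="sep"):
            fit_binomial(df, terms=("sep",))

    def test_single_class_response_rejected(self):
        df = pd.DataFrame({"individual": "T1", "response": np.ones(20,
                                                                   int),
                           "x": standardize(np.arange(20.0))})
        with pytest.raises(SeparationError):
            fit_binomial(df, terms=("x",))


class TestBackwardAic:
    def test_noise_usually_dropped_informative_always_kept(self):
        # a noise term survives elimination iff its LR statistic exceeds 2
        # (probability ~0.16 under the null), so count over several seeds
        kept_signal = dropped_noise = 0
        for seed in range(10):
            df = _sim_design(400, {"signal": 1.5, "noise": 0.0}, seed=seed)
            best, steps = backward_aic(df, ("noise", "signal"))
            kept_signal += "signal" in best.terms
            dropped_noise += "noise" not in best.terms
            assert best.aic <= steps[0][1]
        assert kept_signal == 10
        assert dropped_noise >= 6

    def test_single_informative_term_retained(self):
        df = _sim_design(400, {"signal": 1.5}, seed=2)
        best, _ = backward_aic(df, ("signal",))
        assert best.terms == ("signal",)

    def test_all_noise_tends_to_intercept_only(self):
        hits = 0
        for seed in range(10):
            df = _sim_design(300, {"n1": 0.0, "n2": 0.0}, seed=seed)
            best, _ = backward_aic(df, ("n1", "n2"))
            hits += best.terms == ()
        assert hits >= 5  # plurality of replicates

    def test_selected_aic_never_worse_than_full(self):
        df = _sim_design(300, {"a": 0.8, "b": 0.0, "c": 0.0}, seed=9)
        best, steps = backward_aic(df, ("a", "b", "c"))
        assert best.aic <= steps[0][1]
        assert isinstance(best, ModelFit)

    def test_generating_sign_pattern_recovered(self):
        slopes = {"cloud": -2.5, "day_length": 0.75, "rain": -0.5}
        good = 0
        for seed in range(8):
            df = _sim_design(1000, slopes, intercept=0.5, seed=100 + seed)
            fit = fit_binomial(df, tuple(slopes))
            good += all(np.sign(fit.params[t]) == np.sign(b)
                        for t, b in slopes.items())
        assert good >= 7


class TestBuildDesign:
    def _inputs(self, n_days=30, n_ind=3):
        rng = np.random.default_rng(0)
        budgets = pd.DataFrame({
            "individual": np.repeat([f"T{i}" for i in range(n_ind)], n_days),
            "cycle_date": np.tile(np.arange(n_days), n_ind),
            "midday_h": rng.choice([0.0, 5.0], n_days * n_ind),
        })
        daily = pd.DataFrame({
            "day": np.arange(n_days),
            "t_air": rng.normal(18, 4, n_days),
            "cloud": rng.uniform(0, 1, n_days),
            "rain": rng.exponential(1.0, n_days),
            "day_length": rng.normal(14, 0.5, n_days),
        })
        return budgets, daily

    def test_row_count_and_standardization(self):
        budgets, daily = self._inputs()
        design = build_design(budgets, daily)
        assert len(design) == len(budgets)
        for term in ("t_air", "cloud", "rain", "day_length"):
            assert abs(design[term].mean()) < 1e-10
            assert abs(design[term].var(ddof=1) - 1.0) < 1e-10
        assert set(design["response"].unique()) <= {0, 1}

    def test_all_midday_present_gives_all_ones(self):
        budgets, daily = self._inputs()
        budgets["midday_h"] = 4.0
        design = build_design(budgets, daily)
        assert (design["response"] == 1).all()

    def test_weather_aggregation_mean_and_sum(self):
        weather = pd.DataFrame({
            "time": np.arange(0.0, 2 * 86400.0, 10800.0),
            "t_air_mulhouse": 15.0,
            "cloud_frac": np.concatenate([np.full(8, 0.5),
                                          np.full(8, 1.0)]),
            "rain_mm": 1.0,
        })
        sun = pd.DataFrame({"date": [0, 1], "sunrise": [21600.0, 108000.0],
                            "sunset": [72000.0, 158400.0]})
        daily = aggregate_weather_daily(weather, sun)
        assert daily.loc[0, "cloud"] == pytest.approx(0.5)
        assert daily.loc[1, "cloud"] == pytest.approx(1.0)
        assert daily.loc[0, "rain"] == pytest.approx(8.0)  # sum of 3-h rows
        assert daily.loc[0, "day_length"] == pytest.approx(14.0)


def test_coefficient_table_layout():
    from terrapin.basking_model import coefficient_table

    df = _sim_design(300, {"cloud": -1.0}, seed=4)
    fit = fit_binomial(df, terms=("cloud",))
    table = coefficient_table(fit)
    assert list(table.columns) == ["term", "estimate", "se", "z"]
    row = table.set_index("term").loc["cloud"]
    assert row["z"] == pytest.approx(row["estimate"] / row["se"])
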