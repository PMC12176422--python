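"""Seminested AICc machinery, GMM representative values, EMM, Kaplan-Meier."""

import warnings

import numpy as np
import pandas as pd
import pytest

from tauspread.model_selection import (ComparabilityError, ModelFit,
                                       RepresentativeValues, aicc,
                                       aicc_compare, emm_trajectories,
                                       fit_baseline_set, fit_longitudinal_set,
                                       fit_survival_set, gmm_low_high,
                                       km_median_split)


def _fit(name, loglik, k=3, n=100, n_obs=100):
    return ModelFit(name=name, k=k, loglik=loglik, n=n, n_obs=n_obs)


def _cohort_frame(rng, n=120):
    df = pd.DataFrame({
        "participant_id": [f"p{i:03d}" for i in range(n)],
        "TI": rng.normal(1.2, 0.2, n),
        "TSS": rng.uniform(0, 0.4, n),
        "age": rng.normal(70, 8, n),
        "sex": rng.integers(0, 2, n),
        "education": rng.normal(16, 2, n),
    })
    df["knight_pacc"] = -1.5 * df["TI"] + rng.normal(0, 0.5, n)
    return df


class TestAicc:
    def test_formula(self):
        # AICc = -2 ll + 2K + 2K(K+1)/(n-K-1)
        assert aicc(-100.0, 5, 50) == pytest.approx(200 + 10 + 60 / 44)

    def test_undefined_when_n_too_small(self):
        with pytest.warns(UserWarning):
            assert aicc(-10.0, 5, 6) == np.inf

    def test_weights_for_delta_zero_two(self):
        # by hand: exp(-1)/(1+exp(-1)) = 0.731, 0.269
        table = aicc_compare([_fit("A", -50.0), _fit("B", -51.0)])
        assert np.allclose(table["weight"], [0.731, 0.269], atol=5e-4)

    def test_equal_aicc_gives_symmetric_weights(self):
        table = aicc_compare([_fit("A", -50.0), _fit("B", -50.0)])
        assert np.allclose(table["weight"], [0.5, 0.5])
        assert table["comparable"].all()

    def test_single_model(self):
        table = aicc_compare([_fit("only", -10.0)])
        assert table["weight"].iloc[0] == 1.0
        assert table["delta_aicc"].iloc[0] == 0.0

    def test_nominated_has_delta_zero_and_weights_sum_to_one(self, rng):
        fits = [_fit(s, -50 - 10 * rng.random()) for s in "ABCD"]
        table = aicc_compare(fits)
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert table.loc[table["nominated"], "delta_aicc"].iloc[0] == 0.0
        assert (table["AICc"].diff().dropna() >= 0).all()
        assert set(table.loc[table["comparable"], "model"]) == set(
            table.loc[table["delta_aicc"] < 2, "model"])

    def test_mixed_subsets_rejected(self):
        with pytest.raises(ComparabilityError):
            aicc_compare([_fit("A", -50.0, n_obs=100),
                          _fit("B", -50.0, n_obs=90)])


class TestParameterCounts:
    def test_baseline_additive_k_is_seven(self, rng):
        fits = fit_baseline_set(_cohort_frame(rng), "knight_pacc")
        k = {f.name: f.k for f in fits}
        assert k == {"Covariate": 5, "TI": 6, "TSS": 6, "Additive": 7}

    def test_longitudinal_additive_k_is_sixteen(self, rng):
        df = _cohort_frame(rng, n=60)
        long = df.loc[df.index.repeat(3)].reset_index(drop=True)
        long["visit_time"] = np.tile([0.0, 1.0, 2.0], 60)
        long["knight_pacc"] += 0.1 * long["visit_time"] * np.random.default_rng(0).normal(size=len(long))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = fit_longitudinal_set(long, "knight_pacc")
        k = {f.name: f.k for f in fits}
        assert k == {"Covariate": 12, "TI": 14, "TSS": 14, "Additive": 16}
        assert all(f.n == 60 for f in fits)  # subjects, not observations

    def test_cox_ti_model_k_is_four(self, rng):
        df = _cohort_frame(rng, n=150)
        r = np.random.default_rng(5)
        raw = r.exponential(1 / (0.1 * np.exp(2 * (df["TI"] - 1.2))))
        df["time"] = np.minimum(raw, 5.0)
        df["status"] = (raw <= 5.0).astype(int)
        fits = fit_survival_set(df)
        k = {f.name: f.k for f in fits}
        assert k == {"Covariate": 3, "TI": 4, "TSS": 4, "Additive": 5}

    def test_identical_complete_case_subset_across_members(self, rng):
        df = _cohort_frame(rng)
        df.loc[:5, "TSS"] = np.nan  # missing TSS must shrink ALL members
        fits = fit_baseline_set(df, "knight_pacc")
        assert len({f.n_obs for f in fits}) == 1
        assert fits[0].n_obs == len(df) - 6

    def test_zero_events_rejected(self, rng):
        df = _cohort_frame(rng, n=30)
        df["time"], df["status"] = 5.0, 0
        with pytest.raises(ValueError, match="event"):
            fit_survival_set(df)


class TestNoisePredictorPenalty:
    def test_pure_noise_predictor_raises_aicc_on_average(self):
        """The 2K penalty makes noise predictors lose in expectation."""
        deltas = []
        for rep in range(40):
            r = np.random.default_rng(rep)
            df = _cohort_frame(r, n=150)
            df["knight_pacc"] = r.normal(size=150)  # none of TI/TSS matter
            fits = {f.name: f for f in fit_baseline_set(df, "knight_pacc")}
            deltas.append(fits["TI"].aicc - fits["Covariate"].aicc)
        assert np.mean(deltas) > 0


class TestCoxPartialLikelihood:
    def test_matches_hand_computed_partial_likelihood(self):
        """Evaluate the Efron/Breslow product by hand on a 5-subject toy."""
        df = pd.DataFrame({
            "time": [1.0, 2.0, 3.0, 4.0, 5.0],
            "status": [1, 1, 0, 1, 0],
            "x": [0.5, -0.2, 0.1, 0.8, -0.5],
        })
        from lifelines import CoxPHFitter

        cph = CoxPHFitter().fit(df, "time", "status")
        beta = float(cph.params_.iloc[0])
        # no ties: partial loglik = sum over events of
        # [beta x_i - log(sum of exp(beta x_j) over the risk set)]
        ll = 0.0
        for _, row in df[df["status"] == 1].iterrows():
            risk = df[df["time"] >= row["time"]]
            ll += beta * row["x"] - np.log(np.exp(beta * risk["x"]).sum())
        assert cph.log_likelihood_ == pytest.approx(ll, abs=1e-8)


class TestGmmLowHigh:
    def test_low_below_high_contract(self, rng):
        values = np.r_[rng.normal(1.1, 0.05, 100), rng.normal(1.8, 0.1, 100)]
        rep = gmm_low_high(values, metric="TI", seed=0)
        assert rep.low < rep.high
        assert values.min() <= rep.low and rep.high <= values.max()

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            gmm_low_high(np.full(50, 1.3))

    def test_too_few_values_rejected(self, rng):
        with pytest.raises(ValueError, match="20"):
            gmm_low_high(rng.normal(size=10))

    def test_deterministic_given_seed(self, rng):
        values = np.r_[rng.normal(1.1, 0.05, 200), rng.normal(1.8, 0.1, 200)]
        a = gmm_low_high(values, seed=3)
        b = gmm_low_high(values, seed=3)
        assert (a.low, a.high) == (b.low, b.high)


class TestEmm:
    @staticmethod
    def _fit(gamma=0.0, seed=0):
        from tauspread.lmm import RandomSlopeLMM

        r = np.random.default_rng(seed)
        n, v = 200, 4
        t = np.tile(np.arange(v, dtype=float), n)
        ti = np.repeat(r.normal(1.2, 0.3, n), v)
        age = np.repeat(r.normal(70, 8, n), v)
        y = (-0.5 * ti + gamma * ti * t - 0.01 * t
             + np.repeat(r.normal(0, 0.3, n), v)
             + r.normal(0, 0.2, n * v))
        df = pd.DataFrame({"y": y, "visit_time": t, "TI": ti, "age": age,
                           "participant_id": np.repeat(np.arange(n), v)})
        return RandomSlopeLMM().fit(df, "y", ["TI", "age", "visit_time",
                                              "TI:visit_time",
                                              "age:visit_time"]), df

    def test_zero_interaction_gives_equal_slopes(self):
        fit, df = self._fit(gamma=0.0)
        fit.params[fit.names.index("TI:visit_time")] = 0.0
        rep = RepresentativeValues(metric="TI", low=1.0, high=1.6)
        emm = emm_trajectories(fit, "TI", rep, {"age": 70.0})
        assert emm["slope"].iloc[0] == pytest.approx(emm["slope"].iloc[1])

    def test_slope_gap_is_coefficient_times_value_gap(self):
        fit, df = self._fit(gamma=-0.08, seed=1)
        rep = RepresentativeValues(metric="TI", low=1.0, high=1.6)
        emm = emm_trajectories(fit, "TI", rep, {"age": 70.0})
        coef = fit.params[fit.names.index("TI:visit_time")]
        gap = emm.loc[emm["level"] == "high", "slope"].iloc[0] - \
            emm.loc[emm["level"] == "low", "slope"].iloc[0]
        assert gap == pytest.approx(coef * 0.6, abs=1e-12)
        # and the fitted interaction is near the truth
        assert coef == pytest.approx(-0.08, abs=0.02)

    def test_extrapolation_warns(self):
        fit, df = self._fit()
        rep = RepresentativeValues(metric="TI", low=0.0, high=9.0)
        with pytest.warns(UserWarning, match="extrapolation"):
            emm_trajectories(fit, "TI", rep, {"age": 70.0},
                             data_range=(0.5, 2.5))


class TestKaplanMeier:
    def test_hand_product_limit(self):
        df = pd.DataFrame({"time": [1, 2, 3, 4, 5],
                           "status": [1, 1, 0, 1, 0],
                           "TI": [1.0] * 5})
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter().fit(df["time"], df["status"])
        # S(2) = (4/5)(3/4) = 0.6 by the product-limit definition
        assert km.survival_function_at_times(2.0).iloc[0] == pytest.approx(0.6)

    def test_no_events_survival_identically_one(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0],
                           "status": [0, 0, 0, 0],
                           "TI": [1.0, 1.1, 1.3, 1.4]})
        with pytest.warns(UserWarning, match="no events"):
            curves, cut, fitters = km_median_split(df, "TI")
        assert (curves["survival"] == 1.0).all()

    def test_median_split_sizes_and_tie_rule(self):
        df = pd.DataFrame({"time": [1, 2, 3, 4], "status": [1, 0, 1, 0],
                           "TI": [1.0, 2.0, 3.0, 4.0]})
        curves, cut, fitters = km_median_split(df, "TI")
        assert cut == 2.5
        assert fitters["low"].event_observed.shape[0] == 2
        assert fitters["high"].event_observed.shape[0] == 2
        # ties at the median go to the low group
        df["TI"] = [1.0, 2.5, 2.5, 4.0]
        _, cut, fitters = km_median_split(df, "TI")
        assert fitters["low"].event_observed.shape[0] == 3

    def test_matches_brute_force_risk_sets(self, rng):
        times = rng.integers(1, 8, size=12).astype(float)
        status = rng.integers(0, 2, size=12)
        df = pd.DataFrame({"time": times, "status": status,
                           "TI": rng.normal(1.2, 0.2, 12)})
        if status.sum() == 0:
            status[0] = 1
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter().fit(times, status)
        for t in np.unique(times):
            s = 1.0
            for u in sorted(np.unique(times[times <= t])):
                d = int(((times == u) & (status == 1)).sum())
                at_risk = int((times >= u).sum())
                s *= 1 - d / at_risk
            assert km.survival_function_at_times(t).iloc[0] == pytest.approx(s)
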