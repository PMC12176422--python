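"""Synthetic cohort generator: geometry, tau truth, cognition, conversion."""

import numpy as np
import pandas as pd
import pytest

from tauspread.lmm import RandomSlopeLMM
from tauspread.quantify import NormativeAtlas, compute_tss
from tauspread.simulate import (COMPOSITES, MASK_REGIONS, SPREAD_REGIONS,
                                TI_REGIONS, ConfigError, SimulationConfig,
                                make_region_label_map, simulate_cognition,
                                simulate_cohort, simulate_conversion,
                                simulate_volumes)
from tauspread.stats import wilcoxon_mw
from tauspread.volumes import BACKGROUND_CODE


class TestRegionLabelMap:
    def test_partition_covers_grid_with_substantial_regions(self):
        labels, codes = make_region_label_map(SimulationConfig(grid_shape=(8, 8, 8)))
        assert labels.shape == (8, 8, 8)
        # every voxel has exactly one label; named regions are non-trivial
        assert set(np.unique(labels)) == set(codes.values()) | {BACKGROUND_CODE}
        for name, code in codes.items():
            assert (labels == code).sum() >= 8, name
        assert set(codes) == set(TI_REGIONS) | set(SPREAD_REGIONS)

    def test_deterministic(self):
        cfg = SimulationConfig(grid_shape=(8, 8, 8))
        a, _ = make_region_label_map(cfg)
        b, _ = make_region_label_map(cfg)
        assert np.array_equal(a, b)

    def test_grid_too_small_names_axis(self):
        with pytest.raises(ConfigError, match="axis 0"):
            make_region_label_map(SimulationConfig(grid_shape=(2, 8, 8)))
        with pytest.raises(ConfigError, match="axis 2"):
            make_region_label_map(SimulationConfig(grid_shape=(8, 8, 2)))


class TestSimulateVolumes:
    def test_null_participant_distributed_like_young_controls(self):
        cfg = SimulationConfig(grid_shape=(12, 12, 12), seed=5,
                               burden_by_stage={"OC": (0.0, 0.0)},
                               spread_by_stage={"OC": (0.0, 0.0)})
        vols, truth = simulate_volumes(cfg, ["YC"] * 40 + ["OC"])
        null = vols["sub-0040"]
        yc = np.stack([vols[f"sub-{i:04d}"].suvr for i in range(40)])
        se = yc.std(axis=0).mean() / np.sqrt(40)
        assert abs(null.suvr.mean() - yc.mean()) < 3 * se

    def test_full_spread_at_high_elevation_saturates_tss(self):
        cfg = SimulationConfig(grid_shape=(10, 10, 10), seed=11,
                               burden_by_stage={"Symptomatic": (10.0, 0.0)},
                               spread_by_stage={"Symptomatic": (1.0, 0.0)},
                               spread_intensity=10.0)
        vols, truth = simulate_volumes(cfg, ["YC"] * 30 + ["Symptomatic"])
        atlas = NormativeAtlas().fit([vols[f"sub-{i:04d}"] for i in range(30)])
        v = vols["sub-0030"]
        z = atlas.transform(v)
        frag = compute_tss(z, v.labels, v.region_codes, MASK_REGIONS)
        # brute-force count over the mask
        mask = np.isin(v.labels, [v.region_codes[r] for r in MASK_REGIONS])
        brute = (z[mask] > 1.96).sum() / mask.sum()
        assert frag.TSS == brute
        assert frag.TSS > 0.99

    def test_seed_determinism(self):
        cfg = SimulationConfig(grid_shape=(8, 8, 8), seed=3)
        v1, t1 = simulate_volumes(cfg, ["YC", "OC", "Symptomatic"])
        v2, t2 = simulate_volumes(cfg, ["YC", "OC", "Symptomatic"])
        v3, _ = simulate_volumes(cfg.with_(seed=4), ["YC", "OC", "Symptomatic"])
        for pid in v1:
            assert np.array_equal(v1[pid].suvr, v2[pid].suvr)
        pd.testing.assert_frame_equal(t1, t2)
        assert not np.array_equal(v1["sub-0001"].suvr, v3["sub-0001"].suvr)

    def test_unknown_stage_rejected(self):
        with pytest.raises(ConfigError, match="stage"):
            simulate_volumes(SimulationConfig(grid_shape=(8, 8, 8)), ["Braak6"])

    def test_stage_monotonicity_of_measured_metrics(self):
        """Mean measured TI and TSS strictly increase OC < Pre < Symptomatic."""
        from tauspread.pipeline import PipelineConfig, quantify_stage

        means = {s: {"TI": [], "TSS": []} for s in ("OC", "Preclinical",
                                                    "Symptomatic")}
        for rep in range(50):
            cfg = SimulationConfig(grid_shape=(8, 8, 8), n_young_controls=10,
                                   n_per_stage={"OC": 8, "Preclinical": 8,
                                                "Symptomatic": 8},
                                   visits_per_subject=1, seed=1000 + rep)
            cohort = simulate_cohort(cfg)
            _, metrics = quantify_stage(cohort, PipelineConfig(simulation=cfg))
            merged = metrics.merge(cohort.participants, on="participant_id")
            for s, g in merged.groupby("stage_true"):
                means[s]["TI"].append(g["TI"].mean())
                means[s]["TSS"].append(g["TSS"].mean())
        for m in ("TI", "TSS"):
            oc, pre, sym = (np.mean(means[s][m]) for s in
                            ("OC", "Preclinical", "Symptomatic"))
            assert oc < pre < sym, m


class TestSimulateCognition:
    @staticmethod
    def _truth(n, rng):
        return pd.DataFrame({
            "participant_id": [f"sub-{i:04d}" for i in range(n)],
            "stage_true": ["OC"] * n,
            "burden": rng.normal(2, 1, n).clip(0),
            "spread_achieved": rng.uniform(0, 0.4, n),
        })

    def test_null_effects_give_flat_trajectories(self, rng):
        cfg = SimulationConfig(burden_effect=0, spread_effect=0,
                               burden_slope_effect=0, spread_slope_effect=0,
                               visits_per_subject=4, seed=21)
        visits = simulate_cognition(self._truth(300, rng), cfg)
        fit = RandomSlopeLMM(reml=True).fit(visits, "episodic", ["visit_time"])
        slope = fit.params[fit.names.index("visit_time")]
        se = fit.se()[fit.names.index("visit_time")]
        assert abs(slope) < 2 * se

    def test_slope_effect_linear_arithmetic(self, rng):
        # gamma_b = -0.1/yr and a 1-unit burden gap imply a 0.5-unit
        # composite gap after 5 years, exactly, in the noise-free limit
        cfg = SimulationConfig(effects={"episodic": (0.0, 0.0, -0.1, 0.0)},
                               noise_sd=1e-9, ranef_intercept_sd=1e-9,
                               ranef_slope_sd=1e-9, visits_per_subject=2,
                               follow_up_years=5.0, seed=22)
        truth = self._truth(200, rng)
        visits = simulate_cognition(truth, cfg)
        z = (truth["burden"] - truth["burden"].mean()) / truth["burden"].std(ddof=0)
        end = visits[visits["visit_time"] == 5.0].set_index("participant_id")
        start = visits[visits["visit_time"] == 0.0].set_index("participant_id")
        change = (end["episodic"] - start["episodic"]).to_numpy()
        gap = np.polyfit(z.to_numpy(), change, 1)[0]
        assert gap == pytest.approx(-0.5, abs=1e-6)

    def test_slope_effect_recovery_by_mixed_model(self, rng):
        """Fitting the generating mixed model recovers the tau-slope effect."""
        est = []
        for rep in range(30):
            cfg = SimulationConfig(effects={"working": (0.0, 0.0, -0.1, 0.0)},
                                   visits_per_subject=4, seed=3000 + rep)
            truth = self._truth(400, np.random.default_rng(rep))
            truth["TI"] = (truth["burden"] - truth["burden"].mean()) / \
                truth["burden"].std(ddof=0)
            truth["age"] = 70.0 + np.random.default_rng(rep + 1).normal(0, 8, 400)
            visits = simulate_cognition(truth, cfg)
            df = visits.merge(truth[["participant_id", "TI", "age"]],
                              on="participant_id")
            fit = RandomSlopeLMM().fit(df, "working",
                                       ["TI", "age", "visit_time",
                                        "TI:visit_time", "age:visit_time"])
            est.append(fit.params[fit.names.index("TI:visit_time")])
        assert np.mean(est) == pytest.approx(-0.1, abs=0.02)

    def test_zero_visits_rejected(self, rng):
        with pytest.raises(ConfigError):
            SimulationConfig(visits_per_subject=0)
        with pytest.raises(ConfigError):
            SimulationConfig(follow_up_years=-1.0)

    def test_null_calibration_of_downstream_group_test(self):
        """With all effects zero, a stage comparison rejects at ~5%."""
        rejections = 0
        n_rep = 500
        for rep in range(n_rep):
            r = np.random.default_rng(50_000 + rep)
            cfg = SimulationConfig(burden_effect=0, spread_effect=0,
                                   burden_slope_effect=0,
                                   spread_slope_effect=0,
                                   visits_per_subject=1, seed=60_000 + rep)
            truth = pd.DataFrame({
                "participant_id": [f"sub-{i:04d}" for i in range(60)],
                "stage_true": ["OC"] * 30 + ["Preclinical"] * 30,
                "burden": np.r_[r.normal(0.5, 0.5, 30), r.normal(2, 1, 30)].clip(0),
                "spread_achieved": r.uniform(0, 0.3, 60),
            })
            visits = simulate_cognition(truth, cfg)
            base = visits.merge(truth, on="participant_id")
            x = base.loc[base["stage_true"] == "OC", "attention"]
            y = base.loc[base["stage_true"] == "Preclinical", "attention"]
            if wilcoxon_mw(x, y)[1] < 0.05:
                rejections += 1
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)


class TestSimulateConversion:
    @staticmethod
    def _truth(n, rng, stage="OC"):
        return pd.DataFrame({
            "participant_id": [f"sub-{i:04d}" for i in range(n)],
            "stage_true": [stage] * n,
            "burden": rng.normal(1.5, 1.0, n).clip(0),
            "cdr_baseline": 0.0,
        })

    def test_null_hazard_calibration(self):
        """Zero log-hazard: the low/high-TI log-rank test rejects at ~5%."""
        from lifelines.statistics import logrank_test

        rejections, n_rep = 0, 200
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            cfg = SimulationConfig(conversion_log_hazard_per_TI=0.0,
                                   conversion_base_hazard=0.1,
                                   follow_up_years=5.0, seed=70_000 + rep)
            truth = self._truth(60, r)
            surv = simulate_conversion(truth, cfg)
            surv = surv.merge(truth, on="participant_id")
            low = surv["burden"] <= surv["burden"].median()
            res = logrank_test(surv.loc[low, "time"], surv.loc[~low, "time"],
                               surv.loc[low, "status"], surv.loc[~low, "status"])
            rejections += res.p_value < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.04)

    def test_zero_follow_up_all_censored(self, rng):
        cfg = SimulationConfig(follow_up_years=0.0, seed=1)
        surv = simulate_conversion(self._truth(20, rng), cfg)
        assert (surv["time"] == 0).all()
        assert (surv["status"] == 0).all()

    def test_symptomatic_participants_excluded(self, rng):
        truth = pd.concat([self._truth(10, rng),
                           self._truth(5, rng, "Symptomatic").assign(
                               cdr_baseline=0.5)], ignore_index=True)
        truth["participant_id"] = [f"sub-{i:04d}" for i in range(15)]
        surv = simulate_conversion(truth, SimulationConfig(seed=2))
        assert len(surv) == 10


class TestCohortDeterminism:
    def test_identical_config_bit_identical_cohort(self, small_config):
        a = simulate_cohort(small_config)
        b = simulate_cohort(small_config)
        pd.testing.assert_frame_equal(a.participants, b.participants)
        pd.testing.assert_frame_equal(a.visits, b.visits)
        pd.testing.assert_frame_equal(a.raw_tasks, b.raw_tasks)
        pd.testing.assert_frame_equal(a.survival, b.survival)
        for pid in a.volumes:
            assert np.array_equal(a.volumes[pid].suvr, b.volumes[pid].suvr)

    def test_visit_times_strictly_increasing(self, small_cohort):
        g = small_cohort.visits.groupby("participant_id")["visit_time"]
        assert (small_cohort.visits["visit_time"] >= 0).all()
        assert (g.apply(lambda s: bool((np.diff(s) > 0).all()))).all()

    def test_composite_columns_present(self, small_cohort):
        assert set(COMPOSITES) <= set(small_cohort.visits.columns)
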