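"""Synthetic-study generator: kernels, detection patterns, yields, curves."""

import numpy as np
import pandas as pd
import pytest

from rbstscreen.design import StudyDesign, build_dose_schedule
from rbstscreen.simulate import (GeneProfile, YieldModel, CurveParams,
                                 SimulationConfig, default_profiles,
                                 response_kernel, simulate_expression,
                                 simulate_yield, simulate_curves)
from rbstscreen.expression import REFERENCE_GENES


def profile_by_name(name):
    return {p.gene: p for p in default_profiles()}[name]


class TestResponseKernel:
    def test_peak_gives_full_amplitude(self):
        p = GeneProfile("g", responsive=True, amplitude=2.5, onset_days=1,
                        peak_day=8, washout_tau=6)
        assert response_kernel(8.0, p) == pytest.approx(3.5)

    def test_nonresponsive_is_identity(self):
        p = GeneProfile("g", responsive=False)
        for tau in (0, 5, 30, None):
            assert response_kernel(tau, p) == 1.0

    def test_pre_onset_and_pre_dose_are_silent(self):
        p = GeneProfile("g", responsive=True, amplitude=3, onset_days=2,
                        peak_day=8, washout_tau=6)
        assert response_kernel(None, p) == 1.0
        assert response_kernel(1.0, p) == 1.0

    @pytest.mark.parametrize("gene", ["IGF1R", "CCND1", "TNF", "IL1B"])
    def test_washout_by_28_days(self, gene):
        p = profile_by_name(gene)
        g28 = (response_kernel(28.0, p) - 1.0) / p.amplitude
        assert g28 < 0.05

    def test_unimodal_shape(self):
        p = profile_by_name("CCND1")
        taus = np.linspace(0, 28, 200)
        eff = response_kernel(taus, p)
        peak_idx = int(np.argmax(eff))
        assert np.all(np.diff(eff[:peak_idx + 1]) >= -1e-12)
        assert np.all(np.diff(eff[peak_idx:]) <= 1e-12)

    def test_igf1r_fast_onset(self):
        # near-full effect one day after injection
        p = profile_by_name("IGF1R")
        assert response_kernel(1.0, p) > 1 + 0.9 * p.amplitude


class TestExpression:
    def test_deterministic_under_seed(self, sim_config):
        a = simulate_expression(sim_config)
        b = simulate_expression(sim_config)
        pd.testing.assert_frame_equal(a, b)

    def test_detection_patterns(self, sim_config):
        e = simulate_expression(sim_config)
        never = e[e.gene.isin(["IGFBP3", "IGFBP5", "COL3A1", "ESR2"])]
        assert not never.detected.any()
        # IGF1 detection is per animal: each animal all-or-nothing
        igf1 = e[e.gene == "IGF1"]
        per_animal = igf1.groupby("animal").detected.nunique()
        assert (per_animal == 1).all()
        # CTNNAL1 detected in most samples but with dropout holes
        ct = e[e.gene == "CTNNAL1"]
        assert 0.5 < ct.detected.mean() < 1.0

    def test_controls_and_predose_days_carry_no_effect(self, small_design):
        """With noise silenced, control animals and pre-dose treated samples
        sit exactly on their baseline."""
        quiet = tuple(
            GeneProfile(p.gene, baseline_log10_mean=p.baseline_log10_mean,
                        baseline_log10_sd=0.0, animal_sd=0.0,
                        responsive=p.responsive, onset_days=p.onset_days,
                        peak_day=p.peak_day, washout_tau=p.washout_tau,
                        amplitude=p.amplitude, rise_tau_days=p.rise_tau_days,
                        detection="always", is_reference=p.is_reference)
            for p in default_profiles() if p.detection != "never")
        cfg = SimulationConfig(seed=3, design=small_design, profiles=quiet,
                               loading_sd=0.0)
        e = simulate_expression(cfg)
        base = {p.gene: 10 ** p.baseline_log10_mean for p in quiet}
        ctrl = e[e.group == "control"]
        assert np.allclose(ctrl.abundance,
                           ctrl.gene.map(base), rtol=1e-12)
        pre = e[(e.group == "rbst") & (e.day < 0)]
        assert np.allclose(pre.abundance, pre.gene.map(base), rtol=1e-12)

    def test_igf1r_day1_group_ratio_matches_field_observation(self):
        """Day-1 treated/control group-mean ratio of normalized IGF1R
        abundance ~3.9 (0.348 vs 0.0898), within +-30% over replicates."""
        ratios = []
        for seed in range(60):
            e = simulate_expression(SimulationConfig(seed=seed))
            refs = e[e.gene.isin(REFERENCE_GENES)].pivot(
                index="sample", columns="gene", values="abundance")
            geo = np.exp(np.log(refs).mean(axis=1))
            d1 = e[(e.gene == "IGF1R") & (e.day == 1)].copy()
            d1["rel"] = d1.abundance / d1["sample"].map(geo)
            ratios.append(d1[d1.group == "rbst"].rel.mean()
                          / d1[d1.group == "control"].rel.mean())
        assert 3.9 * 0.7 <= np.mean(ratios) <= 3.9 * 1.3


class TestYield:
    def test_no_boost_no_imbalance_centers_on_zero(self, small_design):
        ym = YieldModel(treatment_boost=0.0, treated_scale=1.0)
        diffs = []
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, design=small_design,
                                   yield_model=ym)
            y = simulate_yield(cfg)
            daily = y.pivot_table(index="day", columns="group", values="kg")
            diffs.append((100 * (daily["rbst"] - daily["control"])
                          / daily["control"]).mean())
        assert abs(np.mean(diffs)) < 10.0

    def test_noiseless_single_animal_is_exact_wood_curve(self):
        d = StudyDesign(n_control=1, n_treated=0, sampling_days=(0,))
        ym = YieldModel(noise_sd=0.0, animal_scale_sd=0.0,
                        treatment_boost=0.0, treated_scale=1.0)
        cfg = SimulationConfig(seed=0, design=d, yield_model=ym,
                               dim_at_first_dose=(67.0, 75.0))
        y = simulate_yield(cfg)
        t = y.day.to_numpy() + 75.0
        expected = ym.wood_a * t ** ym.wood_b * np.exp(-ym.wood_c * t)
        assert np.allclose(y.kg, expected, rtol=1e-12)

    def test_deterministic_under_seed(self, sim_config):
        pd.testing.assert_frame_equal(simulate_yield(sim_config),
                                      simulate_yield(sim_config))


class TestCurves:
    def test_exponential_limit(self):
        """No noise, no baseline, huge plateau, unit session factor:
        fluorescence is exactly X0 * E^cycle."""
        d = StudyDesign(n_control=1, n_treated=0, sampling_days=(0,))
        profiles = (GeneProfile("g", baseline_log10_mean=0.0,
                                baseline_log10_sd=0.0, animal_sd=0.0),)
        cp = CurveParams(default_efficiency=1.9, plateau_k=1e30,
                         baseline=0.0, baseline_jitter_sd=0.0, noise_sd=0.0,
                         x0_scale=1e-4, n_replicates=1)
        cfg = SimulationConfig(seed=0, design=d, profiles=profiles,
                               curve_params=cp, loading_sd=0.0,
                               session_factor_sd=0.0)
        e = simulate_expression(cfg)
        curves = simulate_curves(e, cfg)
        c = curves.cycle.to_numpy()
        assert np.allclose(curves.fluorescence, 1e-4 * 1.9 ** c, rtol=1e-9)

    def test_undetected_rows_are_baseline_only(self, sim_config):
        e = simulate_expression(sim_config)
        und = e[~e.detected].head(3)
        curves = simulate_curves(und, sim_config)
        cp = sim_config.curve_params
        for _, g in curves.groupby("well"):
            rise = g.fluorescence.max() - g.fluorescence.median()
            assert rise < 3 * (cp.noise_sd + cp.baseline_jitter_sd)

    def test_plate_scale_well_count(self):
        """18 genes x 56 samples x 3 replicates = 3024 wells."""
        d = StudyDesign(n_control=2, n_treated=5,
                        sampling_days=tuple(range(8)))  # 56 samples
        cfg = SimulationConfig(seed=0, design=d)
        e = simulate_expression(cfg)
        assert e["sample"].nunique() == 56
        curves = simulate_curves(e, cfg)
        assert curves.well.nunique() == 18 * 56 * 3

    def test_deterministic_under_seed(self, sim_config):
        e = simulate_expression(sim_config)
        sub = e.head(20)
        pd.testing.assert_frame_equal(simulate_curves(sub, sim_config),
                                      simulate_curves(sub, sim_config))
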