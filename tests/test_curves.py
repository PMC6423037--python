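"""Curve quantification against generating-parameter oracles."""

import numpy as np
import pandas as pd
import pytest

from rbstscreen.curves import (AmplificationCurve, CurveFit,
                               correct_baseline, find_window_of_linearity,
                               fit_sample_efficiency, fit_curve,
                               summarize_amplicon_efficiency, quantify_n0,
                               quantify_plate, AmpliconSummary,
                               OK, NO_AMPLIFICATION, POOR_FIT)
from .conftest import logistic_curve


def make(f, well="w", sample="s", gene="g"):
    return AmplificationCurve(well, sample, gene, np.asarray(f, dtype=float))


class TestBaseline:
    def test_recovers_known_offset(self):
        f = 100.0 + 0.001 * 2.0 ** np.arange(1, 41.0)
        b, corrected, flag = correct_baseline(make(f))
        assert flag == OK
        assert b == pytest.approx(100.0, rel=0.01)

    def test_zero_baseline_exponential(self):
        f = 0.001 * 2.0 ** np.arange(1, 41.0)
        b, corrected, flag = correct_baseline(make(f))
        assert flag == OK
        assert abs(b) < 0.01 * f[6]

    def test_flat_curve_flags_no_amplification(self, rng):
        f = 50.0 + rng.normal(0, 0.5, 40)
        b, corrected, flag = correct_baseline(make(f))
        assert flag == NO_AMPLIFICATION
        assert b == pytest.approx(np.median(f))

    def test_noisy_logistic_baseline_within_one_percent(self, rng):
        f = logistic_curve(1e-4, 1.9, rng=rng)
        b, _, flag = correct_baseline(make(f))
        assert flag == OK
        assert b == pytest.approx(100.0, rel=0.01)


class TestWindow:
    def test_pure_exponential_window_is_log_linear(self):
        f = logistic_curve(1e-4, 1.9, noise_sd=0.0, baseline=0.0)
        first, last = find_window_of_linearity(f)
        assert 4 <= last - first + 1 <= 6
        E, r2, *_ = fit_sample_efficiency(f, (first, last))
        assert r2 > 0.999

    def test_window_stays_below_plateau(self, rng):
        f = logistic_curve(1e-4, 1.9, rng=rng) - 100.0
        first, last = find_window_of_linearity(f)
        assert f[last - 1] < 0.9 * f.max()

    def test_no_rise_is_poor_fit(self, rng):
        f = rng.normal(0, 1.0, 40)
        with pytest.raises(ValueError):
            find_window_of_linearity(f)


class TestEfficiency:
    def test_noiseless_doubling(self):
        f = 0.001 * 2.0 ** np.arange(1, 41.0)
        E, r2, *_ = fit_sample_efficiency(f, (10, 15))
        assert E == pytest.approx(2.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("true_e,lo,hi", [(1.85, 1.80, 1.90),
                                              (1.70, 1.65, 1.75)])
    def test_seeded_well_recovery(self, true_e, lo, hi):
        rng = np.random.default_rng(0)
        f = logistic_curve(1e-4, true_e, rng=rng)
        fit = fit_curve(make(f))
        assert fit.ok
        assert lo <= fit.efficiency <= hi

    def test_short_window_rejected(self):
        f = 0.001 * 2.0 ** np.arange(1, 41.0)
        with pytest.raises(ValueError):
            fit_sample_efficiency(f, (10, 12))


def _fit_with_eff(e, flag=OK):
    return CurveFit("w", "s", "g", 1, "", 0.0, (10, 14), e, 0.999,
                    np.log10(e), -3.0, flag)


class TestAmpliconSummary:
    def test_identical_efficiencies(self):
        s = summarize_amplicon_efficiency([_fit_with_eff(2.0)] * 3)
        assert s.mean_efficiency == 2.0 and s.n_excluded == 0

    def test_outlier_excluded_from_mean(self):
        s = summarize_amplicon_efficiency(
            [_fit_with_eff(1.85), _fit_with_eff(1.86), _fit_with_eff(1.60)])
        assert s.mean_efficiency == pytest.approx(1.855)
        assert s.n_used == 2 and s.n_excluded == 1

    def test_empty_or_all_bad_raises(self):
        with pytest.raises(ValueError):
            summarize_amplicon_efficiency([])
        with pytest.raises(ValueError):
            summarize_amplicon_efficiency([_fit_with_eff(2.0, POOR_FIT)])


class TestQuantifyN0:
    def test_noiseless_closed_form(self):
        # F' = 0.001 * 2^c crosses Nq = 1.024 at cycle 10 exactly
        f = 0.001 * 2.0 ** np.arange(1, 41.0)
        first, last = find_window_of_linearity(f)
        E, r2, slope, intercept = fit_sample_efficiency(f, (first, last))
        fit = CurveFit("w", "s", "g", 1, "", 0.0, (first, last), E, r2,
                       slope, intercept, OK)
        # place the threshold inside the fitted window
        nq = 0.001 * 2.0 ** (0.5 * (first + last))
        out = quantify_n0(fit, AmpliconSummary("g", 2.0, 0.0, 1, 0), nq)
        assert out.cq == pytest.approx(0.5 * (first + last), abs=1e-9)
        assert out.n0 == pytest.approx(0.001, rel=1e-9)

    def test_identity_n0_e_cq_equals_nq(self, rng):
        curves = []
        for i in range(12):
            x0 = 10 ** rng.uniform(-5, -3)
            curves.append(pd.DataFrame({
                "well": f"w{i}", "sample": f"s{i}", "gene": "g",
                "replicate": 1, "cycle": np.arange(1, 41),
                "fluorescence": logistic_curve(x0, 1.9, rng=rng)}))
        fits, amps = quantify_plate(pd.concat(curves))
        ok = fits[fits.flag == OK]
        assert len(ok) > 6
        mean_e = amps.mean_efficiency.iloc[0]
        resid = ok.n0 * mean_e ** ok.cq - ok.nq
        assert np.abs(resid).max() < 1e-9 * ok.nq.iloc[0]

    def test_delta_cq_three_cycles_for_ratio_eight(self):
        """Two wells whose true X0 differ 8-fold at E=2 quantify three
        cycles apart, and their N0 ratio recovers 8."""
        rng = np.random.default_rng(100)
        rows = []
        for i, x0 in enumerate([8e-4, 1e-4]):
            for rep in range(3):   # routine triplicates
                rows.append(pd.DataFrame({
                    "well": f"w{i}_{rep}", "sample": f"s{i}", "gene": "g",
                    "replicate": rep, "cycle": np.arange(1, 41),
                    "fluorescence": logistic_curve(x0, 2.0, rng=rng)}))
        fits, _ = quantify_plate(pd.concat(rows))
        ok = fits[fits.flag == OK]
        agg = ok.groupby("sample")[["cq", "n0"]].mean()
        assert agg.loc["s1", "cq"] - agg.loc["s0", "cq"] == pytest.approx(
            3.0, abs=0.3)
        assert 7.2 <= agg.loc["s0", "n0"] / agg.loc["s1", "n0"] <= 8.8

    def test_threshold_outside_window_flags_poor_fit(self):
        fit = _fit_with_eff(2.0)
        out = quantify_n0(fit, AmpliconSummary("g", 2.0, 0.0, 1, 0), 1e6)
        assert out.flag == POOR_FIT


class TestInvariants:
    def test_scale_equivariance(self, rng):
        """Scaling fluorescence by s scales N0 by s; E and Cq unchanged."""
        f = logistic_curve(1e-4, 1.9, rng=rng)
        s = 7.3
        df = []
        for name, series in [("a", f), ("b", s * f)]:
            df.append(pd.DataFrame({
                "well": name, "sample": name, "gene": name, "replicate": 1,
                "cycle": np.arange(1, 41), "fluorescence": series}))
        fits, _ = quantify_plate(pd.concat(df))
        fa = fits[fits.well == "a"].iloc[0]
        fb = fits[fits.well == "b"].iloc[0]
        assert fb.efficiency == pytest.approx(fa.efficiency, abs=1e-6)
        assert fb.cq == pytest.approx(fa.cq, abs=1e-6)
        assert fb.n0 == pytest.approx(s * fa.n0, rel=1e-6)

    def test_monotonicity_larger_x0_smaller_cq(self, rng):
        x0s = 10 ** np.linspace(-5.5, -3, 6)
        rows = [pd.DataFrame({
            "well": f"w{i}", "sample": f"s{i}", "gene": "g", "replicate": 1,
            "cycle": np.arange(1, 41),
            "fluorescence": logistic_curve(x0, 1.9, rng=rng)})
            for i, x0 in enumerate(x0s)]
        fits, _ = quantify_plate(pd.concat(rows))
        ok = fits[fits.flag == OK].sort_values("well")
        assert np.all(np.diff(ok.cq) < 0)
        assert np.all(np.diff(ok.n0) > 0)

    def test_rejects_short_or_nonfinite_series(self):
        with pytest.raises(ValueError):
            make(np.ones(5))
        with pytest.raises(ValueError):
            make([np.nan] * 40)
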