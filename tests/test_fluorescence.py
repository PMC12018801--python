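import numpy as np
import pandas as pd
import pytest

from dynaqtl.fluorescence import (
    compute_pi,
    derive_timeseries,
    fit_induction_slope,
    fit_npq_induction,
    fit_npq_relaxation,
    fit_phipsii_recovery,
    ojip_half_rise,
    qc_filter,
    summarize_extremes,
    trait_table,
)
from dynaqtl.simulate import FluorescenceTrace, TraceParams, simulate_fluorescence_traces


def _trace(fo=200.0, fm=1000.0, light=None, dark=None):
    return FluorescenceTrace("s", fo, fm, light or [(20, 250, 500)], dark or [(20, 260, 520)])


class TestDeriveTimeseries:
    def test_closed_forms(self):
        s = derive_timeseries(_trace(light=[(20, 500, 500)]))
        assert np.isclose(s.npq_light[0], 1.0)  # Fm'=500 vs Fm=1000
        assert np.isclose(s.phi_light[0], 0.0)  # F'=Fm'
        assert np.isclose(s.fvfm, 0.8)

    def test_fvfm_zero_when_fo_equals_fm(self):
        s = derive_timeseries(_trace(fo=1000.0))
        assert s.fvfm == 0.0

    def test_nonpositive_fm_prime_is_error(self):
        with pytest.raises(ValueError, match="non-positive"):
            derive_timeseries(_trace(light=[(20, -1.0, -1.0)]))

    def test_negative_npq_flagged_not_clipped(self):
        s = derive_timeseries(_trace(light=[(20, 500, 1100)]))
        assert s.negative_npq_flag
        assert s.npq_light[0] < 0  # retained

    def test_roundtrip_against_generator(self):
        p = TraceParams()
        tr = simulate_fluorescence_traces({"s": p}, noise_sd=0.0)[0]
        s = derive_timeseries(tr)
        t_l = s.t_light
        assert np.allclose(s.npq_light, p.a_ind * (1 - np.exp(-p.b_ind * t_l)), atol=1e-10)
        t_d = s.t_dark
        assert np.allclose(s.npq_dark, p.a_rel * np.exp(-p.b_rel * t_d) + p.c_rel, atol=1e-10)
        assert np.allclose(s.phi_dark, p.a_phi * (1 - np.exp(-p.b_phi * t_d)) + p.c_phi, atol=1e-10)


class TestQcFilter:
    def test_exact_removal_set(self):
        tab = pd.DataFrame({"sample_id": list("abcd"), "fvfm": [0.8, 0.69, 0.71, 0.5]})
        kept, removed, report = qc_filter(tab)
        assert set(removed["sample_id"]) == {"b", "d"}
        assert set(kept["sample_id"]) == {"a", "c"}
        assert report["removed_fraction"] == 0.5

    def test_one_of_four(self):
        tab = pd.DataFrame({"sample_id": list("abcd"), "fvfm": [0.8, 0.8, 0.8, 0.69]})
        _, _, report = qc_filter(tab)
        assert report["removed_fraction"] == 0.25

    def test_planted_low_fvfm_cohort_fraction(self):
        from dynaqtl.simulate import sample_trace_params

        params = sample_trace_params([f"S{i}" for i in range(800)], seed=21, low_fvfm_fraction=0.02)
        traces = simulate_fluorescence_traces(params, noise_sd=0.01, seed=22)
        tab = trait_table(traces)
        _, _, report = qc_filter(tab)
        assert 0.005 <= report["removed_fraction"] <= 0.04


class TestInductionSlope:
    def test_exact_linear(self):
        t = np.array([20.0, 40.0, 60.0])
        assert np.isclose(fit_induction_slope(t, 0.01 * t), 0.01)

    def test_constant_series(self):
        t = np.array([20.0, 40.0, 60.0])
        slope = fit_induction_slope(t, np.full(3, 0.5), include_origin=False)
        assert np.isclose(slope, 0.0)

    def test_noisy_recovery_within_ols_se(self):
        rng = np.random.default_rng(3)
        t = np.array([20.0, 40.0, 60.0, 80.0])
        hits = 0
        for _ in range(50):
            y = 0.02 * t + rng.normal(0, 0.01, len(t))
            tt = np.concatenate([[0.0], t])
            yy = np.concatenate([[0.0], y])
            x = np.column_stack([np.ones(len(tt)), tt])
            beta, res, *_ = np.linalg.lstsq(x, yy, rcond=None)
            sigma2 = float(res[0]) / (len(tt) - 2)
            se = np.sqrt(sigma2 * np.linalg.inv(x.T @ x)[1, 1])
            if abs(fit_induction_slope(t, y) - 0.02) <= 2 * se + 1e-12:
                hits += 1
        assert hits >= 40  # ~95% coverage of the 2-SE band

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_induction_slope(np.array([90.0]), np.array([0.5]), include_origin=False)


class TestExponentialFits:
    def test_noiseless_exact_recovery(self):
        t = np.array([20, 40, 60, 120, 180, 240, 300, 360, 420, 480, 540, 600], float)
        y = 2.5 * (1 - np.exp(-0.03 * t))
        fit = fit_npq_induction(t, y)
        assert fit.converged
        assert abs(fit.a - 2.5) / 2.5 < 1e-6 and abs(fit.b - 0.03) / 0.03 < 1e-6

        td = np.array([20, 40, 60, 120, 180, 360, 540], float)
        rel = fit_npq_relaxation(td, 1.5 * np.exp(-0.01 * td) + 0.3)
        assert abs(rel.a - 1.5) < 1e-6 and abs(rel.b - 0.01) < 1e-8 and abs(rel.c - 0.3) < 1e-6

        rec = fit_phipsii_recovery(td, 0.3 * (1 - np.exp(-0.02 * td)) + 0.4)
        assert abs(rec.a - 0.3) < 1e-6 and abs(rec.c - 0.4) < 1e-6
        # fitted value at t -> infinity equals a + c
        assert np.isclose(rec.a + rec.c, 0.7, atol=1e-6)

    def test_degenerate_all_zero(self):
        t = np.array([20, 40, 60, 120], float)
        fit = fit_npq_induction(t, np.zeros(4))
        assert not fit.converged
        assert fit.a == 0.0

    def test_constant_relaxation_series(self):
        td = np.array([20, 40, 60, 120, 180], float)
        rel = fit_npq_relaxation(td, np.full(5, 0.42))
        assert abs(rel.a) < 1e-6 and np.isclose(rel.c, 0.42, atol=1e-6)

    def test_monotonicity_of_fitted_curves(self):
        t = np.array([20, 40, 60, 120, 180, 240, 300, 360, 420, 480, 540, 600], float)
        fit = fit_npq_induction(t, 2.0 * (1 - np.exp(-0.05 * t)))
        grid = np.linspace(0, 700, 200)
        curve = fit.a * (1 - np.exp(-fit.b * grid))
        assert (np.diff(curve) >= -1e-12).all()
        assert np.isclose(fit.a * (1 - np.exp(-fit.b * 0.0)), 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_grid_search_oracle_agreement(self, seed):
        """Fit is at least as good as a refined 2-D brute-force grid search."""
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(0.5, 3.0), rng.uniform(0.005, 0.08)
        t = np.array([20, 40, 60, 120, 180, 240, 300, 360, 420, 480, 540, 600], float)
        y = a * (1 - np.exp(-b * t))
        fit = fit_npq_induction(t, y)
        best = np.inf
        a_grid = np.linspace(0.1, 4.0, 60)
        b_grid = np.geomspace(1e-3, 0.2, 60)
        for aa in a_grid:
            pred = aa * (1 - np.exp(-np.outer(b_grid, t)))
            rss = ((pred - y) ** 2).sum(axis=1)
            best = min(best, rss.min())
        assert fit.rss <= best + 1e-9

    def test_noisy_recovery_median_within_5pct(self):
        p = TraceParams(a_ind=2.5, b_ind=0.03)
        errs_a, errs_b = [], []
        for seed in range(40):
            tr = simulate_fluorescence_traces({"s": p}, noise_sd=0.01, seed=seed)[0]
            s = derive_timeseries(tr)
            fit = fit_npq_induction(s.t_light, s.npq_light)
            errs_a.append(abs(fit.a - 2.5) / 2.5)
            errs_b.append(abs(fit.b - 0.03) / 0.03)
        assert np.median(errs_a) < 0.05 and np.median(errs_b) < 0.05


class TestExtremesAndPi:
    def test_extremes_brute_force(self):
        rng = np.random.default_rng(9)
        p = TraceParams()
        tr = simulate_fluorescence_traces({"s": p}, noise_sd=0.05, seed=10)[0]
        s = derive_timeseries(tr)
        ext = summarize_extremes(s)
        assert ext["npq_max"] == max(list(s.npq_light) + list(s.npq_dark))
        assert ext["npq_final"] == s.npq_dark[-1]
        assert ext["phipsii_final"] == s.phi_dark[-1]

    def test_pi_limit_case(self):
        assert np.isclose(compute_pi(0.5, 0.0, 1.0), 0.5)

    def test_pi_hand_evaluated(self):
        # Fv/Fm=1 collapses the bracket to 1; dividing by s=1/2 gives PI=0.3
        assert np.isclose(compute_pi(0.6, 1.0, 1.0), 0.3)

    def test_parses_agree_when_npq_zero(self):
        for fvfm in (0.6, 0.75, 0.9):
            for phif in (0.2, 0.5):
                a = compute_pi(phif, 0.0, fvfm, parse="nested-ratio")
                b = compute_pi(phif, 0.0, fvfm, parse="inner-ratio")
                assert np.isclose(a, b)

    def test_pi_validation(self):
        with pytest.raises(ValueError):
            compute_pi(0.5, 0.0, 0.0)
        with pytest.raises(ValueError):
            compute_pi(0.5, -0.1, 0.8)
        with pytest.raises(ValueError):
            compute_pi(0.5, 0.0, 0.8, parse="bogus")


class TestOjip:
    def test_closed_form_half_rise(self):
        k = np.log(2) / 100.0
        t = np.linspace(0, 1500, 4001)
        f = 200 + 800 * (1 - np.exp(-k * t))
        t_half, inv = ojip_half_rise(t, f, fo=200, fj=1000)
        assert abs(t_half - 100.0) < 0.5
        assert np.isclose(inv, 1.0 / t_half)

    def test_two_point_interpolation_oracle(self):
        t = np.array([0.0, 10.0, 20.0])
        f = np.array([0.0, 0.2, 1.0])
        # half level 0.5 crossed between 10 and 20: 10 + (0.5-0.2)/0.8*10
        t_half, _ = ojip_half_rise(t, f, fo=0.0, fj=1.0)
        assert np.isclose(t_half, 10 + 0.3 / 0.8 * 10)

    def test_rate_scaling(self):
        t = np.linspace(0, 2000, 8001)
        k = np.log(2) / 100.0
        t1, i1 = ojip_half_rise(t, 1 - np.exp(-k * t), fo=0.0, fj=1.0)
        t2, i2 = ojip_half_rise(t, 1 - np.exp(-2 * k * t), fo=0.0, fj=1.0)
        assert np.isclose(t2, t1 / 2, rtol=1e-2)
        assert np.isclose(i2, 2 * i1, rtol=1e-2)

    def test_never_reaches_half(self):
        with pytest.raises(ValueError, match="never reaches"):
            ojip_half_rise(np.array([0.0, 1.0]), np.array([0.0, 0.1]), fo=0.0, fj=1.0)
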