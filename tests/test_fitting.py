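"""Inference layer: self-consistency, closed loops, CI calibration."""

import numpy as np
import pytest

from sectorwalk.core import KeyParams, SimParams, TWO_PI
from sectorwalk import fitting, theory
from sectorwalk import fixtures as fx
from sectorwalk import observables as obs
from sectorwalk import simulator as sim


class TestFitDw:
    def test_noiseless_curves_recover_exactly(self):
        phi = np.linspace(0.01, 1.2, 80)
        curves = [
            fitting.ObservedCurve(
                phi, theory.neutral_heterozygosity(phi, L, 0.1, 3.5, 0.5), L=L)
            for L in (1.0, 2.0, 4.0, 6.5)
        ]
        res = fitting.fit_dw_heterozygosity(curves, 3.5, 0.5)
        assert res.estimate == pytest.approx(0.1, abs=1e-4)

    def test_flat_curve_is_unidentifiable(self):
        phi = np.linspace(0.01, 1.2, 30)
        with pytest.raises(ValueError, match="flat"):
            fitting.fit_dw_heterozygosity(
                [fitting.ObservedCurve(phi, np.zeros_like(phi), L=1.0)],
                3.5, 0.5)

    def test_noisy_ci_calibration(self):
        # 20 random truths: the reported 95% interval should cover >= 90%
        rng = np.random.default_rng(100)
        phi = np.linspace(0.02, 1.5, 60)
        hits = 0
        for _ in range(20):
            Dw_true = rng.uniform(0.05, 0.3)
            R0 = rng.uniform(2.0, 6.0)
            Ls = (1.0, 2.0, 4.0, 6.5)
            curves = []
            for L in Ls:
                y = theory.neutral_heterozygosity(phi, L, Dw_true, R0, 0.5)
                se = np.full_like(phi, 0.01)
                curves.append(fitting.ObservedCurve(
                    phi, y + rng.normal(0, 0.01, phi.size), se, L=L))
            res = fitting.fit_dw_heterozygosity(curves, R0, 0.5)
            hits += res.ci_lo <= Dw_true <= res.ci_hi
        assert hits >= 18

    def test_blurred_fixture_still_converges(self):
        # image-overlap artifact: H(0) > 0, fit converges with downward bias
        R0 = 800 / TWO_PI
        key = KeyParams(Dw=0.5, R0=R0, vw=np.zeros((2, 2)))
        spec = fx.FixtureSpec(truth=key, init_fractions=(0.5, 0.5),
                              n_replicates=40, L_grid=(R0, 2 * R0),
                              phi_bins=300, overlap_blur=0.03, seed=5)
        ff, _ = fx.make_fraction_fields(spec)
        H, H_se = obs.heterozygosity_from_field(ff)
        lags = obs.correlation_lags(300)
        hi = np.searchsorted(lags, 1.2)
        curves = [fitting.ObservedCurve(lags[1:hi], H[1:hi, m],
                                        H_se[1:hi, m], L=float(L))
                  for m, L in enumerate(ff.L_grid)]
        res = fitting.fit_dw_heterozygosity(curves, R0, 0.5)
        assert 0.1 < res.estimate < 1.0  # converged to the right scale


class TestUniversalCurveCache:
    def test_repeated_requests_are_bit_identical(self):
        cache = fitting.UniversalCurveCache(N0=400, n_reps=6, n_bins=128)
        c1 = cache.curve(0.5, 1.0)
        c2 = cache.curve(0.5, 1.0)
        assert c1 is c2
        cache2 = fitting.UniversalCurveCache(N0=400, n_reps=6, n_bins=128)
        c3 = cache2.curve(0.5, 1.0)
        assert np.array_equal(c1.y, c3.y)

    def test_neutral_curve_matches_closed_form(self):
        cache = fitting.UniversalCurveCache(N0=800, n_reps=60, n_bins=400)
        uc = cache.curve(0.0, 1.5, fractions=(0.5, 0.5))
        x = uc.x[8:60]
        F_th = theory.neutral_two_point(
            x * cache.phi_c, 1.5 * cache.R0, cache.Dw, cache.R0,
            np.array([0.5, 0.5]))[0, 1]
        z = (uc.y[8:60] - F_th) / uc.se[8:60]
        assert np.abs(z).max() < 5
        assert abs(np.mean(uc.y[8:60] - F_th)) < 3 * np.mean(uc.se[8:60])

    def test_tiny_ring_rejected_when_phi_c_reaches_system_size(self):
        with pytest.raises(ValueError, match="phi_c"):
            fitting.UniversalCurveCache(N0=6)


class TestFitLs:
    def test_single_candidate_grid_is_degenerate(self):
        cache = fitting.UniversalCurveCache(N0=400, n_reps=6, n_bins=128)
        phi = np.linspace(0.05, 1.0, 12)
        obs_curve = fitting.ObservedCurve(
            phi, np.full(12, 0.2), np.full(12, 0.05), L=50.0)
        res = fitting.fit_ls_correlation(obs_curve, 0.5, 60.0,
                                         ls_grid=np.array([80.0]), cache=cache)
        assert res.estimate == res.ci_lo == res.ci_hi == 80.0
        assert res.probabilities == pytest.approx([1.0])

    def test_closed_loop_recovers_truth_within_ci(self):
        R0t = 3000 / TWO_PI
        Dwt = 0.5
        Lst = R0t / 0.52**2
        vwt = np.sqrt(Dwt / Lst)
        L_obs = 1.857 * R0t
        spec = fx.FixtureSpec(
            truth=KeyParams(Dw=Dwt, R0=R0t, vw=[[0, vwt], [-vwt, 0]]),
            init_fractions=(2 / 3, 1 / 3), n_replicates=20,
            L_grid=(L_obs,), phi_bins=500, seed=31)
        ff, _ = fx.make_fraction_fields(spec)
        Fij, Fij_se = obs.two_point_correlation(ff)
        lags = obs.correlation_lags(500)
        phic = theory.angular_correlation_length(Dwt, R0t)
        hi = np.searchsorted(lags, 7 * phic)
        sl = slice(2, hi, 4)
        observed = fitting.ObservedCurve(lags[sl], Fij[0, 1, sl, 0],
                                         Fij_se[0, 1, sl, 0], L=L_obs)
        cache = fitting.UniversalCurveCache(N0=1000, n_reps=32, base_seed=515)
        grid = np.geomspace(R0t / 8, 60 * R0t, 19)
        res = fitting.fit_ls_correlation(observed, Dwt, R0t, grid, cache,
                                         (2 / 3, 1 / 3))
        assert res.ci_lo <= Lst <= res.ci_hi
        assert 0.3 * Lst < res.estimate < 3 * Lst

    def test_missing_errors_rejected(self):
        with pytest.raises(ValueError, match="standard errors"):
            fitting.fit_ls_correlation(
                fitting.ObservedCurve(np.arange(3.0), np.arange(3.0), L=1.0),
                0.5, 60.0)


def _ensemble_slope_se(traces):
    """SE of the mean fitted slope/2 from per-replicate slopes."""
    slopes = []
    for c in traces:
        keep = np.isfinite(c.y)
        if keep.sum() < 2:
            continue
        x, y = c.x[keep], c.y[keep]
        slopes.append(np.polyfit(x, y, 1)[0] / 2.0)
    slopes = np.asarray(slopes)
    return slopes.std(ddof=1) / np.sqrt(slopes.size)


class TestFitVw:
    def test_noiseless_trace_recovers_exactly(self):
        x = np.linspace(0, 1.5, 10)
        res = fitting.fit_vw_sectors([fitting.ObservedCurve(x, 2 * 0.06 * x)])
        assert res.estimate == pytest.approx(0.06, abs=1e-12)

    def test_empty_and_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fitting.fit_vw_sectors([])
        with pytest.raises(ValueError):
            fitting.fit_vw_sectors(
                [fitting.ObservedCurve(np.array([1.0]), np.array([0.1]))])
        with pytest.raises(ValueError, match="degenerate"):
            fitting.fit_vw_sectors(
                [fitting.ObservedCurve(np.array([1.0, 1.0]),
                                       np.array([0.1, 0.2]))])

    def test_simulated_sectors_recover_bias(self):
        R0 = 500 / TWO_PI
        key = KeyParams(Dw=0.5, R0=R0, vw=[[0, -0.06], [0.06, 0]])
        spec = fx.FixtureSpec(truth=key, init_fractions=(0.5, 0.5),
                              n_replicates=600,
                              L_grid=tuple(R0 * np.array([0.3, 0.7, 1.2, 2.0, 3.0])),
                              seed=13)
        traces, truth = fx.make_sector_traces(spec)
        res = fitting.fit_vw_sectors(traces)
        # honest ensemble error: spread of per-replicate slopes
        se = _ensemble_slope_se(traces)
        assert abs(res.estimate - 0.06) < 3 * se

    def test_ci_calibration_over_random_truths(self):
        # 20 random (vw, R0) draws; sector-based fit covers in >= 90%
        rng = np.random.default_rng(17)
        hits = 0
        for k in range(20):
            vw = rng.uniform(0.02, 0.12)
            N0 = int(rng.uniform(300, 900))
            Rf = np.linspace(1.0, 3.5, 8)
            tr = sim.run_sector_ensemble(vw, N0, Rf, 300, base_seed=1000 + k)
            x = np.log(Rf)
            curves = [fitting.ObservedCurve(x, np.where(a, w - tr.phi0, np.nan))
                      for w, a in zip(tr.widths, tr.alive)]
            res = fitting.fit_vw_sectors(curves)
            se = _ensemble_slope_se(curves)
            hits += abs(res.estimate - vw) < 3 * se
        assert hits >= 18


class TestPredictDynamics:
    def test_neutral_key_parameters_reproduce_neutral_theory(self):
        q = 3
        key = KeyParams(Dw=0.1, R0=3.5, vw=np.zeros((q, q)))
        L_grid = np.array([2.0, 6.5])
        summ = fitting.predict_dynamics(key, (1 / 3,) * q, L_grid,
                                        N0_sim=900, n_reps=40, base_seed=3)
        # fractions stay at the inoculum
        for i in range(q):
            assert np.all(np.abs(summ.Fi[i] - 1 / 3) < 4 * summ.Fi_se[i])
        # heterozygosity tracks the erf law on the physical grid
        idx = np.argmin(np.abs(summ.phi_grid - 2 * key.phi_c))
        H_th = theory.neutral_heterozygosity(
            summ.phi_grid[idx], 6.5, key.Dw, key.R0, 2 / 3)
        assert abs(summ.H[idx, 1] - H_th) < 4 * summ.H_se[idx, 1]

    def test_selection_depletes_the_less_fit_strain(self):
        vw = 0.06
        q = 3
        mat = np.zeros((q, q))
        mat[0, 2] = mat[1, 2] = vw
        mat[2, 0] = mat[2, 1] = -vw
        key = KeyParams(Dw=0.1, R0=3.5, vw=mat)
        Ls = 0.1 / vw**2
        L_grid = np.array([0.1 * Ls, 0.5 * Ls])
        summ = fitting.predict_dynamics(key, (1 / 3,) * q, L_grid,
                                        N0_sim=900, n_reps=40, base_seed=5)
        drop = summ.Fi[2, 0] - summ.Fi[2, 1]
        assert drop > 3 * np.hypot(summ.Fi_se[2, 0], summ.Fi_se[2, 1])

    def test_inconsistent_velocity_matrix_rejected(self):
        key = KeyParams.__new__(KeyParams)
        key.Dw, key.R0 = 0.1, 3.5
        key.vw = np.array([[0.0, 0.06], [0.06, 0.0]])
        with pytest.raises(ValueError, match="antisymmetric"):
            fitting.predict_dynamics(key, (0.5, 0.5), [1.0])
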