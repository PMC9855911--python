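"""Maximum-entropy LDA: grid, kernel, channel fits, L-curve, dataset fits."""

import numpy as np
import pytest
from scipy.optimize import nnls

from flavidyn.datamodel import TimeGrid, ValidationError, exclude_early_delays
from flavidyn.lda import (
    LifetimeGrid,
    RegularizationPath,
    build_lifetime_grid,
    decay_kernel,
    fit_lda,
    mem_fit_channel,
    reconstruct,
    select_lambda_lcurve,
)
from flavidyn.synthetic import (
    KineticScheme,
    SpeciesSpectrum,
    make_log_time_grid,
    simulate_dataset,
    simulate_preset,
)
from flavidyn.datamodel import AxisKind, SpectralAxis


class TestLifetimeGrid:
    def test_default_grid_411_points(self):
        grid = build_lifetime_grid()
        assert grid.n_taus == 411
        assert grid.taus[0] == 1e-13
        assert grid.taus[-1] == 1e-3

    def test_decade_identity(self):
        grid = build_lifetime_grid()
        assert grid.taus[41] / grid.taus[0] == pytest.approx(10.0, rel=1e-12)

    def test_two_point_grid(self):
        np.testing.assert_allclose(
            build_lifetime_grid(1.0, 10.0, 1).taus, [1.0, 10.0]
        )

    def test_non_integral_span_rounds_up(self):
        grid = build_lifetime_grid(1.0, 10 ** 2.5, 2)
        assert grid.taus[-1] == pytest.approx(10 ** 2.5)
        assert grid.n_taus == 6  # ceil(2.5 * 2) + 1

    def test_invalid_range(self):
        with pytest.raises(ValidationError):
            build_lifetime_grid(1e-3, 1e-13)

    def test_rejects_non_log_spacing(self):
        with pytest.raises(ValidationError):
            LifetimeGrid(np.array([1.0, 2.0, 10.0]), 1)


class TestKernel:
    def test_entries(self):
        grid = LifetimeGrid(np.array([1e-9, 1e-8]), 1)
        times = TimeGrid(np.array([1e-9, 1e-7]))
        K = decay_kernel(times, grid, with_offset=False)
        assert K[0, 0] == pytest.approx(np.exp(-1.0))
        assert K[1, 0] < 4e-44  # t/tau = 100
        Koff = decay_kernel(times, grid, with_offset=True)
        np.testing.assert_array_equal(Koff[:, -1], 1.0)


def single_exp_problem(tau_idx=20, n_t=30):
    grid = build_lifetime_grid(1e-12, 1e-5, 6)
    times = TimeGrid(np.geomspace(1e-12, 1e-4, n_t))
    K = decay_kernel(times, grid, with_offset=False)
    y = np.exp(-times.delays / grid.taus[tau_idx])
    return grid, times, K, y


class TestMemFitChannel:
    def test_zero_trace_stays_at_prior(self):
        _, _, K, _ = single_exp_problem()
        fit = mem_fit_channel(np.zeros(K.shape[0]), K, 1.0, 1e-6)
        assert np.abs(fit.amplitudes).max() <= 10 * 1e-6
        assert abs(fit.offset) <= 10 * 1e-6

    def test_single_exponential_mass_concentrates(self):
        grid, _, K, y = single_exp_problem(tau_idx=20)
        m = 1e-6
        fit = mem_fit_channel(y, K, 1e-8 * (y @ y), m, with_offset=False)
        assert fit.converged
        a = np.abs(fit.amplitudes)
        mass_near = a[19:22].sum()
        assert mass_near >= 0.9 * a.sum()
        # NNLS oracle on the same kernel reconstructs the same trace
        coef, _ = nnls(K, y)
        np.testing.assert_allclose(
            K @ fit.amplitudes, K @ coef, atol=1e-4 * np.abs(y).max()
        )

    def test_sign_symmetry(self):
        _, _, K, y = single_exp_problem()
        lam = 1e-5 * (y @ y)
        fp = mem_fit_channel(y, K, lam, 1e-6, with_offset=False)
        fn = mem_fit_channel(-y, K, lam, 1e-6, with_offset=False)
        np.testing.assert_allclose(fn.amplitudes, -fp.amplitudes, atol=1e-10)

    def test_scale_equivariance(self):
        # exact symmetry of the signed-MEM objective: (y, m, lam) -> (s y, s m, s lam)
        _, _, K, y = single_exp_problem()
        y = y - 0.3
        s = 7.5
        lam = 1e-4 * (y @ y)
        f1 = mem_fit_channel(y, K, lam, 1e-6)
        f2 = mem_fit_channel(s * y, K, s * lam, s * 1e-6)
        np.testing.assert_allclose(f2.amplitudes, s * f1.amplitudes, rtol=1e-5, atol=1e-8)
        assert f2.offset == pytest.approx(s * f1.offset, rel=1e-5, abs=1e-8)

    def test_lambda_zero_limit_matches_least_squares(self):
        # brute-force oracle: unregularized LSQ on a tiny grid (8 taus, 12 delays)
        grid = LifetimeGrid(np.geomspace(1e-12, 1e-5, 8), 1)
        times = TimeGrid(np.geomspace(1e-12, 1e-4, 12))
        K = decay_kernel(times, grid, with_offset=False)
        y = (
            1.5 * np.exp(-times.delays / 1e-9)
            - 0.7 * np.exp(-times.delays / 1e-7)
            + 0.2
        )
        fit = mem_fit_channel(y, K, 1e-9 * (y @ y), 1e-6 * np.abs(y).max())
        Koff = np.hstack([K, np.ones((12, 1))])
        coef, *_ = np.linalg.lstsq(Koff, y, rcond=None)
        rec_mem = K @ fit.amplitudes + fit.offset
        rec_ls = Koff @ coef
        assert np.max(np.abs(rec_mem - rec_ls)) <= 1e-4 * np.max(np.abs(y))

    def test_rejects_bad_inputs(self):
        _, _, K, y = single_exp_problem()
        with pytest.raises(ValidationError):
            mem_fit_channel(y[:-1], K, 1.0, 1e-6)
        with pytest.raises(ValidationError):
            mem_fit_channel(y, K, -1.0, 1e-6)


class TestLCurve:
    def make_path(self, x, y, selected=0):
        # encode log10 coordinates as chi2/negentropy values
        lams = np.geomspace(1e-6, 1.0, len(x))
        return RegularizationPath(lams, 10.0 ** np.asarray(x), 10.0 ** np.asarray(y), selected)

    def test_sharp_corner_selected(self):
        # two straight log-log segments meeting at index 5
        x = [-6, -6, -6, -6, -6, -6, -5, -4, -3, -2, -1]
        y = [5, 4, 3, 2, 1, 0, 0, 0, 0, 0, 0]
        path = self.make_path(x, y)
        assert select_lambda_lcurve(path) == pytest.approx(path.lambdas[5])

    def test_collinear_returns_largest_lambda(self):
        path = self.make_path([-3, -2, -1], [2, 1, 0])
        assert select_lambda_lcurve(path) == pytest.approx(path.lambdas[-1])

    def test_direction_invariance(self):
        x = [-6, -6, -6, -5, -4, -3]
        y = [3, 2, 1, 0.98, 0.97, 0.96]
        lams = np.geomspace(1e-6, 1.0, 6)
        fwd = RegularizationPath(lams, 10.0 ** np.array(x), 10.0 ** np.array(y), 0)
        # same points supplied from the reversed generation order
        rev = RegularizationPath(
            lams[::-1][::-1], 10.0 ** np.array(x), 10.0 ** np.array(y), 0
        )
        assert select_lambda_lcurve(fwd) == select_lambda_lcurve(rev)

    def test_too_few_points(self):
        path = RegularizationPath(np.array([0.1, 1.0]), [1.0, 2.0], [2.0, 1.0], 0)
        with pytest.raises(ValidationError):
            select_lambda_lcurve(path)


@pytest.fixture(scope="module")
def wt_fit():
    ds, sc = simulate_preset("wt_h2o", seed=1)
    ds = exclude_early_delays(ds)
    amap, path = fit_lda(ds)
    return ds, sc, amap, path


class TestFitLda:
    def test_noiseless_single_species_near_perfect_fit(self):
        scheme = KineticScheme(("A", "B"), (1e-8,), final_resonant=False)
        spec = SpeciesSpectrum(bands=((500.0, 80.0, 1.0),))
        axis = SpectralAxis(AxisKind.wavelength_nm, np.linspace(380, 1000, 8))
        ds = simulate_dataset(scheme, [spec], axis, make_log_time_grid(30), 0.0)
        ds = exclude_early_delays(ds)
        grid = build_lifetime_grid(1e-13, 1e-3, 8)
        lam_small = 1e-10 * float(np.sum(ds.signal**2))
        amap, _ = fit_lda(ds, grid=grid, lambdas=[lam_small, 2 * lam_small, 4 * lam_small])
        rmse = np.sqrt(np.mean((reconstruct(amap, ds.time) - ds.signal) ** 2))
        assert rmse < 1e-6 * np.abs(ds.signal).max()

    def test_recovers_two_lifetime_clusters(self, wt_fit):
        ds, sc, amap, path = wt_fit
        D = np.sum(amap.amplitudes**2, axis=0)
        taus = amap.grid.taus
        for tau_true in sc.ground_truth_lifetimes:
            window = (taus > tau_true / 2) & (taus < tau_true * 2)
            assert D[window].max() > 0.2 * D.max()

    def test_chi2_monotone_along_path(self, wt_fit):
        _, _, _, path = wt_fit
        # chi2 non-increasing as lambda decreases
        assert np.all(np.diff(path.chi2) >= -1e-9 * path.chi2[1:])

    def test_reconstruction_chi2_matches_path(self, wt_fit):
        ds, _, amap, path = wt_fit
        resid = ds.signal - reconstruct(amap, ds.time)
        chi2 = float(np.sum(resid**2))
        assert chi2 == pytest.approx(path.chi2[path.selected_index], rel=1e-9)

    def test_all_channels_converged(self, wt_fit):
        _, _, amap, _ = wt_fit
        assert amap.converged.all()

    def test_empty_lambda_list_rejected(self, wt_fit):
        ds, *_ = wt_fit
        with pytest.raises(ValidationError):
            fit_lda(ds, lambdas=[])


class TestReconstruct:
    def test_offset_only(self):
        grid = build_lifetime_grid(1e-9, 1e-6, 2)
        axis = SpectralAxis(AxisKind.wavelength_nm, [400.0, 500.0])
        from flavidyn.lda import AmplitudeMap

        amap = AmplitudeMap(
            np.zeros((2, grid.n_taus)), np.full(2, 2.0), grid, axis, 1.0
        )
        out = reconstruct(amap, TimeGrid(np.array([1e-9, 1e-7])))
        np.testing.assert_allclose(out, 2.0)

    def test_single_amplitude_at_tau(self):
        grid = build_lifetime_grid(1e-9, 1e-6, 2)
        axis = SpectralAxis(AxisKind.wavelength_nm, [400.0, 500.0])
        from flavidyn.lda import AmplitudeMap

        amps = np.zeros((2, grid.n_taus))
        amps[0, 0] = 1.0
        amap = AmplitudeMap(amps, np.zeros(2), grid, axis, 1.0)
        out = reconstruct(amap, TimeGrid(np.array([grid.taus[0]])))
        assert out[0, 0] == pytest.approx(np.exp(-1.0))
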