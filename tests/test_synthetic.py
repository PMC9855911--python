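"""Forward model: time grids, Bateman populations, simulated datasets, presets."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from flavidyn.datamodel import AxisKind, SpectralAxis, TimeGrid, ValidationError
from flavidyn.synthetic import (
    KineticScheme,
    SpeciesSpectrum,
    PRESET_NAMES,
    TABLE1_LIFETIMES,
    gaussian_difference_spectrum,
    make_log_time_grid,
    preset_scenario,
    sequential_populations,
    simulate_dataset,
    simulate_preset,
)


def bateman_oracle(rates, t):
    """Closed-form Bateman populations for strictly distinct rates."""
    n = len(rates)
    out = np.zeros(n)
    for j in range(n):
        prod_k = np.prod(rates[:j])
        s = 0.0
        for i in range(j + 1):
            denom = np.prod([rates[l] - rates[i] for l in range(j + 1) if l != i])
            s += np.exp(-rates[i] * t) / denom
        out[j] = prod_k * s
    return out


class TestTimeGrid:
    def test_defaults_span_experiment(self):
        grid = make_log_time_grid()
        assert grid.n_delays == 53
        assert grid.delays[0] == pytest.approx(100e-15, rel=0, abs=0)
        assert grid.delays[-1] == pytest.approx(0.8e-3, rel=0, abs=0)
        ratios = grid.delays[1:] / grid.delays[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    @pytest.mark.parametrize(
        "args,expected",
        [((2, 1.0, 10.0), [1.0, 10.0]), ((3, 1.0, 100.0), [1.0, 10.0, 100.0])],
    )
    def test_small_grids(self, args, expected):
        np.testing.assert_allclose(make_log_time_grid(*args).delays, expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            make_log_time_grid(1, 1.0, 10.0)
        with pytest.raises(ValidationError):
            make_log_time_grid(5, 10.0, 1.0)


class TestSpectra:
    def test_peak_value_and_half_maximum(self):
        axis = SpectralAxis(AxisKind.wavenumber_cm1, [1480.0, 1490.0, 1500.0, 1510.0])
        spec = SpeciesSpectrum(bands=((1500.0, 20.0, 2.0),))
        vals = gaussian_difference_spectrum(spec, axis)
        assert vals[2] == pytest.approx(2.0)
        assert vals[1] == pytest.approx(1.0)  # center - fwhm/2

    def test_opposite_bands_cancel(self):
        axis = SpectralAxis(AxisKind.wavelength_nm, np.linspace(400, 700, 50))
        spec = SpeciesSpectrum(bands=((500.0, 40.0, 1.5), (500.0, 40.0, -1.5)))
        np.testing.assert_allclose(
            gaussian_difference_spectrum(spec, axis), 0.0, atol=1e-15
        )


class TestPopulations:
    def test_initial_condition(self):
        scheme = KineticScheme(("A", "B", "C"), (1e-9, 1e-6))
        pops = sequential_populations(scheme, TimeGrid([1e-18]))
        np.testing.assert_allclose(pops[0], [1.0, 0.0, 0.0], atol=1e-9)

    def test_closed_form_two_step(self):
        # k1 = 1, k2 = 0.5, t = 2 (dimensionless rates via unit lifetimes)
        scheme = KineticScheme(("A", "B", "C"), (1.0, 2.0))
        pops = sequential_populations(scheme, TimeGrid([2.0]))
        cA = np.exp(-2.0)
        cB = (1.0 / (0.5 - 1.0)) * (np.exp(-2.0) - np.exp(-1.0))
        assert pops[0, 0] == pytest.approx(cA, rel=1e-12)
        assert pops[0, 1] == pytest.approx(cB, rel=1e-12)
        assert cB == pytest.approx(0.46509, abs=5e-6)

    def test_equal_rates_analytic_limit(self):
        # k1 = k2 = k: c_B(t) = k t exp(-k t), maximal at t = 1/k
        k = 2.0
        scheme = KineticScheme(("A", "B", "C"), (1.0 / k, 1.0 / k))
        t = np.array([0.1, 0.3, 1.0 / k, 2.0])
        pops = sequential_populations(scheme, TimeGrid(t))
        np.testing.assert_allclose(pops[:, 1], k * t * np.exp(-k * t), rtol=1e-10)
        assert np.argmax(pops[:, 1]) == 2

    def test_matches_closed_form_bateman(self):
        rates = np.array([5.0, 1.0, 0.2, 0.0])
        scheme = KineticScheme(
            ("A", "B", "C", "D"), tuple(1.0 / r for r in rates[:-1])
        )
        times = TimeGrid(np.geomspace(0.01, 50.0, 20))
        pops = sequential_populations(scheme, times)
        for j, t in enumerate(times.delays):
            np.testing.assert_allclose(
                pops[j], bateman_oracle(rates, t), rtol=1e-9, atol=1e-12
            )

    @given(st.integers(min_value=0, max_value=10_000))
    def test_conservation_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5))
        lifetimes = tuple(10.0 ** rng.uniform(-12, -4, n - 1))
        scheme = KineticScheme(tuple(f"S{i}" for i in range(n)), lifetimes)
        times = TimeGrid(np.geomspace(1e-13, 1e-3, 15))
        pops = sequential_populations(scheme, times)
        np.testing.assert_allclose(pops.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(pops >= 0)
        assert np.all(np.diff(pops[:, 0]) <= 1e-15)


class TestSimulation:
    def axis(self, n=16):
        return SpectralAxis(AxisKind.wavelength_nm, np.linspace(380, 1000, n))

    def test_noiseless_single_species_is_rank_one(self):
        scheme = KineticScheme(("A", "B"), (1e-9,), final_resonant=False)
        spec = SpeciesSpectrum(bands=((500.0, 60.0, 1.0),))
        ds = simulate_dataset(
            scheme, [spec], self.axis(), make_log_time_grid(20), noise_sigma=0.0
        )
        c = np.exp(-ds.time.delays / 1e-9)
        s = gaussian_difference_spectrum(spec, ds.axis)
        np.testing.assert_allclose(ds.signal, np.outer(c, s), rtol=1e-9, atol=1e-300)

    def test_rank_bounded_by_resonant_species(self):
        ds, sc = simulate_preset("wt_h2o", seed=0, noise_sigma=0.0)
        sv = np.linalg.svd(ds.signal, compute_uv=False)
        rank = int(np.sum(sv > sv[0] * 1e-10))
        assert rank <= sc.scheme.n_resonant

    def test_same_seed_reproducible(self):
        ds1, _ = simulate_preset("fmn_h2o", seed=7)
        ds2, _ = simulate_preset("fmn_h2o", seed=7)
        np.testing.assert_array_equal(ds1.signal, ds2.signal)
        ds3, _ = simulate_preset("fmn_h2o", seed=8)
        assert not np.array_equal(ds1.signal, ds3.signal)

    def test_resonance_loss_at_long_delays(self):
        # dark terminal species: signal at 0.8 ms collapses vs the 1 ps level
        ds, _ = simulate_preset("wt_h2o", seed=0, noise_sigma=0.0)
        i_1ps = int(np.argmin(np.abs(ds.time.delays - 1e-12)))
        late = np.max(np.abs(ds.signal[-1]))
        early = np.max(np.abs(ds.signal[i_1ps]))
        assert late < 0.05 * early

    def test_negative_noise_rejected(self):
        scheme = KineticScheme(("A", "B"), (1e-9,), final_resonant=False)
        spec = SpeciesSpectrum(bands=((500.0, 60.0, 1.0),))
        with pytest.raises(ValidationError):
            simulate_dataset(
                scheme, [spec], self.axis(), make_log_time_grid(10), noise_sigma=-0.1
            )


class TestPresets:
    def test_unknown_name_lists_valid(self):
        with pytest.raises(ValidationError, match="wt_h2o"):
            preset_scenario("nonsense")

    @pytest.mark.parametrize("name", PRESET_NAMES)
    def test_lifetimes_traceable_to_published_table(self, name):
        sc = preset_scenario(name)
        sample = sc.meta.sample
        solvent = sc.meta.solvent.value
        entry = TABLE1_LIFETIMES[(sample, solvent)]
        assert entry["event1"]["TA"] in sc.scheme.lifetimes
        assert entry["event2"]["TA"] in sc.scheme.lifetimes

    def test_wt_h2o_structure(self):
        sc = preset_scenario("wt_h2o")
        assert sc.scheme.n_species == 3
        assert not sc.scheme.final_resonant
        assert sc.scheme.lifetimes == (2.6e-9, 0.63e-6)

    def test_c78a_has_nondecaying_component(self):
        sc = preset_scenario("c78a_h2o")
        assert sc.scheme.nondecaying_fraction > 0
        sc2 = preset_scenario("c78a_h2o", slow_lifetime=100e-6)
        assert 100e-6 in sc2.scheme.lifetimes

    def test_minor_events_disabled_by_default(self):
        base = preset_scenario("fmn_d2o")
        extended = preset_scenario("fmn_d2o", include_minor_events=True)
        assert base.scheme.n_species == 3
        assert extended.scheme.n_species > base.scheme.n_species
        assert 1.3e-12 in extended.scheme.lifetimes
        assert 152e-12 in extended.scheme.lifetimes

    def test_fsrs_modality_uses_raman_column(self):
        sc = preset_scenario("wt_h2o", modality="FSRS")
        assert sc.axis.kind is AxisKind.wavenumber_cm1
        assert sc.scheme.lifetimes == (2.5e-9, 0.55e-6)
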