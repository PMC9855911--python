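"""Forward model of the flavin photocycle for synthetic test data.

The generator emulates the measured quantity of femtosecond-to-sub-
millisecond pump-probe experiments on FMN, free in solution or bound to
the EL222 LOV photoreceptor: a sequential, irreversible first-order chain
of excited states (singlet -> triplet -> adduct / ground state), each
resonant species contributing a difference spectrum built from Gaussian
bands (positive excited-state features, negative ground-state bleaches),
sampled on 53 exponentially spaced delays from 100 fs to 0.8 ms with
additive Gaussian noise.

Long-lived photoproducts (the cysteinyl-flavin adduct, the recovered
ground state) absorb near 390-450 nm and are non-resonant with an 800 nm
Raman pump, so the terminal species of a chain can be declared dark
(``final_resonant=False``): the signal then collapses at the longest
delays.  The cysteine-less EL222-C78A variant instead shows a resonant
component that does not decay within the 0.8 ms window; this is emulated
by ``nondecaying_fraction``, a constant admixture of the last resonant
spectrum.

Ground-truth lifetimes for the presets are the published mean lifetimes
of the corresponding sample/solvent/detection-region combinations (see
:data:`TABLE1_LIFETIMES`), so every recovery experiment is traceable to a
specific literature value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .datamodel import (
    AxisKind,
    DatasetMeta,
    Modality,
    SpectralAxis,
    Solvent,
    TimeGrid,
    TRDataset,
    ValidationError,
)

__all__ = [
    "KineticScheme",
    "SpeciesSpectrum",
    "Scenario",
    "TABLE1_LIFETIMES",
    "PRESET_NAMES",
    "make_log_time_grid",
    "gaussian_difference_spectrum",
    "sequential_populations",
    "simulate_dataset",
    "preset_scenario",
    "simulate_preset",
]


# ---------------------------------------------------------------------------
# Kinetic scheme and spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticScheme:
    """Irreversible sequential chain: species[i] decays only into species[i+1].

    ``lifetimes[i]`` (seconds) is the lifetime of the i-th transition, so
    ``len(lifetimes) == len(species) - 1`` and the terminal species is
    stable on the experimental window.  ``final_resonant`` states whether
    the terminal species contributes signal; ``nondecaying_fraction`` adds
    a constant fraction of the last resonant spectrum (a component with a
    lifetime at or beyond the time window).
    """

    species: tuple[str, ...]
    lifetimes: tuple[float, ...]
    final_resonant: bool = True
    nondecaying_fraction: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "lifetimes", tuple(float(t) for t in self.lifetimes))
        if len(self.species) < 1:
            raise ValidationError("scheme needs at least one species")
        if len(self.lifetimes) != len(self.species) - 1:
            raise ValidationError(
                "need exactly one lifetime per transition "
                f"({len(self.species)} species -> {len(self.species) - 1} lifetimes)"
            )
        if any(t <= 0 for t in self.lifetimes):
            raise ValidationError("lifetimes must be > 0")
        if not 0.0 <= self.nondecaying_fraction <= 1.0:
            raise ValidationError("nondecaying_fraction must lie in [0, 1]")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_resonant(self) -> int:
        return self.n_species if self.final_resonant else self.n_species - 1


@dataclass(frozen=True)
class SpeciesSpectrum:
    """Difference spectrum of one species: a sum of Gaussian bands.

    Each band is ``(center, fwhm, amplitude)`` in axis units; negative
    amplitudes encode ground-state bleaches.
    """

    bands: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        bands = tuple(
            (float(c), float(w), float(a)) for c, w, a in self.bands
        )
        object.__setattr__(self, "bands", bands)
        if not bands:
            raise ValidationError("a species spectrum needs at least one band")
        if any(w <= 0 for _, w, _ in bands):
            raise ValidationError("band fwhm must be > 0")


def gaussian_difference_spectrum(
    spec: SpeciesSpectrum, axis: SpectralAxis
) -> np.ndarray:
    """Evaluate a band set per channel: sum of a*exp(-4 ln2 (x-c)^2 / w^2)."""
    x = axis.values
    out = np.zeros_like(x)
    for center, fwhm, amp in spec.bands:
        out += amp * np.exp(-4.0 * np.log(2.0) * (x - center) ** 2 / fwhm**2)
    return out


# ---------------------------------------------------------------------------
# Time grid and populations
# ---------------------------------------------------------------------------

def make_log_time_grid(
    n: int = 53, t_min: float = 100e-15, t_max: float = 0.8e-3
) -> TimeGrid:
    """n log-equidistant delays with exact endpoints t_min and t_max."""
    if n < 2:
        raise ValidationError("need at least 2 delays")
    if not 0 < t_min < t_max:
        raise ValidationError("need 0 < t_min < t_max")
    delays = np.geomspace(t_min, t_max, n)
    delays[0], delays[-1] = t_min, t_max
    return TimeGrid(delays)


def sequential_populations(scheme: KineticScheme, times: TimeGrid) -> np.ndarray:
    """Populations of the irreversible decay chain, c(0) = (1, 0, ..., 0).

    Solved as exp(A t) e1 with the bidiagonal first-order rate matrix
    (rates k_i = 1/tau_i; the terminal species does not decay).  The
    matrix exponential is exact for any rate configuration, including
    degenerate or near-degenerate rates where the textbook Bateman
    partial-fraction formula diverges.
    """
    n = scheme.n_species
    rates = np.array([1.0 / t for t in scheme.lifetimes] + [0.0])
    A = np.zeros((n, n))
    for i in range(n):
        A[i, i] = -rates[i]
        if i > 0:
            A[i, i - 1] = rates[i - 1]
    out = np.empty((times.n_delays, n))
    for j, t in enumerate(times.delays):
        out[j] = expm(A * t)[:, 0]
    # clip tiny negative round-off so downstream code can rely on c >= 0
    np.clip(out, 0.0, None, out=out)
    return out


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_dataset(
    scheme: KineticScheme,
    spectra: Sequence[SpeciesSpectrum],
    axis: SpectralAxis,
    times: TimeGrid,
    noise_sigma: float = 0.01,
    seed: int = 0,
    meta: DatasetMeta | None = None,
) -> TRDataset:
    """Simulate a time-resolved matrix from a scheme and species spectra.

    ``spectra`` holds one spectrum per *resonant* species (the terminal
    species is skipped when ``final_resonant`` is False).  The noiseless
    signal is sum_s c_s(t) * spectrum_s(nu) plus a constant
    ``nondecaying_fraction`` admixture of the last resonant spectrum.
    Additive Gaussian noise has standard deviation ``noise_sigma`` times
    the peak absolute noiseless signal, reproducible from ``seed``.
    """
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    if len(spectra) != scheme.n_resonant:
        raise ValidationError(
            f"need one spectrum per resonant species "
            f"({scheme.n_resonant}), got {len(spectra)}"
        )
    pops = sequential_populations(scheme, times)[:, : scheme.n_resonant]
    S = np.stack([gaussian_difference_spectrum(s, axis) for s in spectra])
    signal = pops @ S
    if scheme.nondecaying_fraction > 0:
        signal = signal + scheme.nondecaying_fraction * S[-1]
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        scale = noise_sigma * np.max(np.abs(signal))
        signal = signal + rng.normal(0.0, scale, size=signal.shape)
    if meta is None:
        meta = DatasetMeta(Modality.TA, Solvent.H2O, "synthetic")
    return TRDataset(times, axis, signal, meta)


# ---------------------------------------------------------------------------
# Presets keyed to the published mean lifetimes
# ---------------------------------------------------------------------------

#: Published mean lifetimes from lifetime-distribution analysis, by sample,
#: solvent and detection region (RH = Raman high frequency 1000-1750 cm^-1,
#: RL = Raman low frequency, TA = transient absorption 380-1000 nm).
#: ``event1`` is the few-ns singlet->triplet intersystem crossing; ``event2``
#: the slower sub-us..us transition (adduct formation for EL222-WT, triplet
#: decay for free FMN / C78A).  ``minor`` lists the extra low-abundance
#: events resolved only in some datasets (label, lifetime in seconds).
#: The slow C78A lifetimes follow one plausible reading of an ambiguous
#: published table row and are overridable per preset.
TABLE1_LIFETIMES: dict[tuple[str, str], dict] = {
    ("FMN", "H2O"): {
        "event1": {"RH": 2.9e-9, "RL": 3.3e-9, "TA": 3.8e-9},
        "event2": {"RH": 0.32e-6, "RL": 0.40e-6, "TA": 0.32e-6},
        "minor": {"TA": [("alpha", 115e-12), ("beta", 91e-6)]},
    },
    ("FMN", "D2O"): {
        "event1": {"RH": 3.2e-9, "RL": 3.1e-9, "TA": 2.9e-9},
        "event2": {"RH": 1.7e-6, "RL": 1.5e-6, "TA": 3.0e-6},
        "minor": {"TA": [("gamma", 1.3e-12), ("delta", 152e-12)]},
    },
    ("EL222-WT", "H2O"): {
        "event1": {"RH": 2.5e-9, "RL": 2.7e-9, "TA": 2.6e-9},
        "event2": {"RH": 0.55e-6, "RL": 0.66e-6, "TA": 0.63e-6},
        "minor": {},
    },
    ("EL222-WT", "D2O"): {
        "event1": {"RH": 2.5e-9, "RL": 3.7e-9, "TA": 2.6e-9},
        "event2": {"RH": 4.2e-6, "RL": 7.6e-6, "TA": 4.9e-6},
        "minor": {},
    },
    ("EL222-C78A", "H2O"): {
        "event1": {"RH": 3.9e-9, "RL": 4.4e-9, "TA": 3.2e-9},
        "event2": {"RH": 87e-6, "TA": 208e-6},
        "minor": {},
    },
    ("EL222-C78A", "D2O"): {
        "event1": {"RH": 3.1e-9, "RL": 3.4e-9, "TA": 2.7e-9},
        "event2": {"RH": 109e-6, "TA": 269e-6},
        "minor": {},
    },
}

_PRESET_SAMPLE = {
    "fmn": "FMN",
    "wt": "EL222-WT",
    "c78a": "EL222-C78A",
}

PRESET_NAMES = (
    "fmn_h2o",
    "fmn_d2o",
    "wt_h2o",
    "wt_d2o",
    "c78a_h2o",
    "c78a_d2o",
)

# Difference spectra used by the TA presets (380-1000 nm): ground-state
# bleach near 445 nm, singlet excited-state absorption ~510 nm, stimulated
# emission ~565 nm, triplet-triplet absorption ~660-710 nm.  Band positions
# are representative of oxidized flavins; amplitudes are arbitrary units.
_TA_SINGLET = SpeciesSpectrum(
    bands=((445.0, 90.0, -1.0), (510.0, 80.0, 0.75), (565.0, 110.0, -0.5))
)
_TA_TRIPLET = SpeciesSpectrum(
    bands=((445.0, 90.0, -0.9), (660.0, 150.0, 0.85), (500.0, 60.0, 0.25))
)

# FSRS presets (high-frequency region 1000-1750 cm^-1): positive
# excited-state Raman bands and negative ground-state bleaches around the
# strong isoalloxazine ring/carbonyl modes.
_RH_SINGLET = SpeciesSpectrum(
    bands=((1215.0, 28.0, 0.9), (1390.0, 32.0, 0.6), (1505.0, 35.0, -0.8))
)
_RH_TRIPLET = SpeciesSpectrum(
    bands=((1240.0, 30.0, 0.8), (1440.0, 34.0, 0.7), (1505.0, 35.0, -0.7))
)

# Small distinct spectra for the optional minor events (solvent response,
# ribityl-chain motion, late radical-like component).
_TA_MINOR_FAST = SpeciesSpectrum(bands=((480.0, 70.0, 0.3), (445.0, 90.0, -1.0)))
_TA_MINOR_SLOW = SpeciesSpectrum(bands=((570.0, 90.0, 0.25),))


@dataclass(frozen=True)
class Scenario:
    """Fully specified simulation configuration with its ground truth."""

    name: str
    scheme: KineticScheme
    spectra: tuple[SpeciesSpectrum, ...]
    axis: SpectralAxis
    times: TimeGrid
    noise_sigma: float
    meta: DatasetMeta
    ground_truth_lifetimes: tuple[float, ...]


def preset_scenario(
    name: str,
    n_channels: int = 64,
    noise_sigma: float = 0.01,
    modality: str | Modality = Modality.TA,
    include_minor_events: bool = False,
    slow_lifetime: float | None = None,
) -> Scenario:
    """Build the simulation configuration for a named sample/solvent preset.

    TA presets (the default modality) take their ground-truth lifetimes
    from the transient-absorption column of the published lifetime table;
    FSRS presets use the Raman high-frequency column and a 1000-1750 cm^-1
    axis.  ``slow_lifetime`` overrides the ambiguous slow C78A lifetime.
    ``include_minor_events`` enables the low-abundance extra events listed
    for free FMN (disabled by default).
    """
    if name not in PRESET_NAMES:
        raise ValidationError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    prefix, solvent_key = name.rsplit("_", 1)
    sample = _PRESET_SAMPLE[prefix]
    solvent = Solvent(solvent_key.upper())
    modality = Modality(modality)
    col = "TA" if modality is Modality.TA else "RH"
    entry = TABLE1_LIFETIMES[(sample, solvent.value)]
    tau1 = entry["event1"][col]
    tau2 = entry["event2"][col]
    if prefix == "c78a" and slow_lifetime is not None:
        tau2 = float(slow_lifetime)

    if modality is Modality.TA:
        axis = SpectralAxis(
            AxisKind.wavelength_nm, np.linspace(380.0, 1000.0, n_channels)
        )
        singlet, triplet = _TA_SINGLET, _TA_TRIPLET
    else:
        axis = SpectralAxis(
            AxisKind.wavenumber_cm1, np.linspace(1000.0, 1750.0, n_channels)
        )
        singlet, triplet = _RH_SINGLET, _RH_TRIPLET

    species = ["S1", "T1", "FINAL"]
    lifetimes = [tau1, tau2]
    spectra = [singlet, triplet]
    nondecaying = 0.15 if prefix == "c78a" else 0.0

    if include_minor_events:
        minors = entry["minor"].get(col, [])
        for label, tau in minors:
            if tau < tau1:  # fast events precede the singlet equilibration
                species.insert(0, label.upper())
                lifetimes.insert(0, tau)
                spectra.insert(0, _TA_MINOR_FAST)
            else:  # slow events between event 2 and the terminal state
                species.insert(-1, label.upper())
                lifetimes.append(tau)
                spectra.append(_TA_MINOR_SLOW)

    scheme = KineticScheme(
        species=tuple(species),
        lifetimes=tuple(lifetimes),
        final_resonant=False,
        nondecaying_fraction=nondecaying,
    )
    return Scenario(
        name=name,
        scheme=scheme,
        spectra=tuple(spectra),
        axis=axis,
        times=make_log_time_grid(),
        noise_sigma=noise_sigma,
        meta=DatasetMeta(modality, solvent, sample),
        ground_truth_lifetimes=tuple(sorted(lifetimes)),
    )


def simulate_preset(name: str, seed: int = 0, **kwargs) -> tuple[TRDataset, Scenario]:
    """Simulate a preset scenario; returns the dataset and its ground truth."""
    sc = preset_scenario(name, **kwargs)
    ds = simulate_dataset(
        sc.scheme, sc.spectra, sc.axis, sc.times, sc.noise_sigma, seed, sc.meta
    )
    return ds, sc
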