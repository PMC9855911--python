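"""Dynamical content D(tau), peak significance, and event tables.

The dynamical content condenses a lifetime density map into one curve
per spectral region,

    D(tau_k) = sum_i a_{i,k}^2 ,

summing squared LDA amplitudes over the channels i inside the region
(per-channel offsets are excluded: a non-decaying component has no
lifetime coordinate).  Peaks of D mark the time scales at which spectral
change happens.  A peak is the region around a strict local maximum,
delimited by the flanking local minima (or grid edges); its area is the
trapezoidal integral of D over log10(tau), and only peaks carrying
strictly more than 10% of the total area count as significant dynamical
events.  Event lifetimes are reported as the D-weighted geometric mean
of tau within the peak (the natural mean on a logarithmic grid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .datamodel import DatasetMeta, Region, ValidationError, get_region
from .lda import AmplitudeMap, LifetimeGrid

logger = logging.getLogger("flavidyn")

__all__ = [
    "DynamicalContent",
    "Peak",
    "Event",
    "EventTable",
    "SIGNIFICANCE_THRESHOLD",
    "compute_dynamical_content",
    "normalize_content",
    "detect_peaks",
    "summarize_events",
]

#: Relative-area threshold above which a D peak counts as a dynamical event.
SIGNIFICANCE_THRESHOLD = 0.10

GREEK_LABELS = ("α", "β", "γ", "δ", "ε", "ζ", "η", "θ", "ι", "κ")


@dataclass(frozen=True)
class DynamicalContent:
    grid: LifetimeGrid
    D: np.ndarray
    region: Region | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        object.__setattr__(self, "D", D)
        if D.shape != (self.grid.n_taus,):
            raise ValidationError("D must have one value per grid lifetime")
        if np.any(D < 0) or not np.all(np.isfinite(D)):
            raise ValidationError("D must be finite and non-negative")
        if self.normalized and abs(D.max() - 1.0) > 1e-12:
            raise ValidationError("normalized D must have max 1")


@dataclass(frozen=True)
class Peak:
    lo_idx: int
    hi_idx: int
    argmax_idx: int
    center_tau: float
    area: float
    relative_area: float
    significant: bool


@dataclass(frozen=True)
class Event:
    label: str
    center_tau: float
    relative_area: float


@dataclass(frozen=True)
class EventTable:
    """Significant dynamical events of one dataset/region, by lifetime."""

    events: tuple[Event, ...]
    sample: str = ""
    solvent: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        centers = [e.center_tau for e in events]
        if centers != sorted(centers):
            raise ValidationError("events must be ordered by center lifetime")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "label": e.label,
                    "center_tau_s": e.center_tau,
                    "relative_area": e.relative_area,
                }
                for e in self.events
            ]
        )


def compute_dynamical_content(
    amap: AmplitudeMap, region: Region | str | None = None
) -> DynamicalContent:
    """D(tau_k) = sum over in-region channels of a_{i,k}^2; offsets excluded."""
    if region is None:
        mask = np.ones(amap.axis.n_channels, dtype=bool)
        region_obj = None
    else:
        if isinstance(region, str):
            region = get_region(region, amap.axis)
        if region.kind != amap.axis.kind:
            raise ValidationError(
                f"region {region.name!r} kind does not match the map axis"
            )
        mask = (amap.axis.values >= region.lo) & (amap.axis.values <= region.hi)
        if not mask.any():
            raise ValidationError(
                f"region {region.name!r} selects no channels of the amplitude map"
            )
        region_obj = region
    D = np.sum(amap.amplitudes[mask, :] ** 2, axis=0)
    return DynamicalContent(grid=amap.grid, D=D, region=region_obj, normalized=False)


def normalize_content(dc: DynamicalContent) -> DynamicalContent:
    """Divide by max(D); idempotent; errors on an all-zero curve."""
    peak = float(dc.D.max())
    if peak <= 0:
        raise ValidationError("cannot normalize an all-zero dynamical content")
    return DynamicalContent(dc.grid, dc.D / peak, dc.region, normalized=True)


def _local_maxima(D: np.ndarray) -> list[int]:
    return [
        i for i in range(1, D.size - 1) if D[i] > D[i - 1] and D[i] > D[i + 1]
    ]


def detect_peaks(
    dc: DynamicalContent, min_rel_area: float = SIGNIFICANCE_THRESHOLD
) -> list[Peak]:
    """Peaks of D around strict local maxima, delimited by local minima.

    Areas are trapezoidal integrals of D over log10(tau); relative areas
    are fractions of the total area over the full grid.  Significance is
    strict: relative_area > ``min_rel_area``.
    """
    if dc.grid.n_taus < 3:
        raise ValidationError("peak detection needs at least 3 grid points")
    D = dc.D
    logt = np.log10(dc.grid.taus)
    total = float(np.trapezoid(D, logt))
    maxima = _local_maxima(D)
    if not maxima or total <= 0:
        return []

    # peak boundaries: minimum of D between consecutive maxima, grid edges outside
    bounds = [0]
    for a, b in zip(maxima[:-1], maxima[1:]):
        bounds.append(a + int(np.argmin(D[a : b + 1])))
    bounds.append(D.size - 1)

    peaks: list[Peak] = []
    for k, imax in enumerate(maxima):
        lo, hi = bounds[k], bounds[k + 1]
        area = float(np.trapezoid(D[lo : hi + 1], logt[lo : hi + 1]))
        rel = area / total
        w = D[lo : hi + 1]
        wsum = float(w.sum())
        center = float(np.exp(np.sum(w * np.log(dc.grid.taus[lo : hi + 1])) / wsum))
        peaks.append(
            Peak(
                lo_idx=lo,
                hi_idx=hi,
                argmax_idx=imax,
                center_tau=center,
                area=area,
                relative_area=rel,
                significant=rel > min_rel_area,
            )
        )
    return peaks


def summarize_events(
    peaks: list[Peak],
    sample: str = "",
    solvent: str = "",
    region: str = "",
) -> EventTable:
    """Label significant peaks: the two largest-area events get "1" and "2"
    (by ascending lifetime), the rest Greek letters by ascending lifetime."""
    sig = sorted((p for p in peaks if p.significant), key=lambda p: p.center_tau)
    if not sig:
        logger.warning("no significant dynamical events detected")
        return EventTable(events=(), sample=sample, solvent=solvent, region=region)
    by_area = sorted(sig, key=lambda p: p.area, reverse=True)
    main = set(id(p) for p in by_area[:2])
    labels: dict[int, str] = {}
    n_main = 0
    n_greek = 0
    for p in sig:
        if id(p) in main:
            n_main += 1
            labels[id(p)] = str(n_main)
        else:
            labels[id(p)] = GREEK_LABELS[min(n_greek, len(GREEK_LABELS) - 1)]
            n_greek += 1
    events = tuple(
        Event(label=labels[id(p)], center_tau=p.center_tau, relative_area=p.relative_area)
        for p in sig
    )
    return EventTable(events=events, sample=sample, solvent=solvent, region=region)
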