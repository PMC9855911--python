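"""Kinetic isotope effects from paired H2O/D2O event tables.

The KIE of a photocycle step is the ratio tau(D2O) / tau(H2O) of its
lifetime in the two solvents.  A KIE near 1 means no labile X-H bond
breaks in the rate-limiting step; values well above 1 (7-12 for the
triplet-to-adduct conversion of EL222-WT) implicate proton transfer as
rate-limiting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import ValidationError
from .dynamics import Event, EventTable

logger = logging.getLogger("flavidyn")

__all__ = ["KIEPair", "KIEResult", "match_events", "compute_kie"]

#: Classification boundary between "no isotope effect" (~1) and a
#: proton-transfer-limited step (observed ~7-12); conservative midpoint.
KIE_CLASS_BOUNDARY = 2.0


@dataclass(frozen=True)
class KIEPair:
    label: str
    tau_h: float
    tau_d: float

    @property
    def log10_gap(self) -> float:
        return abs(np.log10(self.tau_d / self.tau_h))


@dataclass(frozen=True)
class KIEResult:
    """Matched pairs with their lifetime ratios and classification."""

    pairs: tuple[KIEPair, ...]
    kie: tuple[float, ...]
    classification: tuple[str, ...]
    unmatched_h: tuple[Event, ...] = ()
    unmatched_d: tuple[Event, ...] = ()

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "label": p.label,
                    "tau_h_s": p.tau_h,
                    "tau_d_s": p.tau_d,
                    "kie": k,
                    "class": c,
                }
                for p, k, c in zip(self.pairs, self.kie, self.classification)
            ]
        )


def match_events(
    h2o: EventTable, d2o: EventTable, max_log10_gap: float = 1.0
) -> tuple[list[KIEPair], list[Event], list[Event]]:
    """Pair events across solvents by photocycle identity.

    Equal event counts are matched by rank (ascending lifetime), mirroring
    how events 1 and 2 align across solvents.  Unequal counts fall back to
    greedy nearest-log10-lifetime matching; pairs further apart than
    ``max_log10_gap`` decades are discarded and reported unmatched.
    Returns (pairs, unmatched_h2o, unmatched_d2o).
    """
    if h2o.n_events == 0 or d2o.n_events == 0:
        raise ValidationError("cannot match events against an empty table")

    if h2o.n_events == d2o.n_events:
        pairs = [
            KIEPair(eh.label, eh.center_tau, ed.center_tau)
            for eh, ed in zip(h2o.events, d2o.events)
        ]
        return pairs, [], []

    remaining_h = list(h2o.events)
    remaining_d = list(d2o.events)
    pairs: list[KIEPair] = []
    while remaining_h and remaining_d:
        best = None
        for eh in remaining_h:
            for ed in remaining_d:
                gap = abs(np.log10(ed.center_tau / eh.center_tau))
                if best is None or gap < best[0]:
                    best = (gap, eh, ed)
        gap, eh, ed = best
        if gap > max_log10_gap:
            break
        pairs.append(KIEPair(eh.label, eh.center_tau, ed.center_tau))
        remaining_h.remove(eh)
        remaining_d.remove(ed)
    for e in remaining_h + remaining_d:
        logger.info("unmatched event %s at %.3g s", e.label, e.center_tau)
    pairs.sort(key=lambda p: p.tau_h)
    return pairs, remaining_h, remaining_d


def compute_kie(
    pairs,
    unmatched_h=(),
    unmatched_d=(),
    class_boundary: float = KIE_CLASS_BOUNDARY,
) -> KIEResult:
    """KIE = tau_D / tau_H per pair with a two-way classification."""
    pairs = tuple(pairs)
    if not pairs:
        raise ValidationError("need at least one matched pair")
    if any(p.tau_h <= 0 or p.tau_d <= 0 for p in pairs):
        raise ValidationError("lifetimes must be > 0")
    kie = tuple(p.tau_d / p.tau_h for p in pairs)
    classification = tuple(
        "proton_transfer_limited" if k > class_boundary else "none" for k in kie
    )
    return KIEResult(
        pairs=pairs,
        kie=kie,
        classification=classification,
        unmatched_h=tuple(unmatched_h),
        unmatched_d=tuple(unmatched_d),
    )
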