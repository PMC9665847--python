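"""Behavioural endpoints computed by rule.

Von Frey paw-withdrawal threshold: the lowest filament force that
caused at least three withdrawals out of five applications.  Zone
metrics (open-arm time, light-zone transitions, etc.) are fractions of
tracked samples in a zone and counts of entries into it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import VonFreyTable
from .traces import InputError

__all__ = ["VonFreyTable", "ZoneTrack", "pw_threshold", "zone_metrics"]

WITHDRAWAL_CRITERION = 3  # of 5 applications


def pw_threshold(table: VonFreyTable, criterion: int = WITHDRAWAL_CRITERION) -> float | None:
    """Paw-withdrawal threshold (g) from a von Frey table.

    The threshold is the lowest force whose withdrawal count reaches the
    criterion (≥3 of 5); the rule is applied literally, so non-monotone
    counts still yield the lowest qualifying force.  Returns ``None``
    (above-range, no numeric threshold) when no filament qualifies — no
    ceiling value is imputed.
    """
    qualifying = np.flatnonzero(table.withdrawals >= criterion)
    if qualifying.size == 0:
        return None
    return float(table.filaments_g[qualifying[0]])


@dataclass(frozen=True)
class ZoneTrack:
    """Zone label per tracked video sample."""

    labels: np.ndarray  # zone id per sample (any hashable dtype)
    rate_hz: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.size == 0:
            raise InputError("zone track must be nonempty")
        object.__setattr__(self, "labels", labels)


def zone_metrics(track: ZoneTrack, zone_of_interest) -> dict[str, float]:
    """Fraction of time in a zone and number of entries into it.

    ``fraction_time`` is the fraction of samples carrying the zone
    label; ``n_transitions`` counts entries into the zone (the
    light/dark-box "transitions" convention).  An entry is a label
    change from outside to inside, so a track that starts inside the
    zone and never leaves has zero transitions.
    """
    labels = track.labels
    if labels.size < 2:
        raise InputError("zone metrics need at least two samples")
    if zone_of_interest not in labels:
        raise InputError(f"unknown zone id {zone_of_interest!r}")
    inside = labels == zone_of_interest
    entries = int(np.sum(~inside[:-1] & inside[1:]))
    return {
        "fraction_time": float(inside.mean()),
        "n_transitions": entries,
    }
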