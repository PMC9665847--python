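"""Intrinsic-excitability profiling from current-clamp step protocols.

Extracts per-neuron: the f-I curve (spike count vs injected current),
rheobase (smallest tested current evoking ≥1 spike), first-spike delay
at the rheobase sweep, the early-/late-spiking phenotype (late-spiking
iff the delay exceeds 1.5 s, strict), resting membrane potential, and
input resistance from the smallest hyperpolarizing step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import StepSweep
from .traces import InputError

__all__ = [
    "ExcitabilityProfile",
    "RheobaseUndefinedError",
    "detect_spikes",
    "profile_neuron",
    "LS_DELAY_THRESHOLD_S",
]

# first-spike delay at rheobase above which a neuron is late-spiking
LS_DELAY_THRESHOLD_S = 1.5


class RheobaseUndefinedError(InputError):
    """No tested sweep evoked a spike."""


def detect_spikes(
    sweep: StepSweep, threshold_mv: float = -20.0, refractory_ms: float = 2.0
) -> np.ndarray:
    """Spike times from upward threshold crossings with positive slope.

    Crossings closer together than the refractory period are counted
    once (guards against waveform re-crossing).  Returns times in
    seconds from sweep start; an empty result is allowed.
    """
    v = sweep.voltage.samples
    rate = sweep.voltage.rate_hz
    above = v >= threshold_mv
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if crossings.size == 0:
        return np.empty(0)
    min_gap = max(int(round(refractory_ms / 1000.0 * rate)), 1)
    accepted = [crossings[0]]
    for i in crossings[1:]:
        if i - accepted[-1] >= min_gap:
            accepted.append(i)
    return np.asarray(accepted) / rate


@dataclass(frozen=True)
class ExcitabilityProfile:
    """Per-neuron intrinsic-excitability summary."""

    fi: list[tuple[float, int]]
    rheobase_pa: float
    first_spike_delay_s: float
    phenotype: str  # "ES" or "LS"
    rmp_mv: float
    rin_mohm: float | None


def profile_neuron(
    sweeps: list[StepSweep],
    spike_threshold_mv: float = -20.0,
    refractory_ms: float = 2.0,
) -> ExcitabilityProfile:
    """Build an :class:`ExcitabilityProfile` from a step-protocol family.

    Rheobase is the smallest injected current with at least one spike;
    the first-spike delay is measured from step onset at the rheobase
    sweep only.  RMP is the mean pre-step voltage across sweeps; input
    resistance is ΔV_steady/ΔI from the smallest-magnitude
    hyperpolarizing step (steady state = final 20% of the step), omitted
    with a warning when no such step exists.
    """
    if not sweeps:
        raise InputError("no sweeps provided")
    sweeps = sorted(sweeps, key=lambda s: s.injected_pa)

    fi: list[tuple[float, int]] = []
    spike_times: dict[float, np.ndarray] = {}
    rmp_parts = []
    for s in sweeps:
        rate = s.voltage.rate_hz
        i_on = int(round(s.step_onset_s * rate))
        rmp_parts.append(s.voltage.samples[:i_on])
        times = detect_spikes(s, spike_threshold_mv, refractory_ms)
        times = times[(times >= s.step_onset_s) & (times < s.step_offset_s)]
        spike_times[s.injected_pa] = times
        fi.append((s.injected_pa, int(times.size)))
    rmp = float(np.concatenate(rmp_parts).mean())

    spiking = [s for s in sweeps if spike_times[s.injected_pa].size > 0]
    if not spiking:
        raise RheobaseUndefinedError("no sweep evoked a spike; rheobase undefined")
    rheo_sweep = spiking[0]
    rheobase = rheo_sweep.injected_pa
    delay = float(spike_times[rheobase][0] - rheo_sweep.step_onset_s)
    phenotype = "LS" if delay > LS_DELAY_THRESHOLD_S else "ES"

    rin = None
    hyper = [s for s in sweeps if s.injected_pa < 0]
    if hyper:
        s = max(hyper, key=lambda s: s.injected_pa)  # smallest magnitude
        rate = s.voltage.rate_hz
        i_on = int(round(s.step_onset_s * rate))
        i_off = int(round(s.step_offset_s * rate))
        steady_start = i_off - max((i_off - i_on) // 5, 1)
        v_steady = float(s.voltage.samples[steady_start:i_off].mean())
        v_pre = float(s.voltage.samples[:i_on].mean())
        # mV / pA = GΩ; report MΩ
        rin = (v_steady - v_pre) / s.injected_pa * 1000.0
    else:
        warnings.warn("no hyperpolarizing step; input resistance omitted", stacklevel=2)

    return ExcitabilityProfile(
        fi=fi,
        rheobase_pa=float(rheobase),
        first_spike_delay_s=delay,
        phenotype=phenotype,
        rmp_mv=rmp,
        rin_mohm=rin,
    )
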