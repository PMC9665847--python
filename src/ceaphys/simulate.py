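"""Synthetic recordings with known ground truth.

Every input the analysis pipeline consumes can be generated here:
miniscope ΔF/F trial pairs around a drug treatment, voltage-clamp
sweeps with spontaneous EPSCs, paired-pulse sweeps, current-clamp step
protocols from a leaky integrate-and-fire (LIF) cell, and von Frey
withdrawal tables.  All draws flow from one seeded
:class:`numpy.random.Generator` per call; identical seed and
configuration give bit-identical output.

The calcium transient is a peak-normalized double exponential
(1 - e^{-t/τ_rise}) e^{-t/τ_decay} — the standard phenomenological model
of a slow indicator such as GCaMP6s — convolved with a Poisson event
train; the drug acts multiplicatively on the per-neuron event rate
(inhibited neurons divided, excited neurons multiplied by the effect
size), optionally on amplitude as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .detect import double_exponential_template
from .traces import ConfigurationError, InputError, Trace, TrialPair

__all__ = [
    "SimConfig",
    "CalciumGroundTruth",
    "EpscGroundTruth",
    "StepGroundTruth",
    "LIFParams",
    "StepSweep",
    "PairedPulseSweep",
    "VonFreyTable",
    "simulate_calcium_cohort",
    "simulate_epsc_trace",
    "simulate_paired_pulse_sweeps",
    "simulate_current_steps",
    "simulate_vonfrey_table",
]

LABEL_INHIBITED = "inhibited"
LABEL_EXCITED = "excited"
LABEL_NO_EFFECT = "no_effect"


@dataclass(frozen=True)
class SimConfig:
    """Conditions for a simulated drug-treatment imaging session.

    Defaults mirror a miniscope session on amygdala neurons expressing a
    slow calcium indicator: 15 Hz acquisition, 9-minute trials, sparse
    spontaneous transients (~0.05 Hz) of ~0.3 ΔF/F, and a strong
    multiplicative drug effect on the event rate in half of the cohort.
    """

    seed: int = 0
    n_neurons: int = 46
    frac_inhibited: float = 0.5
    frac_excited: float = 0.1
    effect_size: float = 5.0
    event_rate_hz: float = 0.05
    transient_rise_s: float = 0.2
    transient_decay_s: float = 1.0
    amp_mean: float = 0.3
    amp_sd: float = 0.1
    noise_sd: float = 0.05
    frame_rate_hz: float = 15.0
    trial_duration_s: float = 540.0
    effect_on: str = "rate"  # "rate" | "amplitude" | "both"
    drift_per_s: float = 0.0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ConfigurationError("n_neurons must be >= 1")
        if not (0 <= self.frac_inhibited <= 1 and 0 <= self.frac_excited <= 1):
            raise ConfigurationError("fractions must lie in [0, 1]")
        if self.frac_inhibited + self.frac_excited > 1 + 1e-12:
            raise ConfigurationError("frac_inhibited + frac_excited must be <= 1")
        if self.effect_size < 1:
            raise ConfigurationError("effect_size must be >= 1 (multiplicative)")
        for name in ("event_rate_hz", "amp_mean", "amp_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.transient_rise_s <= 0 or self.transient_decay_s <= 0:
            raise ConfigurationError("transient time constants must be positive")
        if self.frame_rate_hz not in (15.0, 20.0, 15, 20):
            raise ConfigurationError("frame_rate_hz must be 15 or 20")
        if self.trial_duration_s < 360:
            raise ConfigurationError(
                "trial_duration_s must be >= 360 s (the scored window is 6 min)"
            )
        if self.effect_on not in ("rate", "amplitude", "both"):
            raise ConfigurationError("effect_on must be 'rate', 'amplitude' or 'both'")


@dataclass
class CalciumGroundTruth:
    """Per-neuron truth for a simulated cohort."""

    labels: dict[str, str]
    baseline_events: dict[str, np.ndarray]
    post_events: dict[str, np.ndarray]

    def label_counts(self) -> dict[str, int]:
        counts = {LABEL_INHIBITED: 0, LABEL_EXCITED: 0, LABEL_NO_EFFECT: 0}
        for lab in self.labels.values():
            counts[lab] += 1
        return counts


def _poisson_times(rng: np.random.Generator, rate_hz: float, duration_s: float) -> np.ndarray:
    if rate_hz <= 0 or not np.isfinite(rate_hz):
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def _render_trace(
    rng: np.random.Generator,
    event_times: np.ndarray,
    amplitudes: np.ndarray,
    kernel: np.ndarray,
    n_samples: int,
    rate_hz: float,
    noise_sd: float,
    drift_per_s: float = 0.0,
) -> np.ndarray:
    x = np.zeros(n_samples + kernel.size)
    idx = np.round(event_times * rate_hz).astype(int)
    np.add.at(x, idx, amplitudes)
    x = np.convolve(x, kernel)[:n_samples]
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=n_samples)
    if drift_per_s != 0.0:
        x = x + drift_per_s * np.arange(n_samples) / rate_hz
    return x


def simulate_calcium_cohort(
    config: SimConfig,
) -> tuple[list[TrialPair], CalciumGroundTruth]:
    """Simulate baseline/post-drug ΔF/F trial pairs for a cohort.

    Inhibited neurons have their post-drug event rate (and/or amplitude,
    per ``effect_on``) divided by ``effect_size``, excited neurons
    multiplied, no-effect neurons are unchanged.  Returns the trial
    pairs and the ground truth (labels and true event times).

    Note that under the (default) rate effect, excited and inhibited
    neurons produce *asymmetric* ΔAUC magnitudes after min–max
    normalization (an excited neuron's AUC gain is ~``effect_size``
    times an inhibited neuron's loss, because normalization absorbs
    amplitude scale but not event pileup); the amplitude effect yields
    symmetric magnitudes and is the appropriate condition for
    fraction-recovery studies of the σdev classifier.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_neurons
    n_inh = int(round(config.frac_inhibited * n))
    n_exc = int(round(config.frac_excited * n))
    if n_inh + n_exc > n:  # rounding overshoot on tiny cohorts
        n_exc = n - n_inh
    labels_arr = np.array(
        [LABEL_INHIBITED] * n_inh
        + [LABEL_EXCITED] * n_exc
        + [LABEL_NO_EFFECT] * (n - n_inh - n_exc)
    )
    rng.shuffle(labels_arr)

    kernel = double_exponential_template(
        config.transient_rise_s, config.transient_decay_s, config.frame_rate_hz
    )
    n_samples = int(round(config.trial_duration_s * config.frame_rate_hz))
    pairs: list[TrialPair] = []
    labels: dict[str, str] = {}
    bl_events: dict[str, np.ndarray] = {}
    post_events: dict[str, np.ndarray] = {}

    on_rate = config.effect_on in ("rate", "both")
    on_amp = config.effect_on in ("amplitude", "both")
    for i, label in enumerate(labels_arr):
        neuron_id = f"n{i:03d}"
        if label == LABEL_INHIBITED:
            effect = 1.0 / config.effect_size
        elif label == LABEL_EXCITED:
            effect = config.effect_size
        else:
            effect = 1.0
        post_rate = config.event_rate_hz * effect if on_rate else config.event_rate_hz
        amp_factor = effect if on_amp else 1.0

        traces = []
        for rate, factor, store in (
            (config.event_rate_hz, 1.0, bl_events),
            (post_rate, amp_factor, post_events),
        ):
            times = _poisson_times(rng, rate, config.trial_duration_s)
            amps = np.abs(rng.normal(config.amp_mean, config.amp_sd, size=times.size))
            amps = amps * factor
            store[neuron_id] = times
            traces.append(
                Trace(
                    _render_trace(
                        rng,
                        times,
                        amps,
                        kernel,
                        n_samples,
                        config.frame_rate_hz,
                        config.noise_sd,
                        config.drift_per_s,
                    ),
                    rate_hz=config.frame_rate_hz,
                )
            )
        labels[neuron_id] = str(label)
        pairs.append(TrialPair(neuron_id=neuron_id, baseline=traces[0], post=traces[1]))

    return pairs, CalciumGroundTruth(labels, bl_events, post_events)


@dataclass
class EpscGroundTruth:
    """True EPSC times, amplitudes, decay constants and mixture component."""

    times_s: np.ndarray
    amplitudes_pa: np.ndarray
    decay_taus_ms: np.ndarray
    components: np.ndarray


def simulate_epsc_trace(
    rate_hz: float,
    amp_mean_pa: float = 15.0,
    amp_sd_pa: float = 3.0,
    decay_populations: list[tuple[float, float]] = ((1.0, 5.0),),
    duration_s: float = 60.0,
    noise_sd_pa: float = 2.0,
    seed: int = 0,
    sample_rate_hz: float = 10000.0,
    rise_ms: float = 0.5,
) -> tuple[Trace, EpscGroundTruth]:
    """Simulate a voltage-clamp current trace with spontaneous EPSCs.

    Events occur at Poisson times; each is an inward (negative) double
    exponential with decay τ drawn from a mixture of
    ``(weight, tau_ms)`` populations.
    """
    if rate_hz < 0:
        raise ConfigurationError("rate_hz must be >= 0")
    weights = np.array([w for w, _ in decay_populations], dtype=float)
    taus = np.array([t for _, t in decay_populations], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ConfigurationError("decay population weights must sum to 1")
    if np.any(taus <= 0):
        raise ConfigurationError("decay taus must be positive")

    rng = np.random.default_rng(seed)
    times = _poisson_times(rng, rate_hz, duration_s)
    n_ev = times.size
    amps = np.abs(rng.normal(amp_mean_pa, amp_sd_pa, size=n_ev))
    comp = rng.choice(weights.size, size=n_ev, p=weights)
    ev_taus = taus[comp]

    n_samples = int(round(duration_s * sample_rate_hz))
    x = np.zeros(n_samples)
    for t, a, tau in zip(times, amps, ev_taus):
        kernel = double_exponential_template(rise_ms / 1000.0, tau / 1000.0, sample_rate_hz)
        i0 = int(round(t * sample_rate_hz))
        i1 = min(i0 + kernel.size, n_samples)
        x[i0:i1] -= a * kernel[: i1 - i0]
    if noise_sd_pa > 0:
        x = x + rng.normal(0.0, noise_sd_pa, size=n_samples)

    truth = EpscGroundTruth(times, amps, ev_taus, comp)
    return Trace(x, rate_hz=sample_rate_hz), truth


@dataclass(frozen=True)
class PairedPulseSweep:
    """One paired-pulse sweep: current trace plus the two pulse onsets."""

    current: Trace
    pulse_onsets_s: tuple[float, float]


def simulate_paired_pulse_sweeps(
    a1_pa: float,
    ppr_true: float,
    interval_ms: float = 200.0,
    kinetics: tuple[float, float] = (0.5, 5.0),
    n_sweeps: int = 10,
    noise_sd_pa: float = 0.0,
    seed: int = 0,
    sample_rate_hz: float = 10000.0,
    pre_ms: float = 50.0,
    post_ms: float = 100.0,
) -> list[PairedPulseSweep]:
    """Simulate evoked paired-pulse EPSC sweeps with a known true ratio.

    Each sweep contains two inward EPSCs whose noise-free amplitude
    ratio is exactly ``ppr_true``; the second pulse may ride on the
    residual decay of the first when the interval is short.
    """
    if interval_ms <= 0:
        raise ConfigurationError("interval_ms must be positive")
    if a1_pa <= 0 or ppr_true <= 0:
        raise ConfigurationError("a1_pa and ppr_true must be positive")
    rng = np.random.default_rng(seed)
    rise_ms, decay_ms = kinetics
    kernel = double_exponential_template(rise_ms / 1000.0, decay_ms / 1000.0, sample_rate_hz)
    onset1 = pre_ms / 1000.0
    onset2 = onset1 + interval_ms / 1000.0
    duration_s = onset2 + (decay_ms * 6 + post_ms) / 1000.0
    n_samples = int(round(duration_s * sample_rate_hz))

    sweeps = []
    for _ in range(n_sweeps):
        x = np.zeros(n_samples)
        for onset, amp in ((onset1, a1_pa), (onset2, a1_pa * ppr_true)):
            i0 = int(round(onset * sample_rate_hz))
            i1 = min(i0 + kernel.size, n_samples)
            x[i0:i1] -= amp * kernel[: i1 - i0]
        if noise_sd_pa > 0:
            x = x + rng.normal(0.0, noise_sd_pa, size=n_samples)
        sweeps.append(
            PairedPulseSweep(Trace(x, rate_hz=sample_rate_hz), (onset1, onset2))
        )
    return sweeps


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire cell parameters."""

    e_l_mv: float = -70.0
    v_th_mv: float = -55.0
    g_l_ns: float = 10.0
    tau_m_ms: float = 20.0
    v_reset_mv: float = -65.0
    refractory_ms: float = 3.0
    spike_peak_mv: float = 30.0

    @property
    def rheobase_pa(self) -> float:
        """Analytic rheobase g_L (V_th − E_L)."""
        return self.g_l_ns * (self.v_th_mv - self.e_l_mv)


@dataclass(frozen=True)
class StepSweep:
    """A current-clamp step sweep."""

    voltage: Trace
    injected_pa: float
    step_onset_s: float
    step_offset_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.step_onset_s < self.step_offset_s <= self.voltage.duration_s):
            raise InputError("step window must lie inside the sweep")


@dataclass
class StepGroundTruth:
    """Analytic truth for a simulated step protocol."""

    rheobase_pa: float
    latency_by_step_s: dict[float, float]
    params: LIFParams


def lif_first_spike_latency_s(params: LIFParams, i_pa: float) -> float:
    """Closed-form time from step onset to threshold for a LIF cell.

    Returns ``inf`` for subthreshold currents.
    """
    dv_inf = i_pa / params.g_l_ns  # mV, since pA / nS = mV
    dv_th = params.v_th_mv - params.e_l_mv
    if dv_inf <= dv_th:
        return math.inf
    return (params.tau_m_ms / 1000.0) * math.log(dv_inf / (dv_inf - dv_th))


def simulate_current_steps(
    neuron_params: LIFParams,
    step_amplitudes_pa: np.ndarray,
    step_duration_s: float = 2.5,
    seed: int = 0,
    sample_rate_hz: float = 10000.0,
    pre_s: float = 0.2,
    post_s: float = 0.2,
    noise_sd_mv: float = 0.0,
) -> tuple[list[StepSweep], StepGroundTruth]:
    """Simulate a family of current-clamp step sweeps from a LIF cell.

    Spikes are rendered as brief stereotyped waveforms to the spike peak
    so that threshold-crossing detectors see realistic deflections.  The
    step must last at least 2 s so late-spiking delays (>1.5 s) are
    expressible.
    """
    if step_duration_s < 2.0:
        raise ConfigurationError(
            "step_duration_s must be >= 2 s so that late-spiking delays are expressible"
        )
    rng = np.random.default_rng(seed)
    p = neuron_params
    dt = 1.0 / sample_rate_hz
    n_pre = int(round(pre_s * sample_rate_hz))
    n_step = int(round(step_duration_s * sample_rate_hz))
    n_post = int(round(post_s * sample_rate_hz))
    n_total = n_pre + n_step + n_post
    tau_s = p.tau_m_ms / 1000.0
    n_ref = max(int(round(p.refractory_ms / 1000.0 * sample_rate_hz)), 1)
    n_spike = max(int(round(0.001 * sample_rate_hz)), 2)  # 1 ms rendered spike

    sweeps = []
    latencies: dict[float, float] = {}
    for i_pa in np.asarray(step_amplitudes_pa, dtype=float):
        v = np.full(n_total, p.e_l_mv)
        i_trace = np.zeros(n_total)
        i_trace[n_pre : n_pre + n_step] = i_pa
        vm = p.e_l_mv
        k = 0
        while k < n_total - 1:
            dv = (-(vm - p.e_l_mv) + i_trace[k] / p.g_l_ns) / tau_s
            vm = vm + dv * dt
            if vm >= p.v_th_mv:
                # render stereotyped spike: ramp to peak then reset
                up = np.linspace(p.v_th_mv, p.spike_peak_mv, n_spike)
                end = min(k + 1 + n_spike, n_total)
                v[k + 1 : end] = up[: end - k - 1]
                k = end
                hold_end = min(k + n_ref, n_total)
                v[k:hold_end] = p.v_reset_mv
                k = hold_end
                vm = p.v_reset_mv
                continue
            v[k + 1] = vm
            k += 1
        if noise_sd_mv > 0:
            v = v + rng.normal(0.0, noise_sd_mv, size=n_total)
        sweeps.append(
            StepSweep(
                voltage=Trace(v, rate_hz=sample_rate_hz),
                injected_pa=float(i_pa),
                step_onset_s=pre_s,
                step_offset_s=pre_s + step_duration_s,
            )
        )
        latencies[float(i_pa)] = lif_first_spike_latency_s(p, float(i_pa))

    return sweeps, StepGroundTruth(p.rheobase_pa, latencies, p)


@dataclass(frozen=True)
class VonFreyTable:
    """Withdrawal counts out of ``n_trials`` per filament force."""

    filaments_g: np.ndarray
    withdrawals: np.ndarray
    n_trials: int = 5

    def __post_init__(self) -> None:
        filaments = np.asarray(self.filaments_g, dtype=float)
        withdrawals = np.asarray(self.withdrawals, dtype=int)
        if filaments.size != withdrawals.size:
            raise InputError("filaments and withdrawal counts must align")
        if np.any(np.diff(filaments) <= 0):
            raise InputError("filament forces must be strictly increasing")
        if np.any((withdrawals < 0) | (withdrawals > self.n_trials)):
            raise InputError(f"withdrawal counts must lie in [0, {self.n_trials}]")
        object.__setattr__(self, "filaments_g", filaments)
        object.__setattr__(self, "withdrawals", withdrawals)


# standard ascending von Frey series spanning 0.04-1.4 g
DEFAULT_FILAMENTS_G = (0.04, 0.07, 0.16, 0.4, 0.6, 1.0, 1.4)


def simulate_vonfrey_table(
    threshold_g: float,
    slope: float = 20.0,
    filaments_g: tuple[float, ...] = DEFAULT_FILAMENTS_G,
    n_trials: int = 5,
    seed: int = 0,
) -> VonFreyTable:
    """Simulate a withdrawal table from a logistic psychometric function.

    ``P(withdraw | f) = 1 / (1 + exp(-slope (f - threshold)))``; in the
    ``slope = inf`` limit the function is a right-continuous step
    (always withdraw at and above the threshold force).
    """
    filaments = np.asarray(filaments_g, dtype=float)
    if np.any(np.diff(filaments) <= 0):
        raise InputError("filament forces must be strictly increasing")
    rng = np.random.default_rng(seed)
    if np.isinf(slope):
        p = (filaments >= threshold_g).astype(float)
    else:
        p = 1.0 / (1.0 + np.exp(-slope * (filaments - threshold_g)))
    withdrawals = rng.binomial(n_trials, p)
    return VonFreyTable(filaments, withdrawals, n_trials)
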