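"""Core containers for uniformly sampled recordings.

A :class:`Trace` is the atom of every signal-processing step in this
package: an ordered sequence of real values (ΔF/F for imaging data,
pA for voltage-clamp current, mV for current-clamp voltage) together
with its sampling rate.  A :class:`TrialPair` couples a neuron's
baseline trial with its post-drug trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trace",
    "TrialPair",
    "ConfigurationError",
    "InputError",
    "DegenerateTraceError",
]


class ConfigurationError(ValueError):
    """Invalid simulation / analysis configuration."""


class InputError(ValueError):
    """Malformed or insufficient input data."""


class DegenerateTraceError(InputError):
    """Input degenerate for the requested operation (e.g. constant trace)."""


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled series with its sampling rate.

    Parameters
    ----------
    samples : array-like of float
        Signal values in acquisition order.
    rate_hz : float
        Sampling rate in frames (samples) per second; must be positive.
    """

    samples: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise InputError("trace samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise InputError("trace samples must be finite")
        if not (self.rate_hz > 0 and np.isfinite(self.rate_hz)):
            raise InputError(f"sampling rate must be positive, got {self.rate_hz}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "rate_hz", float(self.rate_hz))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Nominal duration: number of samples divided by the rate."""
        return self.samples.size / self.rate_hz

    @property
    def span_s(self) -> float:
        """Time spanned between the first and last sample."""
        return (self.samples.size - 1) / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.rate_hz

    def with_samples(self, samples: np.ndarray) -> "Trace":
        """Return a new trace with the same rate and different samples."""
        return Trace(samples=np.asarray(samples, dtype=float), rate_hz=self.rate_hz)


@dataclass(frozen=True)
class TrialPair:
    """Baseline and post-drug trials of a single neuron.

    Both traces must share the same sampling rate; the pair is the input
    unit of the drug-response classifier.
    """

    neuron_id: str
    baseline: Trace
    post: Trace

    def __post_init__(self) -> None:
        if self.baseline.rate_hz != self.post.rate_hz:
            raise InputError(
                f"neuron {self.neuron_id}: baseline and post traces must share "
                f"a sampling rate ({self.baseline.rate_hz} != {self.post.rate_hz})"
            )

    @property
    def rate_hz(self) -> float:
        return self.baseline.rate_hz
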