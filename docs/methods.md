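# Methods

This note documents the models, parameter choices, numerical details
and known limitations of `ceaphys`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Calcium-trace scoring and σdev classification

The scoring chain is applied per neuron in a fixed order: smoothing of
each whole-trial trace, min–max normalization of the concatenated
baseline+post signal, extraction and resampling of the scored window,
then AUC/s.

**Smoothing.** The Gaussian kernel is self-normalizing: at every output
index the weights K(t,i) = exp(−(t−i)²/2b²) are renormalized over the
indices actually present, which is also the edge rule (near a boundary
the kernel simply sums over fewer samples). The bandwidth is specified
in frames (default b = 10) and is applied in frame units regardless of
the 15 vs 20 Hz acquisition rate; the CLI logs the effective width in
seconds. Support is the full trace by default, computed as a ratio of
two convolutions (FFT path for long traces, roundoff ~1e−12); an
optional `truncate` radius (in multiples of b) exists for speed. The
truncation error tracks the Gaussian tail mass beyond the radius:
about 6e−5 of the local signal scale at ±4b, below 1e−7 at ±6b.

**Normalization.** One S_min/S_max pair per neuron, taken over the
concatenated pair, so baseline and post trials share a scale;
per-trial extrema need not reach 0/1. A constant concatenation is a
degenerate input and raises (the formula divides by zero). A
consequence used by the tests: the final labels are invariant under any
positive affine transform of the raw traces.

**Scored window.** The initial 360 s of each trial, resampled to 10 Hz
by linear interpolation on the original time base (extraction precedes
resampling). AUC/s is the trapezoidal integral divided by the spanned
time, so a constant trace of value c scores exactly c.

**Classification.** σdev is the population (ddof = 0) SD of all ΔAUC
values — the denominator convention is a deliberate choice, since the
source procedure says only "standard deviation of all neuron changes" —
and the cutoff comparisons are strict, so a degenerate cohort with all
ΔAUC = 0 is entirely "no effect". At least two neurons are required.

**Properties of the rule worth knowing.** The cutoff is *not* centred
on the mean change, and σdev is estimated from the same cohort it
thresholds. Two consequences, both exercised by the acceptance tests:
(1) on a pure-noise cohort the rule labels ≈31.7% of neurons as
affected (the two-sided 1 SD tail of an approximately Gaussian ΔAUC
distribution); (2) recovery of a truly inhibited fraction saturates
below the truth — with half the cohort strongly inhibited, recovery
plateaus near 42% of the cohort even as the effect size goes to its
limit, because within-neuron AUC measurement noise (dominated by
Poisson variation of the ~18 events expected in the scored window at
0.05 Hz) inflates σdev. The fraction-recovery test therefore uses a
large amplitude effect (50-fold, i.e. near-complete suppression) and a
±10-percentage-point band.

**Rate vs amplitude drug effects.** The generator can apply the drug
effect to the event rate (default), the transient amplitude, or both.
These are not symmetric under the pipeline: min–max normalization
absorbs amplitude scale *linearly*, so an amplitude effect produces
equal-magnitude ΔAUC for inhibited and excited neurons, whereas a rate
effect produces excitation changes roughly `effect_size`-fold larger
than inhibition changes (event pileup raises the normalizing maximum
only sublinearly). With a mixed cohort, the large positive tail of
rate-excited neurons inflates σdev and masks the inhibited class;
fraction-recovery studies of the classifier are therefore well-posed
under the amplitude effect, and that is the condition the acceptance
test uses.

## Event detection

A Clements–Bekkers scaled-template detector: at every offset the
template (peak-normalized double exponential) is fitted to the data
window by least squares in scale and offset; the detection criterion is
the fitted scale divided by the residual standard error, thresholded at
the classical 3.5. Detection windows span the rise plus 2 decay
constants (calcium) or 1.5 (EPSC) — long enough to pin the kinetics,
short enough that a neighbouring event rarely corrupts the fit.

Two refinements stabilize the detector:

- **Rise consistency.** The decaying tail of an event is self-similar
  to the template and can re-trigger the criterion at a slightly
  smaller scale. A candidate onset is only accepted if the (lightly
  smoothed) signal actually climbs by at least 40% of the fitted scale
  over the rise span; a tail falls over that span and is rejected.
- **Iterative peeling.** After a pass, each accepted event (fitted
  scale × full-length kernel) is subtracted and detection repeats on
  the residual, recovering events masked by an overlapping neighbour.
  Because the subtraction is sample-quantized it leaves a small
  residual (kernel slope × misalignment) whose criterion diverges as
  noise vanishes; a later-pass candidate inside the span of a
  subtracted event must exceed 20% of that event's amplitude. Two
  passes suffice at physiological rates.

Default templates: τ_rise 0.2 s / τ_decay 1.0 s for a slow indicator
(GCaMP6s-like), τ_rise 0.5 ms / τ_decay 5 ms for EPSCs; both are
arguments. Events are separated by at least one template time-to-peak.
Measured on generator traces at SNR ≥ 5 (see `tests/test_acceptance.py`),
recall and precision exceed 0.9 with event-frequency error under 10%;
the false-positive rate on pure noise at the default noise level is
below 0.01 events/s.

## Synaptic readouts

**Paired-pulse ratio.** A₁ is measured from the pre-pulse-1 baseline;
A₂ from the mean current in the 5 ms immediately preceding pulse 2 — no
subtraction of the pulse-1 decay, which at the 200 ms protocol interval
with ms-scale decays is negligible (the short-interval behaviour is
exercised in tests at 50 ms). Peak location is taken from a 1 ms
boxcar-smoothed trace and amplitude as the mean of a ±0.5 ms raw
window around it: a raw windowed minimum is an extreme-value statistic
whose bias inflates both amplitudes and biases the ratio upward, while
a windowed mean is noise-unbiased and the identical waveform
attenuation cancels in the ratio. PPR is conventionally computed on the
averaged sweep (`average_sweeps`), which suppresses the residual
peak-selection bias. An A₁ below 3 baseline SDs raises an
undefined-PPR error.

**Drug sensitivity (1×SD_BL rule).** SD_BL is the sample (ddof = 1) SD
of sweep-wise baseline evoked amplitudes — the averaging windows are
not pinned down by the source procedure, so sweep-wise amplitudes are
the default and documented reading; at least 3 baseline sweeps are
required. Inhibited ⇔ mean_bl − mean_post > 1×SD_BL, strictly; the
call is invariant under common rescaling and monotone in the post-drug
mean.

**Decay-time populations.** Single-event τ comes from a nonlinear
exponential fit to the post-peak segment down to 10% of peak,
initialized from the log-linear slope; a non-decaying segment returns a
failure flag rather than a number. The population split fits 1- and
2-component Gaussian mixtures to log τ (positivity and scale symmetry
argue for the log scale) via expectation-maximization with 10
random-from-data restarts and a 1e−6 variance floor, selecting k by
BIC; components are reported in ascending mean order. "At least two
populations" ⇔ BIC(2) < BIC(1). At least 20 values are required.

## Excitability profiling

Spikes are upward crossings of −20 mV with positive slope and a 2 ms
refractory guard (the detector is deliberately simple; step protocols
with rendered spikes do not need more). Rheobase is the smallest tested
current with ≥1 spike — so it is quantized at the step increment, and
the recovery test asserts agreement with the analytic
leaky-integrate-and-fire value I_rheo = g_L(V_th − E_L) to within one
increment. The first-spike delay is measured at the rheobase sweep
only; late-spiking ⇔ delay > 1.5 s strictly, so a delay of exactly
1.5 s is early-spiking. RMP is the mean pre-step voltage; input
resistance is ΔV_steady/ΔI from the smallest-magnitude hyperpolarizing
step (steady state = final 20% of the step), omitted with a warning
when no such step exists. Simulated steps default to 2.5 s so
late-spiking delays are expressible; shorter than 2 s is a
configuration error.

## Behaviour

The withdrawal threshold is applied literally: the lowest filament
force whose count reaches 3 of 5, even if a higher filament scored
lower. When no filament qualifies the result is an explicit above-range
value (`None`) rather than an imputed ceiling — imputation policies
vary between labs and silently imputing would bias group means. Zone
"transitions" are entries into the zone of interest, counted as label
changes from outside to inside; a track that never leaves the zone has
zero transitions.

## Exact statistics

The Mann–Whitney null distribution is computed by a subset-sum dynamic
programme over ranks, equivalent to enumerating all C(m+n, m)
labelings (and tested against that enumeration for all group sizes
≤ 7); the exact path requires no ties and m+n ≤ 30. U is reported as
min(U₁, U₂) and the two-sided p is min(1, 2·P(U ≤ u)) — this
convention reproduces legend-style printed values (e.g. U = 0 with
groups of 5 and 6 gives 2/462 → 0.004). Tied data fall back to
mid-ranks with a seeded 10,000-draw label-permutation Monte Carlo.

The Wilcoxon null enumerates all 2ⁿ sign patterns through a polynomial
convolution on a doubled-rank integer grid, which remains exact under
mid-ranks from tied |differences|; zeros are dropped before ranking.
Beyond n = 20 a normal approximation with tie correction and
continuity correction is used and flagged as non-exact.

The KS statistic is the exact sup-difference of the two ECDFs over the
pooled sample; the default p is the classical Kolmogorov limit at
√(mn/(m+n))·D (scipy's "asymp" mode adds a small-sample refinement and
can differ by a few hundredths at n ≈ 25), with an exact option for
m·n ≤ 10⁴. The 2×2 chi-square is Pearson's statistic without
continuity correction on 1 df; empirically (10,000-rep null
simulation in the test suite) it is mildly anticonservative at n = 8
per group (~0.08 at nominal 0.05) — a known small-sample property of
the uncorrected test, bounded rather than hidden by the tests — while
the exact MW and Wilcoxon tests sit in [0.035, 0.065] and the
asymptotic KS is conservative.

## Synthetic data: what it emulates, and what it does not

The generator covers every input the pipeline consumes: ΔF/F trial
pairs (Poisson transient trains convolved with a peak-normalized
double-exponential kernel plus white Gaussian noise; multiplicative
drug effect per neuron label), EPSC traces (Poisson inward events, τ
from a specified mixture), paired-pulse sweeps with an exact true
ratio, leaky-integrate-and-fire step families with analytic rheobase
and latency, and Bernoulli psychometric von Frey tables (logistic in
force, centred on the true threshold; the infinite-slope limit is a
right-continuous step so the threshold filament always withdraws). All
draws flow from one `numpy` generator seeded per call; identical
seed+config is bit-identical.

Defaults were chosen once to mirror the recording conditions the
pipeline targets: 15 Hz frames, 9-minute trials (so the 6-minute scored
window fits with margin), 0.05 Hz spontaneous transients of ~0.3 ΔF/F
with 0.05 noise SD (SNR 6), GCaMP6s-like kinetics, 10 kHz
electrophysiology sampling, and a 0.04–1.4 g filament series.

Deliberately absent, so passing tests must not be over-read: no
photobleaching or motion artefacts (an optional linear drift flag
exists), no correlated or non-Gaussian noise, no cell-to-cell kinetic
variability within a cohort, no conductance-based spiking (the
integrate-and-fire cell renders stereotyped spikes), and no raw
miniscope video — the pipeline starts at extracted ΔF/F, and source
extraction, motion correction and cross-session registration are out
of scope. Real recordings violate several of these idealizations;
detector and classifier performance numbers from the synthetic suite
are upper bounds, not field calibrations.

## Problem sizes

The test and acceptance workloads are sized for a laptop-class single
core: cohorts of 200 neurons × two 9-minute trials for classifier
recovery, 20-neuron cohorts for detector fidelity, 100 s EPSC traces,
20 simulated neurons for rheobase recovery (2 kHz integration), and
10,000-replicate null calibrations; the full suite runs in well under a
minute.
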