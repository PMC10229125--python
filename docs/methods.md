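# Methods

This note documents the models, conventions and numerical choices behind
`alquant`, and what the synthetic-data suite does and does not establish
about real recordings.

## Conventions

Time is seconds internally; kinetic quantities (rise, decay, latency) are
reported in milliseconds at interfaces.  Sample `i` of a trial sits at
`t0 + i/fs` (0-based); all bins and analysis windows are half-open
`[start, end)`.  Windows are anchored to the *nominal* stimulus command
time, not to physical odor arrival at the preparation — latencies of odor
transport are therefore part of the measured response, which is the
convention the windowed metrics assume.  EPSCs are inward (negative) in raw
current sweeps; every reported amplitude is a positive magnitude.
Post-stimulus hyperpolarization is signed positive when the membrane is
hyperpolarized.

## Spike detection

Spikes are detected on the first and second temporal derivatives of Vm
(central differences at the native sampling rate; no resampling).  A
candidate requires dV/dt to exceed `d1_thresh_k` robust standard deviations
*and* d²V/dt² to dip below `−d2_thresh_k` robust SDs within ±1 ms — the
conjunction keeps slow depolarizations and noise shoulders out.  The robust
scale is 1.4826×MAD of the derivative over the whole trial, which makes the
detector invariant to Vm offsets and its thresholds dimensionless; on
noiseless synthetic traces the MAD is exactly zero (the trace is flat
almost everywhere), and the detector falls back to the plain SD, which is
then spike-dominated but still a usable scale.  Spike time is the Vm
maximum within 2 ms after the slope crossing; the 2 ms absolute refractory
keeps the larger-slope event.  Defaults `d1_thresh_k = 5`,
`d2_thresh_k = 3` were chosen for, and validated by, the synthetic recovery
suite (recall and precision ≥ 0.98 at the default SNR, exactness on
noiseless traces); real recordings replace manual spike inspection with QC
flags (clipped-trace detection) rather than silent failure.  Small-spike
cells whose spikes cannot be counted reliably should carry a
`spikes_unreliable` flag in trial metadata and be analyzed by membrane
potential only.

Two-unit extracellular traces are split by 1-D k-means (k = 2) on peak
amplitude, deterministically initialized at the amplitude extremes; the
larger class is unit A.  A silhouette below 0.5 flags the units as not
separable.  Event extraction uses a 1 ms minimum peak separation — half the
single-unit refractory — because events of *different* units may fall
closer than either unit's refractory; near-coincident spikes (closer than
1 ms) are not resolved, which bounds attainable recall at roughly
`1 − 2 ms × rate` of the companion unit.

## Windowed metrics

Evoked rate and depolarization are onset-window statistics minus the
immediately preceding baseline window (both 500 ms by default; the onset
window is a per-glomerulus configuration, 1000 ms for protracted
responders).  Vm means are computed on spike-stripped traces: ±2 ms around
each detected spike replaced by linear interpolation.  Stripping more than
half a window raises a QC flag instead of an error — at high evoked rates
(inter-spike intervals near 4 ms) most of the onset window is interpolated
and the depolarization estimate leans on the interpolation anchors; this is
inherent to subtracting spikes from a 200+ Hz response and is surfaced, not
hidden.  The membrane-potential CV divides by |mean Vm| (Vm is negative);
means within 1 mV of zero make the CV undefined and are flagged.  The
baseline for the post-stimulus hyperpolarization is the pre-stimulus
500 ms window mean.

Control normalization divides each cell's per-stimulus value by the mean of
the solvent-exposed group for that stimulus, so the solvent normalized mean
is exactly 1; a pooled per-cell mean across stimuli is appended.  Stimuli
whose solvent mean is below ε (default 0.5 in metric units) are excluded
from normalization — ratios against near-zero denominators are
uninterpretable — and the exclusion is recorded.

## Permutation statistics

The test statistic is mean(a) − mean(b).  Monte-Carlo mode reshuffles the
pooled labels (preserving group sizes) independently in each of the 10,000
iterations; iterations are not deduplicated, which is the standard reading
of repeated shuffling "without replacement" (each shuffle is itself a
draw without replacement of labels).  The two-tailed p is the fraction of
shuffles with |Δ_perm| ≥ |Δ_obs|; ties count as extreme and no +1
correction is added, so p = 0 is attainable in Monte-Carlo mode.  The exact
mode enumerates all C(n, n_a) assignments (bounded at 200,000) and is the
oracle for the Monte-Carlo mode in the test suite; its type-I error at
α = 0.05 on Gaussian nulls (n = 8, 8) is calibrated to [0.03, 0.07].
Bonferroni m — the number of comparisons per panel — is supplied by
configuration, defaulting in the CLI to the number of stimuli tested; it is
a judgment the analysis cannot infer from the data.  The rank-sum test is
exact by enumeration over midranks when min(n) ≤ 8 (ties permitted; with
identical groups the two-tailed p is 1), and a tie-corrected,
continuity-corrected normal approximation otherwise (within 0.01 of
enumeration at n = 9, 9).

## ΔF/F imaging

The background estimate is a scalar dark offset subtracted before any
ratio; F₀ is the per-pixel mean of the 70 frames preceding the stimulus,
and ΔF/F = (F′ − F₀)/F₀ is gain-invariant by construction.  Pixels with
F₀ ≤ ε are masked and propagate as NaN, never as zeros.  The 4×4 Gaussian
lowpass has no central pixel; the kernel grid is offset half a pixel,
sampling the Gaussian at {−1.5, −0.5, +0.5, +1.5} with σ = 1 px (the kernel
size is a protocol constant, σ a configuration choice validated only by
the recovery suite).  Peak extraction searches the frames whose acquisition
interval intersects the stimulus window — ceil(stim_len × frame rate)
frames, i.e. 6 frames for 500 ms at 11 Hz.

## 3-D anatomy

Saturation QC rejects a brain when more than 10⁻⁴ of neuropil voxels sit at
0 or at the bit-depth maximum in either channel; the digital thresholds
{0, 2^bits − 1} stand in for unstated detector limits.  ROIs traced on
every k-th slice are interpolated by linearly blending the signed distance
fields of the flanking traced slices and thresholding at zero — chosen
over nearest-slice copying because glomeruli are smooth volumes; traced
slices are preserved exactly, and tracing every slice reproduces the input
(idempotence).  Volumes are voxel counts times the anisotropic voxel volume
(1 µm slices, sub-µm pixels), reported in µm³; channel sums are raw
digital numbers (no background subtraction — the ratio of sums is then
background-sensitive, which users should keep in mind when backgrounds
differ between channels).  Cross-brain pooling normalizes each
glomerulus/metric to the mean of the solvent-exposed control brains.

## Unitary EPSCs

The unitary EPSC template is a difference of exponentials parameterized
directly by the 10–90% rise time and the peak-to-half decay time; the two
time constants are solved numerically (log-parameterized root find), so
generator inputs and estimator outputs live on the same scale.  Detection:
baseline mean and SD from the 20 ms before the light pulse; onset is the
first sample whose inward deviation exceeds 3·SD and stays beyond threshold
for ≥ 1 ms within a 100 ms search window; the amplitude is the extremum
magnitude on a 0.5 ms boxcar-smoothed trace (raw maxima ride single noise
samples).  Staircase segmentation computes per-intensity success rates and
median success amplitudes; the recruitment threshold is the lowest
intensity with success rate ≥ 0.5, and the doubling intensity the first
whose median reaches 1.5× the running plateau median — 0.5 and 1.5 are
configuration constants separating the qualitative "mostly failures" and
"suddenly doubles" regimes.

The mean unitary EPSC averages ~8–12 unitary-sized successes (amplitude
≤ 1.5× the plateau median, excluding chance multi-axon sweeps) collected at
the sampled intensity closest to the midpoint of the unitary range,
widening to the next-closest in-range intensity only when the chosen one
cannot supply eight sweeps.  Traces are aligned at their measured peaks and
averaged; because single-sweep peak estimates jitter with noise (which
would smear the mean-trace rising phase), one cross-correlation refinement
pass (± 2 ms integer shifts against the provisional mean) follows the
initial peak alignment.  Amplitude, 10–90% rise and half-decay are read off
the mean trace with linear interpolation of the level crossings; latency
statistics are taken over individual sweeps (onset minus light onset; the
threshold-crossing onset carries a small positive bias, ≈0.2 ms at the
default SNR, well inside the ±1 ms recovery band).  The protocol's discard
criteria are raised as QC flags: failure rate > 10% at the chosen
intensity, median amplitude spread > 30% across in-range intensities near
the chosen one, and any sweep correlating < 0.8 with the mean waveform.

## Synthetic data: what it emulates, and what it does not

Spike trains are inhomogeneous Poisson processes with a 2 ms dead time,
generated by thinning with a dead-time-corrected hazard
λ(t) = r(t)/(1 − r(t)·τ) so that the *realized* rate matches the requested
profile (exact for stationary rates, quasi-static for rates varying slowly
against τ; requested rates must stay below 500 Hz).  The default PN trial
is 9 s (5 s pre-stimulus for CV/spontaneous windows, 1 s stimulus, 3 s
post for the 2.5 s AHP window) at 10 kHz, resting at −60 mV with 5 Hz
spontaneous rate (the 3–7 Hz range of these cells), an adapting evoked
rate (τ = 0.6 s) whose peak is solved so the expected stimulus-window count
equals 150 — the chronic-exposure calibration — an 8 mV depolarization,
2 mV afterhyperpolarization, and 0.4 mV noise low-passed at 1 kHz
(recording noise is band-limited; white noise at 10 kHz would be an
unrealistically hostile regime for a derivative detector).  Spikes are a
biphasic template, 12 mV peak and 2 ms width: PN somatic spikes are small,
which keeps detection non-trivial.  The generators are phenomenological —
no conductances, no synaptic dynamics, no correlated (non-Poisson) firing,
no electrode drift or movement artifacts — so the recovery suite
establishes correctness of the *estimators* under the stated noise model,
not detector performance on every real recording.

The minimal-stimulation generator recruits each axon with probability
sigmoid((I − θ_k)/slope) per sweep (θ = 0.17, 0.21 mW/mm², slope
0.004), adds one 40 pA template per recruited axon at a latency drawn
N(23, 2.2²) ms, and overlays 2 pA white noise; the default ramp covers
0.10–0.26 mW/mm² in 0.01 steps with 10 sweeps each.  The imaging generator
uses a saturating-rise (τ = 50 ms), exponential-decay (τ = 400 ms)
indicator kernel in a circular ROI with Poisson shot noise on a 100-count
baseline.  The exposure budget follows the 1 s / 20 s / 48 h protocol
(a 21 s cycle appears in part of the protocol description and is accepted
as an alternative value of the same parameter).  The gas-phase estimate is
the ideal Raoult/mole-fraction formula and makes no claim to reproduce
measured headspace concentrations, which depend on activity coefficients.

## Problem sizes

The recovery studies use 200 synthetic trials for the spike-count
calibration, 50 minimal-stimulation sessions (≈170 sweeps each) for the
unitary-EPSC estimates, 1,000 simulated null experiments for the type-I
calibration, and 10–100 seeds for the remaining recovery checks — sizes at
which the Monte-Carlo standard errors are several times smaller than the
tolerance bands being checked.
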