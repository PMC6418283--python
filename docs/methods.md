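# Methods

## Scope and data flow

The package analyzes gaze-restricted SSVEP sessions: a central fixation
point, one flickering disc shown at a time at one of 46 positions, EEG
recorded at 500 Hz from 31 extended 10–20 electrodes, gaze sampled at
60 Hz. A trial is valid only if every gaze sample stays within a 1.5°
ring around fixation (boundary inclusive; "beyond the ring" is read as
strictly outside). The pipeline is simulate (or read) → gate → filter →
epoch → CCA score → retinotopic and topographic statistics. All geometry
is in degrees of visual angle, origin at fixation, y up, x rightward;
stimulus and layer indices are 1-based with index/layer 1 the central
flicker.

## Stimulus geometry

The default layout places one disc at fixation and rings of 3, 6, 9, 12
and 15 discs at eccentricities 2–10° (2° layer spacing, 3° disc diameter),
46 discs total; the outermost disc edge reaches 10 + 1.5 = 11.5°. The
per-ring counts are a package choice: they give a uniform ≈4.19° arc
spacing on every ring, satisfying the within-ring non-overlap constraint
(discs on *different* rings may overlap spatially because they are never
shown simultaneously). Each ring is rotated by one eighth of its arc step;
with that offset an angle (360/c)(k + 1/8) can never be a multiple of 90°
(8k + 1 is odd), so no stimulus sits exactly on either axis and
hemifield/vertical-field labels are total for any ring count.

## Generative model

Each valid 4-s epoch is

    x_c(t) = w_c · A(x, y) · Σ_m (1/m) · sin(2π m f₀ t + φ_m)
             + σ_n · η_c(t) + a_line · sin(2π · 50 · t + φ)

with f₀ = 15 Hz, M = 3 simulated harmonics with 1/m amplitude decay and
zero phases (the flicker is driven at phase 0°), η_c unit-RMS 1/f^α noise
(α = 1), independent across channels, generated by spectral shaping of
white noise, and a common-phase 50 Hz line component (a_line = 0.5).

The evoked amplitude follows the retinotopic structure the analysis is
meant to detect:

    A(x, y) = A₀ · exp(−e² / 2σ_r²) · (1 + β·[y < 0]),   e = √(x² + y²)

and the per-channel forward weights w_c peak over the occipital pole
(Gaussian of width 0.55 head-radii around the schematic Oz position) with
channels contralateral to a lateralized stimulus scaled by (1 + γ), then
normalized to maximum 1.

Defaults (frozen after a single calibration pass checking only that the
qualitative structure — saturating central response, graded falloff,
detectable lateralization — appears at realistic strength):

| parameter | default | meaning |
|---|---|---|
| A₀ | 1.0 | evoked amplitude at fixation (signal units) |
| σ_r | 3.5° | Gaussian eccentricity-falloff width |
| β | 0.3 | lower-visual-field amplitude boost |
| γ | 0.5 | contralateral channel gain |
| snr | 2.0 | A₀ / per-channel background-noise RMS |
| α | 1.0 | background-noise spectral exponent |
| a_line | 0.5 | 50 Hz line amplitude |
| gaze σ | 0.3° | fixation jitter per axis |
| p_excursion | 0.1 | per-trial gaze-excursion probability |

Gaze traces are i.i.d. Gaussian jitter; with probability `p_excursion` one
contiguous out-and-back ramp crossing the fixation ring is injected, which
deterministically invalidates the trial. Sessions repeat each failed
(run, stimulus) pair until it succeeds, retaining failures with
`valid=False`; a cap of 20 attempts guarantees termination (the physical
paradigm has no cap). Only the 4-s flicker epoch carries signal; prompt and
rest stages exist as protocol bookkeeping, not simulated data.

What the simulator deliberately does **not** emulate: saccade dynamics and
oculomotor artifacts (EOG/EMG), electrode drift, spatially correlated
background noise (available as nothing more than a future config switch;
independent noise is the default), inter-participant variability beyond the
seed, and any absolute amplitude calibration — the source study reports no
SNR or microvolt figures, so simulator units are arbitrary. Passing tests
therefore demonstrate that the analysis recovers the structure the
generative model encodes, not that real recordings will show effects of the
same magnitude.

## Preprocessing

A 50 Hz notch (quality factor 30 — the acquisition protocol names only the
frequency, so the bandwidth is a package default) followed by a 4–35 Hz
Butterworth bandpass (order 4 per pass), both applied forward–backward so
the filtering is zero-phase and sinusoid peaks are not displaced. Epochs
are half-open 0-based windows [onset, onset + 4·fs). Note that the 45 Hz
third harmonic lies above the passband: after filtering, the reference rows
at 45 Hz simply contribute no correlation, exactly as in the reference
protocol's parameterization.

## CCA scoring

The response is the largest canonical correlation between the centered
epoch and the centered reference bank, computed by SVD of the whitened
cross-covariance `Cxx^{-1/2} Cxy Cyy^{-1/2}`. Whitening truncates
eigenvalue directions below 1e-10 relative to the largest eigenvalue
(pseudo-inverse style): full-rank inputs are solved exactly (noise-free
in-band signals give R = 1 to machine precision) while duplicated or
constant channels remain well-defined. An all-zero epoch scores R = 0 with
a warning. Weight-vector sign is fixed by making the first nonzero
component of w_x positive (R itself is sign-invariant; weights are
diagnostic only). The per-stimulus response is the per-trial CCA
coefficient averaged over the (up to 12) valid runs; averaging trials
before CCA is a configuration the source protocol leaves open and is not
the default.

## Error rate

The published error-rate values lie on a lattice of multiples of 1/12
(once 1/11), matching the 12 runs — which identifies the run as the unit
of comparison. The default definition follows: a run counts as an error at
angle d iff the maximum response over the layer-d stimuli of that run
exceeds the central response of the same run; the denominator is the
number of usable runs (those with a valid central trial and at least one
valid layer-d trial), so missing runs naturally produce 11-run
denominators. A pooled variant (every (stimulus, run) comparison counted
individually) is available via `variant="pooled"`. The error rate depends
only on the within-run ordering of responses, so it is invariant under any
monotone transform of the responses. Angle columns map to single layers
(2°→layer 2 … 10°→layer 6). Rates are rounded to 2 decimals in tables;
internal values keep full precision. Group comparisons use Welch's
two-sample t-test (the protocol does not specify pooled vs unequal
variance); degenerate zero-variance groups fall back to p = 1 for equal
means and p = 0 otherwise, with a warning.

## Topography

Channel contributions are leave-one-out: `r_i = (R_all − R_wo_i)/R_all`
over all 31 channels. (The summation form in which this statistic is
sometimes written is degenerate as printed; the implementation follows the
operational description — CCA with and without the channel.) Covariances
are computed once per epoch and rows/columns dropped per channel, so the 31
leave-one-out solves cost only small eigendecompositions. Contributions are
non-negative up to numerical error (nesting property of CCA), at most 1,
and equal 1 only if removing the channel drives R to zero.

Contralateral scores normalize each hemisphere's single-channel response by
its own central-stimulus response before differencing, which cancels static
between-hemisphere gain differences; "stimuli within angle d" is read
cumulatively (eccentricity ≤ d, center excluded). Swapping the pair members
negates the score exactly; mirror-symmetric responses give 0. The
Kruskal–Wallis test compares the two channels' normalized per-stimulus
responses; fully tied samples return H = 0, p = 1. In the multi-participant
pipeline, per-participant normalized response tables are averaged across
participants before scoring.

## Retinotopic surface

The per-participant surface is piecewise-linear interpolation over the
Delaunay triangulation of the stimulus positions, evaluated on a regular
grid spanning the field; points outside the convex hull are missing.
Collinear position sets raise an error.

## Parameter recovery

σ_r is recovered by fitting `sqrt((A·exp(−e²/2σ²))² + c²)` to
layer-averaged *fundamental projection amplitudes* (the 15 Hz Fourier
amplitude, RMS over the 11 analysis channels) rather than to CCA
coefficients: R saturates near 1 and sits on a noise floor, both of which
bias a direct Gaussian fit, whereas the projection amplitude is linear in
the evoked amplitude; the quadrature constant c absorbs the incoherent
noise floor. The lower-field boost β is recovered in sign as the mean
response below minus above the horizontal midline.

## Problem sizes and determinism

Stochastic claims (the eccentricity falloff, the lower-field advantage,
the contralateral sign pattern) are evaluated over 20 replicate sessions —
one 12-run, 46-stimulus simulated participant per seed, seeds 0–19 — and
required to hold in at least 95% of replicates; parameter recovery uses the
first three replicates. All randomness flows through
`numpy.random.default_rng` seeded from the configuration; a fixed seed
reproduces every table byte-for-byte, and the run manifest (seed, config
hash, package version, trial counts) suffices to regenerate any output.

## Known limitations

* Per-participant p-values and absolute contralateral score magnitudes
  depend on physiological variability the simulator does not model; only
  their signs and orders are meaningful on synthetic data.
* The Kruskal–Wallis grouping for pair significance is one of several
  defensible readings (per-stimulus normalized responses); alternative
  groupings would change flags, not scores.
* EDF input is read via `mne` when available; sessions are written as
  delimited text only (no EDF writer dependency).
* The 46-position layout's per-ring counts are conventional defaults;
  any counts satisfying the within-ring spacing constraint may be
  configured.
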