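# Methods

`erkpulse` quantifies pulsatile ERK activity from ratiometric FRET
time-lapse recordings of single cells. This note describes the model, the
processing chain, the synthetic data the package tests itself against, and
the numerical choices made where the procedure left room for design.

## The trace model

Each cell's FRET/CFP ratio time course `y(t)` is described either as a
flat line (basal activity only) or as a max-composition of cosine pulses
on a basal level:

```
y(t) = ω0                                        (N = 0)
y(t) = max{ y_1(t), …, y_N(t) } + ω0             (N ≥ 1)

y_i(t) = A_i · φ_i(t − t_i)
φ_i(s) = cos(ω_i s) + 1      for −π/ω_i ≤ s ≤ π/ω_i,   0 otherwise
```

- `ω0` — basal ERK activity (ratio units), the sustained component.
- `A_i` — pulse amplitude (ratio units); the peak rises `2 A_i` above
  basal because `φ(0) = 2`.
- `t_i` — pulse center time (min).
- `ω_i` — angular frequency (rad/min); the pulse lasts one cosine period,
  `2π/ω_i` minutes.

Overlapping pulses combine through the pointwise **maximum**, not the sum.
All parameters are estimated per cell by least squares. A cell is
**ERK-pulse⁺** if at least one fitted amplitude exceeds a threshold,
otherwise **ERK-pulse⁻**.

## Image processing

Two-channel stacks (CFP donor, FRET acceptor) are converted to ratio
stacks as `(FRET − bg_F) / (CFP − bg_C)` with user-supplied constant
backgrounds. Pixels whose background-subtracted CFP does not exceed a
floor are flagged invalid (NaN) and excluded everywhere downstream, never
silently zeroed. Z-stacks are reduced by maximum intensity projection
**per channel before division**; projecting first avoids dividing dim
out-of-focus voxels. A 5×5 median filter can be applied to ratio frames;
its window excludes invalid pixels and shrinks at image borders rather
than inventing padded values. Whether the filter precedes or follows
trace extraction is exposed as an option (`--median-size` on the CLI);
it mainly matters for very noisy recordings.

Intensity-modulated display (IMD) renders a ratio frame with hue encoding
the ratio in 8 discrete bins from blue (240° in HSV, low) to red (0°,
high) — evenly spaced, since only the endpoints and the count are fixed
by convention — and brightness encoding donor intensity in 32 grades.
Invalid pixels render black; out-of-range ratios clip to the end bins.

Per-cell traces are the mean ratio over each ROI label's valid pixels per
frame (static labels, no tracking; segmentation is out of scope).

## Trace preprocessing

- **Smoothing**: centered moving average with a 6-min total span (five
  samples at the standard 1.5-min sampling). Centered rather than
  trailing, so pulse timing is not phase-lagged. The window shrinks at
  the recording ends; missing frames are excluded, not interpolated.
- **Baseline normalization**: division by the mean over a pre-treatment
  window, for drug-response displays.
- **Autocorrelation**: biased mean-subtracted sample autocorrelation
  (r(0)=1); used to check for periodicity of pulse timing.

The pipeline default is smooth-then-fit. Smoothing attenuates a 20-min
pulse's peak by roughly 10% (the 5-point discrete window transmits
cos-shaped pulses with factor ≈0.9), so amplitude-accuracy studies on
low-noise data are run on raw traces, while classification of noisy data
uses the smoothed pipeline.

## Fitting and model selection

The number of pulses N is not part of the model statement, so the package
selects it by greedy forward addition:

1. Fit the flat model (`ω0` = trace mean).
2. Seed a new pulse at the largest positive local maximum of the current
   residual, with amplitude half the residual height and a multi-start
   over initial durations {10, 20, 40} min.
3. Jointly re-optimize all parameters (`ω0`, every `A_i, t_i, ω_i`) with
   bounded trust-region least squares (`scipy.optimize.least_squares`).
   Bounds: `A_i ≥ 0`; durations in [6, 60] min by default (sampling floor
   of ≥4 frames; recording-length ceiling); centers may sit up to half
   the longest admissible duration outside the recording so truncated
   edge pulses are representable.
4. Repeat up to `max_pulses` (default 5), keeping the whole path of
   models N = 0, 1, 2, …
5. Select the path model with minimal BIC; ties prefer the smaller model.

Two choices deserve emphasis:

- **BIC at the effective sample size.** A trace smoothed over m samples
  carries about n/m independent observations; judging fits on the nominal
  n systematically over-accepts components that chase smoothing-induced
  noise bumps (and, because amplitudes are nonnegative, biases the basal
  estimate low on pulse-poor cells). Traces therefore carry their
  smoothing factor and the selection criterion uses
  `n_eff = max(n/m, 8)`: `BIC = n_eff·ln(SSE/n) + k·ln(n_eff)` with
  `k = 1 + 3N`. A degenerate-SSE floor keeps the criterion finite on
  noiseless traces without disturbing the parameter-count ordering.
- **Whole-path selection.** When several pulses share the variance of a
  trace, the first added pulse may improve the fit by less than its own
  penalty even though the full multi-pulse model wins decisively; greedy
  stopping at the first non-improving step would return the flat model.
  Selecting the BIC minimum over the whole path fixes this at the cost of
  always building `max_pulses` candidates.

Nestedness (an extra pulse can never worsen the SSE) is enforced: a
refinement step that fails to lower the SSE terminates path growth.

## Classification threshold

The ERK-pulse⁺ rule compares the largest fitted amplitude against a
threshold. No absolute value is inherent to the method, so the default is
expressed in units of the trace's own noise: `k ×` a robust noise sd
estimated from the median absolute successive difference of the selected
model's **residuals** (successive differences of the trace itself ride on
pulse flanks at realistic pulse densities and would overstate the noise
several-fold). The default `k = 7` was calibrated by Monte Carlo at the
standard pipeline settings: amplitudes fitted to pure smoothed noise stay
below ≈6.4 of these units while genuine pulses whose peak reaches six raw
noise sd fit above ≈8.2, giving a false-positive rate ≲1% and essentially
full sensitivity at that boundary. The threshold can be overridden as an
absolute ratio value (`threshold_abs`), which is recommended whenever the
pipeline deviates from the standard smoothing.

Population metrics (pulse frequency, durations, amplitudes) count only
**detected** pulses: supra-threshold components whose center lies within
the recording (±3 min for edge-truncated pulses). Sub-threshold
components absorb correlated noise, and components centered far outside
the recording have amplitudes unconstrained by data; counting either
would inflate frequencies. The total component count is still reported as
`n_components`. Both amplitude conventions are reported — the model
amplitude `A` and the peak height `2A` — since figures in the literature
are ambiguous about which is shown.

## Synthetic data

The generator emulates the study's imaging conditions and provides the
ground truth every downstream test compares against:

- **Recordings**: 90 min at 1.5-min sampling, basal ratio 1.0.
- **Pulse timing**: homogeneous Poisson (default 2 pulses/h) with an
  optional hard refractory separation (default 0); sporadic timing with
  no periodicity matches the observed flat autocorrelation.
- **Pulse shape**: amplitudes Gaussian (mean 0.1, sd 0.02 ratio units,
  truncated at 0); durations Gaussian (mean 20, sd 4 min, floored at
  6 min so ω stays finite and pulses stay resolvable).
- **Noise**: additive Gaussian on the ratio, default sd 0.01. The real
  recordings' noise magnitude is unknown; this is a fixture parameter
  chosen to make single pulses clearly super-threshold (peak = 20 σ), not
  an estimate of in vivo noise. Photon-limited noise, bleaching and focus
  drift are deliberately not modelled.
- **Condition effects**: multiplicative perturbations of pulse rate
  (EGFR-inhibition-like) and basal level (ErbB2-inhibition-like),
  emulating the drug regimes used for group comparisons (rate ×0.2 and
  basal ×0.8 in the bundled regime experiment).
- **Waves**: on a rectangular cell grid (default 20 µm spacing), source
  cells fire and recruit 4-neighbours once each with a fixed onset lag
  per hop (default 2 min → construction velocity 10 µm/min). Single
  outward waves, no re-triggering.
- **Movies**: cells are rendered as constant-CFP disks with
  FRET = CFP × ratio per pixel, plus uniform background and optional
  noise, so ratio extraction inverts rendering exactly in the clean case.
  Overlapping nuclei are rejected to keep ROI truth unambiguous.

Because the generator produces exactly the model the fitter assumes,
passing tests demonstrate correctness of the implementation and
calibration of its defaults under the stated conditions — not robustness
to model mismatch (asymmetric pulses, drifting baselines, segmentation
errors) in real microscopy data.

A note on detection efficiency: at 2 pulses/h with 20-min pulses and no
refractory period, roughly a third of generated pulses overlap a
neighbour within one pulse duration; such pairs are genuinely
indistinguishable from single broad pulses under max-composition, so
population-level detected frequencies under-count the control condition
by ~30% while sparse conditions are counted nearly fully. Group
comparisons remain valid (the bias is monotone), but detected-rate ratios
between dense and sparse conditions are compressed toward 1 relative to
the generating-rate ratios.

## Propagation analysis

Pulse onsets are defined as the start of the fitted cosine support
(center − π/ω; a half-maximum convention is also available). Cells are
neighbours if their centroids lie within a radius (default 1.5× the
median nearest-neighbour spacing). Events (cell, onset) form a directed
acyclic graph with an edge whenever a neighbour's onset follows by
0 < Δ ≤ `max_lag`; waves are extracted by repeatedly removing the longest
path, keeping chains of at least `min_cells` (default 3) cells. The wave
velocity is the summed centroid path length divided by the onset span.
The detector is validated only against synthetic ground truth (velocity
within 10% on jittered chains; shuffled-onset controls nearly empty) —
the original propagation observations were qualitative.

## Group statistics

- **Mann–Whitney U** (two-sided) for two groups: exact enumeration for
  small untied samples, tie-corrected normal approximation otherwise
  (scipy's policy).
- **Steel–Dwass** for ≥3 groups: pairwise joint midranks, tie-corrected
  rank-sum variance, statistic `|t|·√2` referred to the Studentized range
  distribution with k groups and infinite degrees of freedom. Bartlett's
  homoscedasticity check is reported alongside, not enforced. Null
  family-wise error measures ≈4–6% at nominal 5% (n=20/group).
- **χ² + BH**: Pearson chi-square per contingency table,
  Benjamini–Hochberg step-up adjustment across tables.

## Problem sizes and determinism

All stochastic components take explicit integer seeds and are bit-exact
reproducible. The bundled verification runs use 100 traces for parameter
recovery and count selection, 200+100 for classification calibration,
50 cells per condition for the regime experiment, 50 chains for wave
recovery, and 1000 simulations for the Steel–Dwass null — sizes at which
the Monte-Carlo error is comfortably below each decision margin.

## Known limitations

- Pulses closer than about one duration merge; N is a lower bound under
  heavy overlap.
- The greedy optimizer is local; pathological traces could in principle
  find poorer optima than exhaustive search, though the bundled
  grid-search comparisons never observe it.
- The classification default is calibrated for the standard smoothing;
  other windows change the residual scale and deserve a re-calibration or
  an absolute threshold.
- Static ROIs only; no tracking, registration, bleaching correction or
  segmentation.
- Wave detection assumes one onset per cell per wave and fixed cell
  positions.
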