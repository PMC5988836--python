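# erkpulse

Quantification of pulsatile ERK activity in single cells from ratiometric
FRET time-lapse imaging.

Epithelial cells — intestinal epithelium and organoids are the motivating
system — show two modes of ERK activity when observed with a FRET
biosensor (e.g. EKAREV): a sustained **basal** level and sporadic,
minutes-scale **pulses** that can propagate between neighbouring cells.
The two modes are controlled by different receptors, so separating them
quantitatively is the analysis problem this package solves: given
two-channel (CFP / FRET) movies or pre-extracted per-cell ratio traces,
it measures each cell's basal activity, detects and parameterizes its
pulses, classifies cells as ERK-pulse⁺/⁻, detects propagating pulse
waves, and runs the group statistics used to compare conditions.

## The model

A cell's FRET/CFP ratio trace is fitted to a flat line or a multi-peak
function

```
y(t) = ω₀                                  (N = 0)
y(t) = max{y₁(t), …, y_N(t)} + ω₀          (N ≥ 1),    yᵢ(t) = Aᵢ φᵢ(t − tᵢ)
```

where `φᵢ(s) = cos(ωᵢ s) + 1` on a single period `|s| ≤ π/ωᵢ` and zero
outside — each pulse is a cosine bump of amplitude `Aᵢ` (peak `2Aᵢ` above
basal), center `tᵢ` and duration `2π/ωᵢ`. Overlapping pulses combine via
the pointwise maximum, not the sum. Parameters are fitted by bounded
least squares with greedy pulse addition and BIC model selection; a cell
is ERK-pulse⁺ when some fitted amplitude exceeds a noise-calibrated
threshold. `docs/methods.md` has the full account.

The processing chain around the model follows the standard recipe for
ratiometric imaging: per-channel maximum intensity projection,
background-subtracted FRET/CFP ratio with invalid-pixel flagging, 5×5
median filtering, intensity-modulated display rendering (8 hues × 32
intensity grades), per-ROI trace extraction, 6-min moving-average
smoothing, temporal autocorrelation, wave detection from pulse onsets,
and Mann–Whitney / Steel–Dwass / χ²+BH statistics.

A synthetic-data module generates traces, condition-labelled populations,
propagating-wave scenes and renderable two-channel movies with full
ground truth, so the entire pipeline is testable without microscopy data.

## Worked example

```python
import numpy as np
import erkpulse as ep
from erkpulse.traces import moving_average

# simulate one cell: basal 1.0 plus one pulse (A=0.1, t=45 min, 20 min long)
pulse = ep.PulseParams(amplitude=0.1, center=45.0, angular_freq=2*np.pi/20)
trace, truth = ep.generate_trace([pulse], ep.TraceSpec(noise_sd=0.01), seed=2)

fit = ep.fit_trace(trace)
print(fit.n_pulses, round(fit.basal, 4), fit.classification)
p = fit.pulses[0]
print(round(p.amplitude, 4), round(p.center, 2), round(p.duration, 2))
print(ep.pulse_metrics(fit, trace.duration)["frequency_per_hour"])
```

prints

```
1 1.001 pulse+
0.098 45.17 20.34
0.6666666666666666
```

— the fitter recovers the generating pulse (amplitude 0.098 ≈ 0.1,
center 45.17 ≈ 45 min, duration 20.34 ≈ 20 min) on the true basal level
(1.001 ≈ 1.0),
classifies the cell ERK-pulse⁺, and reports its pulse frequency
(1 pulse / 90 min = 0.67 h⁻¹).

The same workflow from the shell:

```
erkpulse simulate --n-cells 20 --rate 2.0 --seed 1 --out traces.csv
erkpulse fit traces.csv --out fits.csv
erkpulse stats fits.csv --out summary.csv
```

or end-to-end from a single YAML config (`erkpulse run config.yaml`),
which writes raw/smoothed traces, fits, condition summaries, pairwise
tests, optional wave events, and a manifest that makes the run exactly
reproducible. `erkpulse ratio / imd / extract` cover the imaging steps
for TIFF stacks, and `erkpulse fixtures` writes a small demo dataset.

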