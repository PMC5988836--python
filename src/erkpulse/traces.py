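"""Per-cell ratio time series and the standard preprocessing steps.

A :class:`Trace` holds one cell's FRET/CFP ratio time course on a uniform
time grid. Missing frames (e.g. frames where a cell had no valid pixels)
are stored as NaN and excluded from window means rather than interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from statsmodels.tsa.stattools import acf

__all__ = [
    "Trace",
    "moving_average",
    "normalize_to_baseline",
    "autocorrelation",
]

_SPACING_RTOL = 1e-6


@dataclass(frozen=True)
class Trace:
    """One cell's ratio time series.

    Parameters
    ----------
    cell_id : identifier of the cell (integer label or string).
    times : sample times in minutes, strictly increasing, uniformly spaced.
    values : dimensionless FRET/CFP ratio per time point; NaN marks a
        missing frame.
    condition : experimental condition label.
    """

    cell_id: object
    times: np.ndarray
    values: np.ndarray
    condition: str = "control"
    # samples averaged per point by smoothing (1 = raw); consumers use it
    # as the loss of independent information in model selection
    smoothing_samples: int = 1

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.shape != times.shape:
            raise ValueError("times and values must be 1-D and equal length")
        if times.size < 4:
            raise ValueError("a trace needs at least 4 samples")
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if np.ptp(dt) > _SPACING_RTOL * dt.mean():
            raise ValueError("times must be uniformly spaced")

    @property
    def interval(self) -> float:
        """Sampling interval in minutes."""
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        """Recording span in minutes (last minus first sample time)."""
        return float(self.times[-1] - self.times[0])

    def with_values(self, values: np.ndarray) -> "Trace":
        return replace(self, values=np.asarray(values, dtype=float))


def moving_average(trace: Trace, window: float = 6.0) -> Trace:
    """Centered moving average over a fixed time span.

    Each output sample is the mean of all non-missing samples within
    ``±window/2`` minutes of its time point, so the window shrinks near the
    ends of the recording instead of padding. At 1.5-min sampling the
    default 6-min window covers five samples in the interior.

    Parameters
    ----------
    window : total window span in minutes; must be at least the sampling
        interval.
    """
    if window < trace.interval:
        raise ValueError(
            f"window ({window} min) must be >= sampling interval "
            f"({trace.interval} min)"
        )
    half = window / 2.0 + 1e-9 * window  # tolerate float grid round-off
    t = trace.times
    v = trace.values
    out = np.empty_like(v)
    for i, ti in enumerate(t):
        sel = np.abs(t - ti) <= half
        vals = v[sel]
        vals = vals[np.isfinite(vals)]
        out[i] = vals.mean() if vals.size else np.nan
    m = int(np.round(window / trace.interval)) + 1
    return replace(
        trace,
        values=out,
        smoothing_samples=max(trace.smoothing_samples * m, 1),
    )


def normalize_to_baseline(trace: Trace, baseline_window: tuple[float, float]) -> Trace:
    """Divide a trace by its mean over a baseline time window.

    Used to express post-treatment activity relative to the pre-treatment
    level; the baseline mean of the output equals 1.

    Parameters
    ----------
    baseline_window : (start, stop) in minutes, inclusive; must contain at
        least two non-missing samples with positive mean.
    """
    lo, hi = baseline_window
    sel = (trace.times >= lo) & (trace.times <= hi)
    vals = trace.values[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("baseline window must contain at least 2 samples")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError(f"baseline mean must be positive, got {mean}")
    return trace.with_values(trace.values / mean)


def autocorrelation(trace: Trace, max_lag: int) -> np.ndarray:
    """Sample autocorrelation r(0..max_lag) of a trace.

    Mean-subtracted biased estimator (normalized by the lag-0
    autocovariance), so r(0)=1 and |r(k)| <= 1. Used to ask whether pulses
    recur periodically; a flat correlogram indicates sporadic timing.
    """
    v = trace.values
    if np.any(~np.isfinite(v)):
        raise ValueError("autocorrelation requires a gap-free trace")
    if max_lag >= v.size / 2:
        raise ValueError("max_lag must be below half the trace length")
    if np.var(v) == 0:
        raise ValueError("autocorrelation undefined for a zero-variance trace")
    return acf(v, nlags=max_lag, fft=False, adjusted=False)
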