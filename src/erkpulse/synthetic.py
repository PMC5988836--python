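"""Synthetic single-cell ERK-activity data with ground truth.

Emulates the study conditions of ratiometric FRET time-lapse imaging of
intestinal epithelium: per-cell basal ratio, sporadic cosine-shaped pulses
(stochastic timing, tens-of-minutes durations), neighbour-to-neighbour
pulse propagation with a fixed per-hop onset lag, additive sensor noise,
90-min recordings sampled every 1.5 min. Every generator is deterministic
for a given seed and carries its ground truth, so each downstream stage can
be tested without external imaging data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import PulseFit, PulseParams, evaluate_model
from .traces import Trace

__all__ = [
    "PulseTrainSpec",
    "TraceSpec",
    "SceneSpec",
    "ConditionEffect",
    "generate_pulse_train",
    "generate_trace",
    "generate_population",
    "generate_propagating_scene",
    "render_movie",
]

_DURATION_FLOOR = 6.0  # min; keeps omega finite and pulses resolvable


@dataclass(frozen=True)
class PulseTrainSpec:
    """Stochastic pulse-train parameters.

    rate : pulses per hour (homogeneous Poisson intensity).
    amplitude_mean, amplitude_sd : Gaussian amplitude draw in ratio units,
        truncated at 0.
    duration_mean, duration_sd : Gaussian pulse-duration draw in minutes,
        floored at 6 min.
    refractory : minimum separation between pulse centers in minutes.
    """

    rate: float = 2.0
    amplitude_mean: float = 0.1
    amplitude_sd: float = 0.02
    duration_mean: float = 20.0
    duration_sd: float = 4.0
    refractory: float = 0.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("pulse rate must be >= 0")
        if self.amplitude_mean < 0:
            raise ValueError("amplitude mean must be >= 0")
        if self.duration_mean <= 0:
            raise ValueError("duration mean must be > 0")
        if self.refractory < 0:
            raise ValueError("refractory period must be >= 0")


@dataclass(frozen=True)
class TraceSpec:
    """Recording parameters: basal level, noise, length and sampling."""

    basal: float = 1.0
    noise_sd: float = 0.01
    duration: float = 90.0
    interval: float = 1.5

    def __post_init__(self) -> None:
        if self.basal <= 0:
            raise ValueError("basal level must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.duration <= 0 or self.interval <= 0:
            raise ValueError("duration and interval must be > 0")
        if self.duration / self.interval < 4:
            raise ValueError("need at least 4 frames (duration/interval >= 4)")

    def time_grid(self) -> np.ndarray:
        n = int(np.floor(self.duration / self.interval)) + 1
        return np.arange(n) * self.interval


@dataclass(frozen=True)
class SceneSpec:
    """Propagating-wave scene on a rectangular cell grid.

    rows, cols : grid dimensions; spacing : centroid spacing in um.
    wave_sources : flat cell indices (row-major) that fire triggered
        pulses; hop_lag : onset delay per neighbour hop in minutes;
    trigger_prob : probability each 4-neighbour is recruited.
    """

    rows: int = 1
    cols: int = 5
    spacing: float = 20.0
    wave_sources: tuple[int, ...] = (0,)
    hop_lag: float = 2.0
    trigger_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must be nonempty")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.hop_lag <= 0:
            raise ValueError("hop_lag must be > 0")
        if not 0.0 <= self.trigger_prob <= 1.0:
            raise ValueError("trigger_prob must lie in [0, 1]")
        n = self.rows * self.cols
        if any(not 0 <= s < n for s in self.wave_sources):
            raise ValueError("wave_sources indices out of range")


@dataclass(frozen=True)
class ConditionEffect:
    """Multiplicative perturbation of a condition relative to control.

    Encodes the inhibitor regimes used for group comparisons: an EGFR-type
    inhibition suppresses pulse rate, an ErbB2-type inhibition lowers the
    basal level.
    """

    name: str
    rate_multiplier: float = 1.0
    basal_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.rate_multiplier < 0 or self.basal_multiplier < 0:
            raise ValueError("condition multipliers must be >= 0")


def generate_pulse_train(
    spec: PulseTrainSpec, duration: float, seed
) -> list[PulseParams]:
    """Draw one cell's ground-truth pulses over ``duration`` minutes.

    Timing is a homogeneous Poisson process (count ~ Poisson(rate x
    duration), centers uniform) with hard refractory rejection: candidates
    closer than ``refractory`` to an already-accepted earlier center are
    discarded. Amplitudes are Gaussian truncated at 0; durations Gaussian
    floored at 6 min. Returned sorted by center.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    rng = np.random.default_rng(seed)
    n = rng.poisson(spec.rate * duration / 60.0)
    centers = np.sort(rng.uniform(0.0, duration, size=n))
    kept: list[float] = []
    for c in centers:
        if not kept or c - kept[-1] >= spec.refractory:
            kept.append(float(c))
    pulses = []
    for c in kept:
        a = max(rng.normal(spec.amplitude_mean, spec.amplitude_sd), 0.0)
        d = max(rng.normal(spec.duration_mean, spec.duration_sd), _DURATION_FLOOR)
        pulses.append(PulseParams(amplitude=a, center=c, angular_freq=2 * np.pi / d))
    return pulses


def generate_trace(
    train: list[PulseParams],
    tspec: TraceSpec,
    seed,
    cell_id=0,
    condition: str = "control",
) -> tuple[Trace, PulseFit]:
    """Sample a noisy trace from a pulse train; also return the generating
    model as ground truth."""
    rng = np.random.default_rng(seed)
    truth = PulseFit(
        basal=tspec.basal,
        pulses=tuple(train),
        sse=0.0,
        cell_id=cell_id,
        condition=condition,
    )
    t = tspec.time_grid()
    y = evaluate_model(truth, t)
    if tspec.noise_sd > 0:
        y = y + rng.normal(0.0, tspec.noise_sd, size=t.size)
    return Trace(cell_id=cell_id, times=t, values=y, condition=condition), truth


def generate_population(
    n_cells: int,
    train_spec: PulseTrainSpec,
    tspec: TraceSpec,
    effects: list[ConditionEffect] = (),
    seed=0,
) -> tuple[list[Trace], list[PulseFit]]:
    """Condition-labelled population of traces with ground truth.

    A control group plus one group per effect, each of ``n_cells`` cells;
    an effect scales the control pulse rate and basal level by its
    multipliers.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    conditions = [ConditionEffect("control")] + list(effects)
    traces, truths = [], []
    for eff in conditions:
        tr_spec = PulseTrainSpec(
            rate=train_spec.rate * eff.rate_multiplier,
            amplitude_mean=train_spec.amplitude_mean,
            amplitude_sd=train_spec.amplitude_sd,
            duration_mean=train_spec.duration_mean,
            duration_sd=train_spec.duration_sd,
            refractory=train_spec.refractory,
        )
        cond_tspec = TraceSpec(
            # TraceSpec requires basal > 0; a zero multiplier maps to a
            # negligible positive level
            basal=max(tspec.basal * eff.basal_multiplier, 1e-12),
            noise_sd=tspec.noise_sd,
            duration=tspec.duration,
            interval=tspec.interval,
        )
        for i in range(n_cells):
            cid = f"{eff.name}_{i:03d}"
            train = generate_pulse_train(
                tr_spec, tspec.duration, rng.integers(2**31)
            )
            trace, truth = generate_trace(
                train, cond_tspec, rng.integers(2**31), cell_id=cid,
                condition=eff.name,
            )
            traces.append(trace)
            truths.append(truth)
    return traces, truths


def _grid_positions(scene: SceneSpec) -> np.ndarray:
    rr, cc = np.divmod(np.arange(scene.rows * scene.cols), scene.cols)
    return np.column_stack([cc, rr]).astype(float) * scene.spacing


def generate_propagating_scene(
    scene: SceneSpec, tspec: TraceSpec, seed, pulse: PulseTrainSpec | None = None
) -> tuple[list[Trace], np.ndarray, dict]:
    """Simulate a pulse wave spreading across a cell grid.

    Each source cell fires at a time drawn uniformly from the first third
    of the recording; the wave then spreads breadth-first to 4-neighbours,
    each recruited at most once with probability ``trigger_prob`` and an
    onset ``hop_lag`` minutes after its recruiter. Pulse onset is the start
    of the cosine support, so the pulse center is onset + duration/2.

    Returns
    -------
    traces : one per grid cell (non-recruited cells stay at basal+noise).
    positions : (n_cells, 2) centroid coordinates in um.
    truth : dict with per-cell onsets, the recruitment chains and the
        construction wave velocity spacing/hop_lag (um/min).
    """
    rng = np.random.default_rng(seed)
    pulse = pulse or PulseTrainSpec()
    n = scene.rows * scene.cols
    positions = _grid_positions(scene)
    onsets: dict[int, float] = {}
    parent: dict[int, int | None] = {}
    frontier: list[int] = []
    for s in scene.wave_sources:
        onsets[s] = float(rng.uniform(0.0, tspec.duration / 3.0))
        parent[s] = None
        frontier.append(s)
    while frontier:
        nxt = []
        for cell in frontier:
            r, c = divmod(cell, scene.cols)
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < scene.rows and 0 <= cc < scene.cols):
                    continue
                nb = rr * scene.cols + cc
                if nb in onsets:
                    continue
                if rng.uniform() < scene.trigger_prob:
                    onsets[nb] = onsets[cell] + scene.hop_lag
                    parent[nb] = cell
                    nxt.append(nb)
        frontier = nxt

    duration = max(pulse.duration_mean, _DURATION_FLOOR)
    omega = 2 * np.pi / duration
    traces = []
    for cell in range(n):
        train = []
        if cell in onsets:
            train = [
                PulseParams(
                    amplitude=pulse.amplitude_mean,
                    center=onsets[cell] + duration / 2.0,
                    angular_freq=omega,
                )
            ]
        trace, _ = generate_trace(
            train, tspec, rng.integers(2**31), cell_id=cell
        )
        traces.append(trace)

    chains = _recruitment_chains(parent, onsets)
    truth = {
        "onsets": onsets,
        "parent": parent,
        "chains": chains,
        "velocity": scene.spacing / scene.hop_lag,
    }
    return traces, positions, truth


def _recruitment_chains(parent, onsets) -> list[list[int]]:
    """Root-to-leaf recruitment paths, ordered by onset along each path."""
    children: dict[int, list[int]] = {c: [] for c in onsets}
    roots = []
    for cell, par in parent.items():
        if par is None:
            roots.append(cell)
        else:
            children[par].append(cell)
    chains = []

    def walk(cell, path):
        path = path + [cell]
        if not children[cell]:
            if len(path) >= 2:
                chains.append(path)
            return
        for ch in sorted(children[cell]):
            walk(ch, path)

    for root in sorted(roots):
        walk(root, [])
    return chains


def render_movie(
    traces: list[Trace],
    positions: np.ndarray,
    *,
    pixel_size: float = 1.0,
    shape: tuple[int, int] | None = None,
    nucleus_radius: float = 5.0,
    cfp_level: float = 1000.0,
    background: float = 0.0,
    noise_sd: float = 0.0,
    seed=0,
):
    """Render traces into a two-channel movie plus a label mask.

    Each cell is a disk of constant CFP intensity; the FRET channel is
    CFP x ratio(t) per pixel, so that FRET/CFP recovers the input trace
    exactly. A uniform background is added to both channels and optional
    Gaussian noise on top. Disks must not overlap so ROI ground truth stays
    unambiguous.

    Returns an :class:`~erkpulse.imaging.ImageStack` and a
    :class:`~erkpulse.imaging.LabelMask` whose labels are 1..n_cells in
    trace order.
    """
    from .imaging import ImageStack, LabelMask

    rng = np.random.default_rng(seed)
    positions = np.asarray(positions, dtype=float)
    if nucleus_radius <= 0:
        raise ValueError("nucleus_radius must be > 0")
    if traces:
        interval = traces[0].interval
        n_frames = traces[0].times.size
        if positions.shape != (len(traces), 2):
            raise ValueError("need one (x, y) position per trace")
    else:
        interval, n_frames = 1.5, 1
    r_px = nucleus_radius / pixel_size
    if shape is None:
        if len(traces):
            extent = positions.max(axis=0) / pixel_size + 2 * r_px + 2
            shape = (int(np.ceil(extent[1])), int(np.ceil(extent[0])))
        else:
            shape = (16, 16)
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    labels = np.zeros((ny, nx), dtype=np.int32)
    for i, pos in enumerate(positions):
        cx, cy = pos / pixel_size
        if not (r_px <= cx <= nx - r_px and r_px <= cy <= ny - r_px):
            raise ValueError(f"cell {i} does not fit inside the field")
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2
        if np.any(labels[disk]):
            raise ValueError(f"cell {i} overlaps another nucleus")
        labels[disk] = i + 1

    cfp = np.full((n_frames, ny, nx), 0.0)
    fret = np.zeros_like(cfp)
    for i, trace in enumerate(traces):
        disk = labels == i + 1
        cfp[:, disk] = cfp_level
        fret[:, disk] = cfp_level * trace.values[:, None]
    cfp += background
    fret += background
    if noise_sd > 0:
        cfp += rng.normal(0.0, noise_sd, size=cfp.shape)
        fret += rng.normal(0.0, noise_sd, size=fret.shape)
        np.clip(cfp, 0.0, None, out=cfp)
        np.clip(fret, 0.0, None, out=fret)
    stack = ImageStack(cfp=cfp, fret=fret, pixel_size=pixel_size, interval=interval)
    return stack, LabelMask(labels=labels)
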