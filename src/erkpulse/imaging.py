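"""Ratiometric FRET image processing.

Turns two-channel (CFP donor, FRET/YFP acceptor) time-lapse stacks into
background-corrected FRET/CFP ratio images, maximum intensity projections,
median-filtered ratio stacks, intensity-modulated display (IMD) renderings
and per-cell ratio traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .traces import Trace

__all__ = [
    "ImageStack",
    "RatioStack",
    "LabelMask",
    "compute_ratio_stack",
    "median_filter",
    "max_intensity_projection",
    "render_imd",
    "extract_cell_traces",
]


@dataclass(frozen=True)
class ImageStack:
    """Two-channel T(xZ)xYxX intensity stack.

    pixel_size is in micrometres, interval in minutes.
    """

    cfp: np.ndarray
    fret: np.ndarray
    pixel_size: float = 1.0
    interval: float = 1.5

    def __post_init__(self) -> None:
        cfp = np.asarray(self.cfp, dtype=float)
        fret = np.asarray(self.fret, dtype=float)
        object.__setattr__(self, "cfp", cfp)
        object.__setattr__(self, "fret", fret)
        if cfp.shape != fret.shape:
            raise ValueError("CFP and FRET stacks must have identical shapes")
        if cfp.ndim not in (3, 4):
            raise ValueError("expected TxYxX or TxZxYxX stacks")
        if self.interval <= 0:
            raise ValueError("frame interval must be > 0")
        if np.any(cfp < 0) or np.any(fret < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def has_z(self) -> bool:
        return self.cfp.ndim == 4

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.cfp.shape[0]) * self.interval


@dataclass(frozen=True)
class RatioStack:
    """TxYxX FRET/CFP ratio stack; NaN marks invalid pixels (CFP at or
    below the floor after background subtraction)."""

    values: np.ndarray
    pixel_size: float = 1.0
    interval: float = 1.5

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 3:
            raise ValueError("ratio stack must be TxYxX")

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) * self.interval


@dataclass(frozen=True)
class LabelMask:
    """Static integer ROI mask (YxX); 0 is background."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if labels.ndim != 2 or np.any(labels < 0):
            raise ValueError("labels must be a YxX array of nonnegative ints")
        object.__setattr__(self, "labels", labels)

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def compute_ratio_stack(
    stack: ImageStack,
    background_cfp: float = 0.0,
    background_fret: float = 0.0,
    cfp_floor: float = 0.0,
) -> RatioStack:
    """Per-pixel (FRET - bg) / (CFP - bg) ratio.

    Pixels whose background-subtracted CFP does not exceed ``cfp_floor``
    are flagged invalid (NaN) rather than silently set — dividing by dim or
    background pixels would otherwise produce meaningless ratios. Z-stacks
    are maximum-projected per channel before the division.

    Raises
    ------
    ValueError
        If no pixel is valid (floor or background set too high).
    """
    if background_cfp < 0 or background_fret < 0 or cfp_floor < 0:
        raise ValueError("backgrounds and floor must be >= 0")
    cfp, fret = stack.cfp, stack.fret
    if stack.has_z:
        cfp = np.stack([max_intensity_projection(f) for f in cfp])
        fret = np.stack([max_intensity_projection(f) for f in fret])
    denom = cfp - background_cfp
    valid = denom > cfp_floor
    if not np.any(valid):
        raise ValueError("no valid pixels: CFP floor/background too high")
    values = np.full(cfp.shape, np.nan)
    values[valid] = (fret[valid] - background_fret) / denom[valid]
    return RatioStack(
        values=values, pixel_size=stack.pixel_size, interval=stack.interval
    )


def median_filter(image: np.ndarray, size: int = 5) -> np.ndarray:
    """Median filter with invalid-pixel exclusion and shrinking borders.

    Each output pixel is the median of the finite values in its
    ``size x size`` neighbourhood; NaN inputs are excluded from the window
    and the window is truncated (not padded) at the image borders. A pixel
    whose whole window is invalid stays NaN. Accepts a 2-D frame or a
    TxYxX stack (filtered frame by frame).
    """
    image = np.asarray(image, dtype=float)
    if size < 3 or size % 2 == 0:
        raise ValueError("filter size must be odd and >= 3")
    if image.ndim == 3:
        return np.stack([median_filter(frame, size) for frame in image])
    if image.ndim != 2 or min(image.shape) < size:
        raise ValueError(f"image must be 2-D and at least {size}x{size}")
    pad = size // 2
    padded = np.pad(image, pad, mode="constant", constant_values=np.nan)
    windows = np.lib.stride_tricks.sliding_window_view(padded, (size, size))
    with np.errstate(all="ignore"):
        return np.nanmedian(windows, axis=(-2, -1))


def max_intensity_projection(zstack: np.ndarray) -> np.ndarray:
    """Project a ZxYxX stack to YxX by taking the per-pixel maximum over z."""
    zstack = np.asarray(zstack, dtype=float)
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise ValueError("expected a nonempty ZxYxX stack")
    return zstack.max(axis=0)


def render_imd(
    ratio: np.ndarray,
    intensity: np.ndarray,
    ratio_range: tuple[float, float],
    n_hues: int = 8,
    n_levels: int = 32,
) -> np.ndarray:
    """Intensity-modulated display of a ratio frame.

    Hue encodes the ratio in ``n_hues`` discrete bins from blue (low end of
    ``ratio_range``) to red (high end); brightness encodes the donor (CFP)
    intensity in ``n_levels`` grades. Out-of-range ratios clip to the end
    bins; invalid (NaN) ratio pixels render black. Returns an (Y, X, 3)
    uint8 RGB image.
    """
    lo, hi = ratio_range
    if not hi > lo:
        raise ValueError("ratio_range must have positive width")
    ratio = np.asarray(ratio, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if ratio.shape != intensity.shape or ratio.ndim != 2:
        raise ValueError("ratio and intensity must be matching 2-D frames")

    valid = np.isfinite(ratio)
    hue_idx = np.zeros(ratio.shape, dtype=int)
    frac = (np.nan_to_num(ratio, nan=lo) - lo) / (hi - lo)
    hue_idx = np.clip((frac * n_hues).astype(int), 0, n_hues - 1)
    # blue (240 deg) for the lowest bin through red (0 deg) for the highest
    hues = np.linspace(240.0, 0.0, n_hues) / 360.0

    imax = intensity.max()
    if imax > 0:
        level = np.clip(
            (intensity / imax * n_levels).astype(int), 0, n_levels - 1
        )
    else:
        level = np.zeros(intensity.shape, dtype=int)
    value = level / (n_levels - 1)
    value[~valid] = 0.0

    hsv = np.stack(
        [hues[hue_idx], np.ones_like(value), value], axis=-1
    )
    return (hsv_to_rgb(hsv) * 255).round().astype(np.uint8)


def extract_cell_traces(ratio: RatioStack, mask: LabelMask) -> list[Trace]:
    """Mean ratio per labelled cell per frame.

    Only valid pixels contribute to each frame's mean; a frame where a cell
    has no valid pixel becomes NaN in its trace. Labels are static over
    time (no tracking).
    """
    ids = mask.cell_ids
    if ids.size == 0:
        raise ValueError("mask contains no labelled cells")
    times = ratio.times
    traces = []
    for cid in ids:
        sel = mask.labels == cid
        if not np.any(sel):
            raise ValueError(f"label {cid} has no pixels")
        pix = ratio.values[:, sel]
        with np.errstate(all="ignore"):
            vals = np.nanmean(pix, axis=1)
        traces.append(Trace(cell_id=int(cid), times=times, values=vals))
    return traces
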