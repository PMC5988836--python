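"""CSV and TIFF input/output for traces, fits and image stacks."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fitting import PulseFit, PulseParams
from .imaging import ImageStack, LabelMask
from .traces import Trace

__all__ = [
    "traces_to_frame",
    "write_traces",
    "read_traces",
    "write_fits",
    "read_fits",
    "write_stack",
    "read_stack",
    "write_mask",
    "read_mask",
    "traces_to_heatmap",
]


def traces_to_frame(traces: list[Trace]) -> pd.DataFrame:
    """Long-format table (cell_id, condition, time_min, value)."""
    parts = [
        pd.DataFrame(
            {
                "cell_id": tr.cell_id,
                "condition": tr.condition,
                "time_min": tr.times,
                "value": tr.values,
            }
        )
        for tr in traces
    ]
    return pd.concat(parts, ignore_index=True)


def write_traces(traces: list[Trace], path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces(path) -> list[Trace]:
    df = pd.read_csv(path)
    out = []
    for (cid, cond), grp in df.groupby(["cell_id", "condition"], sort=False):
        grp = grp.sort_values("time_min")
        out.append(
            Trace(
                cell_id=cid,
                times=grp["time_min"].to_numpy(),
                values=grp["value"].to_numpy(),
                condition=str(cond),
            )
        )
    return out


def write_fits(fits: list[PulseFit], path) -> None:
    """Fit results as CSV: one summary row per cell (pulse_index = -1)
    followed by one row per pulse with amplitude, center and duration."""
    rows = []
    for fit in fits:
        rows.append(
            {
                "cell_id": fit.cell_id,
                "condition": fit.condition,
                "pulse_index": -1,
                "n_pulses": fit.n_pulses,
                "basal": fit.basal,
                "classification": fit.classification,
                "sse": fit.sse,
                "threshold": fit.threshold,
                "t_start": fit.t_start,
                "t_stop": fit.t_stop,
                "amplitude": np.nan,
                "center_min": np.nan,
                "duration_min": np.nan,
            }
        )
        for k, p in enumerate(fit.pulses):
            rows.append(
                {
                    "cell_id": fit.cell_id,
                    "condition": fit.condition,
                    "pulse_index": k,
                    "n_pulses": fit.n_pulses,
                    "basal": fit.basal,
                    "classification": fit.classification,
                    "sse": fit.sse,
                    "threshold": fit.threshold,
                    "t_start": fit.t_start,
                    "t_stop": fit.t_stop,
                    "amplitude": p.amplitude,
                    "center_min": p.center,
                    "duration_min": p.duration,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fits(path) -> list[PulseFit]:
    df = pd.read_csv(path)
    fits = []
    for (cid, cond), grp in df.groupby(["cell_id", "condition"], sort=False):
        head = grp[grp["pulse_index"] == -1].iloc[0]
        pulses = tuple(
            PulseParams(
                amplitude=row["amplitude"],
                center=row["center_min"],
                angular_freq=2 * np.pi / row["duration_min"],
            )
            for _, row in grp[grp["pulse_index"] >= 0]
            .sort_values("pulse_index")
            .iterrows()
        )
        fits.append(
            PulseFit(
                basal=head["basal"],
                pulses=pulses,
                sse=head["sse"],
                classification=head["classification"],
                threshold=head["threshold"],
                cell_id=cid,
                condition=str(cond),
                t_start=head.get("t_start", np.nan),
                t_stop=head.get("t_stop", np.nan),
            )
        )
    return fits


def write_stack(stack: ImageStack, cfp_path, fret_path) -> None:
    """Each channel as a multi-page float32 TIFF (one page per frame)."""
    tifffile.imwrite(cfp_path, stack.cfp.astype(np.float32))
    tifffile.imwrite(fret_path, stack.fret.astype(np.float32))


def read_stack(
    cfp_path, fret_path, pixel_size: float = 1.0, interval: float = 1.5
) -> ImageStack:
    return ImageStack(
        cfp=tifffile.imread(cfp_path),
        fret=tifffile.imread(fret_path),
        pixel_size=pixel_size,
        interval=interval,
    )


def write_mask(mask: LabelMask, path) -> None:
    tifffile.imwrite(path, mask.labels.astype(np.int32))


def read_mask(path) -> LabelMask:
    return LabelMask(labels=tifffile.imread(path).astype(np.int64))


def traces_to_heatmap(traces: list[Trace]) -> pd.DataFrame:
    """Cell x time matrix (heat-map layout): rows = cells, columns = time
    in minutes."""
    frame = traces_to_frame(traces)
    return frame.pivot_table(
        index="cell_id", columns="time_min", values="value"
    )
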