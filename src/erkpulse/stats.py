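"""Population summaries, wave-propagation detection, and group statistics.

Covers the quantifications used to compare conditions: the proportion of
ERK-pulse+ cells, pulse frequency and basal-level distributions, detection
of pulse waves travelling between adjacent cells with a velocity estimate,
and the nonparametric tests (Mann-Whitney U for two groups, Steel-Dwass
all-pairs comparison for three or more, Pearson chi-square with
Benjamini-Hochberg adjustment for count tables).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .fitting import PULSE_POS, PulseFit, detected_pulses, pulse_metrics

__all__ = [
    "WaveEvent",
    "TestResult",
    "summarize_population",
    "pulse_onsets",
    "detect_propagation",
    "mann_whitney",
    "steel_dwass",
    "bartlett_check",
    "chi2_bh",
]


@dataclass(frozen=True)
class WaveEvent:
    """An ordered chain of cells firing in sequence.

    onsets are in minutes (non-decreasing along the chain); velocity is the
    total centroid path length divided by the onset span, in um/min.
    """

    cells: tuple
    onsets: tuple
    velocity: float

    def __post_init__(self) -> None:
        if len(self.cells) < 2 or len(self.cells) != len(self.onsets):
            raise ValueError("a wave needs >= 2 cells with matching onsets")
        if np.any(np.diff(self.onsets) < 0):
            raise ValueError("onsets must be non-decreasing along the chain")
        if self.velocity <= 0:
            raise ValueError("velocity must be > 0")


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p: float
    groups: tuple
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p - 1e-12:
            raise ValueError("adjusted p cannot fall below the raw p")


def summarize_population(
    fits: list[PulseFit], recording_duration: float
) -> pd.DataFrame:
    """Per-condition summary of fitted cells.

    Returns a DataFrame indexed by condition with cell count, ERK-pulse+
    proportion, mean and median pulse frequency (per hour) and mean basal
    level.
    """
    if not fits:
        raise ValueError("no fits supplied")
    rows = []
    for fit in fits:
        m = pulse_metrics(fit, recording_duration)
        rows.append(
            {
                "condition": fit.condition,
                "pulse_pos": fit.classification == PULSE_POS,
                "frequency_per_hour": m["frequency_per_hour"],
                "basal": fit.basal,
            }
        )
    df = pd.DataFrame(rows)
    out = df.groupby("condition").agg(
        n_cells=("basal", "size"),
        proportion_pulse_pos=("pulse_pos", "mean"),
        mean_frequency_per_hour=("frequency_per_hour", "mean"),
        median_frequency_per_hour=("frequency_per_hour", "median"),
        mean_basal=("basal", "mean"),
    )
    return out


def pulse_onsets(fits: list[PulseFit], mode: str = "support") -> dict:
    """Pulse onset times per cell from fitted models.

    ``support`` takes the start of the cosine support, center - pi/omega
    (i.e. center minus half the duration); ``half_max`` takes the
    half-maximum upcrossing, center - pi/(2*omega). Only detected
    (supra-threshold) pulses contribute.
    """
    if mode not in ("support", "half_max"):
        raise ValueError("mode must be 'support' or 'half_max'")
    factor = 1.0 if mode == "support" else 0.5
    return {
        fit.cell_id: np.array(
            [
                p.center - factor * np.pi / p.angular_freq
                for p in detected_pulses(fit)
            ]
        )
        for fit in fits
    }


def _neighbour_pairs(ids, positions, neighbour_radius):
    pos = np.asarray(positions, dtype=float)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    if neighbour_radius is None:
        # adjacency from the typical packing: 1.5x the median
        # nearest-neighbour spacing
        np.fill_diagonal(d, np.inf)
        neighbour_radius = 1.5 * np.median(d.min(axis=1))
        np.fill_diagonal(d, 0.0)
    pairs = {}
    for i in range(len(ids)):
        for j in range(len(ids)):
            if i != j and d[i, j] <= neighbour_radius:
                pairs[(ids[i], ids[j])] = d[i, j]
    return pairs


def detect_propagation(
    onsets: dict,
    positions: dict,
    neighbour_radius: float | None = None,
    max_lag: float = 5.0,
    min_cells: int = 3,
) -> list[WaveEvent]:
    """Detect pulse waves travelling between adjacent cells.

    Cells are neighbours if their centroids lie within ``neighbour_radius``
    (default: 1.5x the median nearest-neighbour spacing). Each pulse onset
    is an event; a wave is a maximal chain of events in neighbouring cells
    whose onsets strictly increase by at most ``max_lag`` minutes per hop.
    Chains are extracted by repeatedly removing the longest path of the
    event DAG; chains shorter than ``min_cells`` are discarded. Velocity is
    the summed centroid path length over the chain divided by the onset
    span.

    Parameters
    ----------
    onsets : mapping cell_id -> array of pulse onset times (min).
    positions : mapping cell_id -> (x, y) centroid in um.
    """
    ids = [cid for cid in onsets if len(onsets[cid])]
    if len(ids) < 2:
        return []
    pos = {cid: np.asarray(positions[cid], dtype=float) for cid in onsets}
    pairs = _neighbour_pairs(
        list(onsets), [pos[c] for c in onsets], neighbour_radius
    )

    g = nx.DiGraph()
    events = [
        (cid, float(t)) for cid in ids for t in np.sort(np.asarray(onsets[cid]))
    ]
    g.add_nodes_from(events)
    for (ci, ti) in events:
        for (cj, tj) in events:
            if (ci, cj) in pairs and 0.0 < tj - ti <= max_lag:
                g.add_edge((ci, ti), (cj, tj))

    waves = []
    while g.number_of_nodes():
        path = nx.dag_longest_path(g)
        if len(path) < max(min_cells, 2):
            break
        cells = tuple(c for c, _ in path)
        times = tuple(t for _, t in path)
        length = sum(
            np.linalg.norm(pos[cells[k + 1]] - pos[cells[k]])
            for k in range(len(cells) - 1)
        )
        span = times[-1] - times[0]
        waves.append(
            WaveEvent(cells=cells, onsets=times, velocity=length / span)
        )
        g.remove_nodes_from(path)
    return waves


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test between two samples.

    Exact enumeration for small samples without ties; normal approximation
    with tie correction otherwise (scipy's automatic policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult(
        method="mann-whitney",
        statistic=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        groups=("a", "b"),
    )


def bartlett_check(groups: dict) -> TestResult:
    """Bartlett's test of homoscedasticity across groups (reported, not
    enforced, before the Steel-Dwass comparison)."""
    stat, p = sps.bartlett(*groups.values())
    return TestResult(
        method="bartlett", statistic=float(stat), p=float(p),
        groups=tuple(groups),
    )


def steel_dwass(groups: dict) -> list[TestResult]:
    """Steel-Dwass all-pairs nonparametric multiple comparison.

    For each pair of groups, the samples are ranked jointly (midranks for
    ties) and the rank-sum statistic is standardized with the
    tie-corrected variance; the standardized statistic times sqrt(2) is
    referred to the Studentized range distribution with k groups and
    infinite degrees of freedom, which controls the family-wise error over
    all pairs.

    Parameters
    ----------
    groups : mapping of group label -> 1-D sample. Requires >= 3 nonempty
        groups (use :func:`mann_whitney` for two).
    """
    labels = list(groups)
    k = len(labels)
    if k < 3:
        raise ValueError("steel_dwass needs >= 3 groups; use mann_whitney")
    samples = {g: np.asarray(groups[g], dtype=float) for g in labels}
    if any(s.size == 0 for s in samples.values()):
        raise ValueError("all groups must be nonempty")

    results = []
    for i in range(k):
        for j in range(i + 1, k):
            x, y = samples[labels[i]], samples[labels[j]]
            ni, nj = x.size, y.size
            n = ni + nj
            ranks = sps.rankdata(np.concatenate([x, y]))
            w = ranks[:ni].sum()
            expected = ni * (n + 1) / 2.0
            # tie-corrected variance of the rank sum
            var = ni * nj / (n * (n - 1.0)) * (
                np.sum(ranks**2) - n * (n + 1.0) ** 2 / 4.0
            )
            if var <= 0:
                stat, p = 0.0, 1.0
            else:
                t = (w - expected) / np.sqrt(var)
                stat = abs(t) * np.sqrt(2.0)
                p = float(sps.studentized_range.sf(stat, k, np.inf))
            results.append(
                TestResult(
                    method="steel-dwass",
                    statistic=float(stat),
                    p=float(min(max(p, 0.0), 1.0)),
                    groups=(labels[i], labels[j]),
                )
            )
    return results


def chi2_bh(tables: list[np.ndarray], labels=None) -> list[TestResult]:
    """Pearson chi-square per contingency table with BH adjustment.

    Each table is a 2 x k (or r x k) count matrix; p-values across tables
    are adjusted with the Benjamini-Hochberg step-up procedure.
    """
    if not tables:
        raise ValueError("no tables supplied")
    labels = labels or [f"table_{i}" for i in range(len(tables))]
    raw = []
    stats = []
    for tab in tables:
        tab = np.asarray(tab, dtype=float)
        if np.any(tab < 0):
            raise ValueError("counts must be >= 0")
        if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
            raise ValueError("every row and column must have a positive margin")
        if np.all(tab == tab[0, 0]):
            # uniform table: no association by construction
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.chi2_contingency(tab, correction=False)[:2]
        raw.append(float(p))
        stats.append(float(stat))
    adjusted = multipletests(raw, method="fdr_bh")[1]
    return [
        TestResult(
            method="chi2-bh",
            statistic=stats[i],
            p=raw[i],
            adjusted_p=float(adjusted[i]),
            groups=(labels[i],),
        )
        for i in range(len(tables))
    ]
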