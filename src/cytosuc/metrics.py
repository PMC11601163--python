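"""Evaluation metrics: correlation heatmaps, sigma change, fold changes,
energy distance between cell populations, and threshold classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.stats import gaussian_kde

from ._exceptions import DataError, DegenerateDataError
from .io_panel import EventTable


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over a cell stratum.

    Zero-variance markers get NaN rows/columns (with a warning).
    """

    markers: list[str]
    values: np.ndarray
    stratum: str = "all cells"


@dataclass
class ConfusionCounts:
    """2x2 cross-tabulation: reference classification vs comparison."""

    both_positive: int
    ref_only: int
    cmp_only: int
    both_negative: int

    @property
    def total(self) -> int:
        return self.both_positive + self.ref_only + self.cmp_only + self.both_negative

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [[self.both_positive, self.ref_only], [self.cmp_only, self.both_negative]],
            dtype=int,
        )


def marker_correlations(
    table: EventTable,
    markers: list[str] | None = None,
    stratum: np.ndarray | None = None,
    stratum_name: str = "all cells",
) -> CorrelationMatrix:
    """Pairwise Pearson r between z-scored marker values within a stratum."""
    markers = list(markers) if markers is not None else list(table.channel_names)
    table.require_channels(markers)
    idx = [table.index_of(m) for m in markers]
    values = table.values[:, idx]
    if stratum is not None:
        values = values[np.asarray(stratum, dtype=bool)]
    if values.shape[0] < 3:
        raise DataError("marker_correlations needs at least 3 cells in the stratum")
    sd = values.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        warnings.warn(
            f"zero-variance markers {[markers[i] for i in dead]}: correlation undefined"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr[dead, :] = np.nan
    corr[:, dead] = np.nan
    keep = np.setdiff1d(np.arange(len(markers)), dead)
    corr[keep, keep] = 1.0
    return CorrelationMatrix(markers=markers, values=corr, stratum=stratum_name)


def delta_sigma(before: np.ndarray, after: np.ndarray) -> float:
    """Signed percent change of the standard deviation, after vs before."""
    before = np.asarray(before, dtype=np.float64)
    after = np.asarray(after, dtype=np.float64)
    s0 = before.std(ddof=1)
    if s0 == 0:
        raise DegenerateDataError("delta_sigma undefined: zero SD before correction")
    return float((after.std(ddof=1) - s0) / s0 * 100.0)


def fold_change(
    table: EventTable, marker: str, group_a: np.ndarray, group_b: np.ndarray
) -> float:
    """Difference of group means of asinh-scale values, mean(A) - mean(B).

    On the asinh scale a difference of means is a log-fold-change
    analogue.
    """
    y = table.channel(marker)
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    if not group_a.any() or not group_b.any():
        raise DataError("fold_change: both groups must be non-empty")
    return float(y[group_a].mean() - y[group_b].mean())


def e_distance(
    group_a: np.ndarray,
    group_b: np.ndarray,
    max_cells: int | None = None,
    seed: int | None = None,
) -> float:
    """Energy distance between two cell populations.

    ``E = 2*d_AB - d_AA - d_BB`` where ``d_XY`` is the mean pairwise
    squared Euclidean distance between (or within) groups. Within-group
    means average over all ordered pairs including self-pairs (the
    V-statistic), which makes ``E(A, A) = 0`` exactly; a singleton group
    contributes 0. Groups larger than ``max_cells`` are subsampled
    without replacement using ``seed``.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(group_b, dtype=np.float64))
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise DataError("e_distance groups must be 2-D with matching marker count")
    if len(a) < 1 or len(b) < 1:
        raise DataError("e_distance needs non-empty groups")
    if max_cells is not None:
        rng = np.random.default_rng(seed)
        if len(a) > max_cells:
            a = a[rng.choice(len(a), size=max_cells, replace=False)]
        if len(b) > max_cells:
            b = b[rng.choice(len(b), size=max_cells, replace=False)]

    def within(x: np.ndarray) -> float:
        if len(x) < 2:
            return 0.0
        return float(pdist(x, metric="sqeuclidean").sum() * 2.0 / len(x) ** 2)

    d_ab = float(cdist(a, b, metric="sqeuclidean").mean())
    return 2.0 * d_ab - within(a) - within(b)


def find_bimodal_threshold(
    values: np.ndarray, bw_method: str | float = "silverman", grid_size: int = 512
) -> float:
    """Valley of a Gaussian KDE between its two highest modes.

    Intended for gating a bimodal marker (e.g. an apoptosis marker) into
    low/high populations. Raises when the density has fewer than two
    modes on the evaluation grid.
    """
    values = np.asarray(values, dtype=np.float64)
    if len(values) < 50:
        raise DataError("find_bimodal_threshold needs at least 50 cells")
    if values.std() == 0:
        raise DegenerateDataError("constant vector has no threshold")
    kde = gaussian_kde(values, bw_method=bw_method)
    grid = np.linspace(values.min(), values.max(), grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    if dens[0] > dens[1]:
        peaks = np.append(0, peaks)
    if dens[-1] > dens[-2]:
        peaks = np.append(peaks, grid_size - 1)
    if len(peaks) < 2:
        raise DegenerateDataError("density is unimodal: no threshold found")
    top2 = peaks[np.argsort(dens[peaks])][-2:]
    lo, hi = int(top2.min()), int(top2.max())
    if hi - lo < 2:
        raise DegenerateDataError("modes are adjacent on the grid: no valley")
    valley = lo + 1 + int(np.argmin(dens[lo + 1 : hi]))
    return float(grid[valley])


def classify_and_compare(
    values_before: np.ndarray,
    values_after: np.ndarray,
    t_before: float,
    t_after: float,
) -> ConfusionCounts:
    """Cross-tabulate per-cell classifications before vs after correction."""
    vb = np.asarray(values_before, dtype=np.float64)
    va = np.asarray(values_after, dtype=np.float64)
    if vb.shape != va.shape:
        raise DataError("classify_and_compare: length mismatch")
    if not (np.isfinite(t_before) and np.isfinite(t_after)):
        raise DataError("thresholds must be finite")
    ref = vb > t_before
    cmp_ = va > t_after
    return ConfusionCounts(
        both_positive=int(np.sum(ref & cmp_)),
        ref_only=int(np.sum(ref & ~cmp_)),
        cmp_only=int(np.sum(~ref & cmp_)),
        both_negative=int(np.sum(~ref & ~cmp_)),
    )
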