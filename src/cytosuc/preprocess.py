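"""Transforms, surrogate-channel assembly, centering, and PCA.

Surrogate channels (SUCs) are per-cell proxies of confounders such as
cell size and staining efficiency: the mean of standardized DNA stain
channels, the mean of the top barcoding isotopes, and designated
abundant-protein antibody channels. They are assembled into a
:class:`SucMatrix` on the asinh scale, optionally centered globally or
per sample, and can be summarized by PCA (:func:`pca_sucs`).

Conventions: standard deviations use denominator ``n - 1`` everywhere;
PCA loading columns are sign-fixed so their largest-magnitude entry is
positive, making output deterministic across linear-algebra backends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._exceptions import ConfigurationError, DegenerateDataError, StateError
from .io_panel import ASINH, ASINH_ZSCORED, RAW, EventTable, PanelConfig

MEAN_DNA = "mean_DNA"
MEAN_BC = "mean_BC"


@dataclass
class SucMatrix:
    """Cells x n_suc surrogate values plus the centering applied."""

    values: np.ndarray
    suc_names: list[str]
    centering: str  # none | global | per_sample
    sample_labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_labels), len(self.suc_names)):
            raise ValueError("SucMatrix shape inconsistent with names/labels")
        if self.centering not in ("none", "global", "per_sample"):
            raise ValueError(f"unknown centering {self.centering!r}")


@dataclass
class PcaResult:
    """Scores, unit-norm loadings (columns = PCs) and % variance explained."""

    scores: np.ndarray
    loadings: np.ndarray
    var_explained: np.ndarray


def asinh_transform(table: EventTable, cofactor: float | None = None) -> EventTable:
    """Apply ``asinh(v / cofactor)`` element-wise (default cofactor 5)."""
    if table.transform_state != RAW:
        raise StateError(
            f"asinh_transform expects raw data, got {table.transform_state!r}"
        )
    cofactor = 5.0 if cofactor is None else float(cofactor)
    if not cofactor > 0:
        raise ConfigurationError("asinh cofactor must be positive")
    out = table.copy()
    out.values = np.arcsinh(out.values / cofactor)
    out.transform_state = ASINH
    return out


def _zscore_columns(values: np.ndarray, names: list[str], where: str) -> np.ndarray:
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DegenerateDataError(
            f"zero-variance channel(s) {[names[i] for i in dead]} in {where}"
        )
    return (values - mean) / sd


def zscore(table: EventTable, per_sample: bool = False) -> EventTable:
    """Z-score every channel (SD with denominator n-1), globally or per sample."""
    if table.transform_state != ASINH:
        raise StateError(f"zscore expects asinh data, got {table.transform_state!r}")
    out = table.copy()
    if per_sample:
        for lab in out.samples():
            mask = out.sample_labels == lab
            out.values[mask] = _zscore_columns(
                out.values[mask], out.channel_names, f"sample {lab!r}"
            )
    else:
        out.values = _zscore_columns(out.values, out.channel_names, "global stratum")
    out.transform_state = ASINH_ZSCORED
    return out


def minmax(values: np.ndarray) -> np.ndarray:
    """Affine rescale of a vector onto [0, 1]."""
    values = np.asarray(values, dtype=np.float64)
    lo, hi = values.min(), values.max()
    if hi <= lo:
        raise DegenerateDataError("minmax undefined for a constant vector")
    return (values - lo) / (hi - lo)


def compute_mean_dna(table: EventTable, panel: PanelConfig) -> np.ndarray:
    """Per-cell mean of the standardized DNA-stain (iridium) channels.

    Each DNA channel is z-scored across all cells on the asinh scale
    before averaging so channels with different absolute sensitivity
    contribute equally.
    """
    if table.transform_state != ASINH:
        raise StateError("compute_mean_dna expects asinh-transformed data")
    if not panel.dna_channels:
        raise ConfigurationError("panel defines no dna_channels")
    table.require_channels(panel.dna_channels)
    cols = table.values[:, [table.index_of(c) for c in panel.dna_channels]]
    return _zscore_columns(cols, list(panel.dna_channels), "DNA channels").mean(axis=1)


def compute_mean_bc(table: EventTable, panel: PanelConfig) -> np.ndarray:
    """Per-cell mean of the ``n_top_barcodes`` largest barcode-channel values.

    Which channels are "used" may differ cell to cell; only the magnitude
    ranking within each cell matters.
    """
    if table.transform_state != ASINH:
        raise StateError("compute_mean_bc expects asinh-transformed data")
    if not panel.barcode_channels:
        raise ConfigurationError("panel defines no barcode_channels")
    if panel.n_top_barcodes > len(panel.barcode_channels):
        raise ConfigurationError("n_top_barcodes exceeds available barcode channels")
    table.require_channels(panel.barcode_channels)
    cols = table.values[:, [table.index_of(c) for c in panel.barcode_channels]]
    k = panel.n_top_barcodes
    top = np.partition(cols, cols.shape[1] - k, axis=1)[:, -k:]
    return top.mean(axis=1)


def assemble_sucs(
    table: EventTable, panel: PanelConfig, centering: str = "global"
) -> SucMatrix:
    """Build the surrogate matrix [mean_DNA, mean_BC, antibody..., extra...].

    Roles absent from the panel are skipped. ``centering`` subtracts the
    column mean over all cells (``global``) or within each sample
    (``per_sample``); ``none`` leaves the columns untouched.
    """
    if table.transform_state != ASINH:
        raise StateError("assemble_sucs expects asinh-transformed data")
    if centering not in ("none", "global", "per_sample"):
        raise ConfigurationError(f"unknown centering {centering!r}")
    columns: list[np.ndarray] = []
    names: list[str] = []
    if panel.dna_channels:
        columns.append(compute_mean_dna(table, panel))
        names.append(MEAN_DNA)
    if panel.barcode_channels:
        columns.append(compute_mean_bc(table, panel))
        names.append(MEAN_BC)
    for marker in list(panel.antibody_suc_markers) + list(panel.extra_suc_markers):
        columns.append(table.channel(marker))
        names.append(marker)
    if not columns:
        raise ConfigurationError("panel yields an empty SUC roster")
    values = np.column_stack(columns)
    if centering == "global":
        values = values - values.mean(axis=0)
    elif centering == "per_sample":
        values = values.copy()
        for lab in table.samples():
            mask = table.sample_labels == lab
            values[mask] -= values[mask].mean(axis=0)
    return SucMatrix(values, names, centering, table.sample_labels.copy())


def pca_sucs(sucs: SucMatrix, z_per_sample: bool = False) -> PcaResult:
    """PCA of the z-scored surrogate matrix.

    Columns are z-scored (per sample when ``z_per_sample``, else
    globally) and the covariance matrix (denominator n-1) is
    eigendecomposed, i.e. a correlation PCA in the global case. Scores
    are the z-scored data projected on the loadings.
    """
    if sucs.values.shape[1] < 2:
        raise ConfigurationError("PCA needs at least two surrogate columns")
    z = sucs.values.copy()
    if z_per_sample:
        for lab in dict.fromkeys(sucs.sample_labels):
            mask = sucs.sample_labels == lab
            z[mask] = _zscore_columns(z[mask], sucs.suc_names, f"sample {lab!r}")
    else:
        z = _zscore_columns(z, sucs.suc_names, "global stratum")
    # per-sample z-scoring leaves a (tiny) global mean; PCA is on centered data
    z = z - z.mean(axis=0)
    cov = z.T @ z / (z.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval[-1] < -1e-10 * max(eigval[0], 1.0):  # pragma: no cover
        raise DegenerateDataError("covariance matrix is not PSD")
    eigval = np.clip(eigval, 0.0, None)
    if eigval[-1] <= 1e-12 * max(eigval[0], 1.0):
        warnings.warn("surrogate matrix is rank deficient after z-scoring")
    # deterministic sign: largest-magnitude loading entry positive
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    scores = z @ eigvec
    var_explained = 100.0 * eigval / eigval.sum()
    return PcaResult(scores=scores, loadings=eigvec, var_explained=var_explained)
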