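"""Per-marker linear models and residual-based correction.

Each marker ``y`` (asinh scale) is regressed on centered surrogate
columns or on their principal-component scores, with one of three
designs:

* ``simple``      — one intercept and one slope vector for the whole
  dataset: ``[1, X]``.
* ``offset``      — per-sample intercepts, shared slopes: one indicator
  column per sample and no global intercept (cell-means coding), so the
  per-sample offsets are read directly as coefficients.
* ``interaction`` — per-sample intercepts *and* slopes, fitted as
  independent ordinary-least-squares problems within each sample.

The corrected value keeps the per-sample offset plus the residual
(``y* = O(j) + eps``); with ``keep_offset=False`` every offset is
replaced by the unweighted mean of the per-sample offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import (
    ConfigurationError,
    SingularDesignError,
    StateError,
    StratumSizeError,
)
from .io_panel import ASINH, EventTable, PanelConfig
from .preprocess import PcaResult, SucMatrix, assemble_sucs, pca_sucs

#: relative condition-number threshold below which a design is singular
RCOND = 1e-10

_FORMS = ("simple", "offset", "interaction")
_PREDICTORS = ("sucs", "pcs")
_CENTERINGS = ("global", "per_sample")


@dataclass(frozen=True)
class ModelSpec:
    """Choice of model form, predictor source, centering, and offset policy."""

    form: str = "interaction"
    predictors: str = "pcs"
    n_pcs: int | None = None  # None = all surrogate PCs
    centering: str = "global"
    keep_offset: bool = True

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ConfigurationError(f"unknown model form {self.form!r}")
        if self.predictors not in _PREDICTORS:
            raise ConfigurationError(f"unknown predictor source {self.predictors!r}")
        if self.centering not in _CENTERINGS:
            raise ConfigurationError(f"unknown centering {self.centering!r}")
        if self.n_pcs is not None and self.n_pcs < 1:
            raise ConfigurationError("n_pcs must be at least 1")


@dataclass
class ModelFit:
    """One marker's fitted intercepts, slopes, and residuals."""

    marker_name: str
    form: str
    intercepts: dict  # sample label -> offset O(j)
    slopes: dict  # sample label -> slope vector (shared object unless interaction)
    residuals: np.ndarray
    fitted: np.ndarray
    predictor_names: list[str]
    r_squared: float
    sample_labels: np.ndarray = field(repr=False, default=None)

    def offset_per_cell(self, keep_offset: bool = True) -> np.ndarray:
        if keep_offset:
            lut = self.intercepts
            return np.array([lut[lab] for lab in self.sample_labels])
        grand = float(np.mean(list(self.intercepts.values())))
        return np.full(len(self.residuals), grand)


def _ols(design: np.ndarray, y: np.ndarray, context: str) -> np.ndarray:
    """Least squares via SVD with an explicit rank check."""
    coef, _, rank, sv = np.linalg.lstsq(design, y, rcond=RCOND)
    if rank < design.shape[1]:
        raise SingularDesignError(
            f"rank-deficient design ({rank} < {design.shape[1]} columns) in {context}; "
            "predictors are collinear"
        )
    return coef


def fit_marker(
    y: np.ndarray,
    X: SucMatrix | np.ndarray,
    samples: np.ndarray,
    spec: ModelSpec,
    marker_name: str = "marker",
    predictor_names: list[str] | None = None,
) -> ModelFit:
    """Ordinary-least-squares fit of one marker against predictor columns.

    ``X`` must already be centered according to ``spec.centering`` (an
    :class:`SucMatrix` carries its centering; PC scores are centered by
    construction). ``samples`` gives the stratum label of each cell.
    """
    if isinstance(X, SucMatrix):
        if predictor_names is None:
            predictor_names = list(X.suc_names)
        X = X.values
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=np.float64)
    samples = np.asarray(samples, dtype=object)
    n, p = X.shape
    if p < 1:
        raise ConfigurationError("fit_marker needs at least one predictor column")
    if len(y) != n or len(samples) != n:
        raise ConfigurationError("y, X and samples disagree in length")
    if predictor_names is None:
        predictor_names = [f"x{i + 1}" for i in range(p)]

    labels = list(dict.fromkeys(samples))
    intercepts: dict = {}
    slopes: dict = {}
    fitted = np.empty(n)

    if spec.form == "simple":
        coef = _ols(np.column_stack([np.ones(n), X]), y, f"marker {marker_name!r}")
        beta0, alpha = coef[0], coef[1:]
        for lab in labels:
            intercepts[lab] = float(beta0)
            slopes[lab] = alpha
        fitted = beta0 + X @ alpha
    elif spec.form == "offset":
        _check_strata(samples, labels, p, marker_name)
        indicators = np.column_stack([(samples == lab).astype(float) for lab in labels])
        coef = _ols(np.column_stack([indicators, X]), y, f"marker {marker_name!r}")
        alpha = coef[len(labels):]
        for i, lab in enumerate(labels):
            intercepts[lab] = float(coef[i])
            slopes[lab] = alpha
        fitted = indicators @ coef[: len(labels)] + X @ alpha
    else:  # interaction: independent per-sample OLS
        _check_strata(samples, labels, p, marker_name)
        for lab in labels:
            mask = samples == lab
            coef = _ols(
                np.column_stack([np.ones(mask.sum()), X[mask]]),
                y[mask],
                f"marker {marker_name!r}, sample {lab!r}",
            )
            intercepts[lab] = float(coef[0])
            slopes[lab] = coef[1:]
            fitted[mask] = coef[0] + X[mask] @ coef[1:]

    residuals = y - fitted
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(residuals**2))
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return ModelFit(
        marker_name=marker_name,
        form=spec.form,
        intercepts=intercepts,
        slopes=slopes,
        residuals=residuals,
        fitted=fitted,
        predictor_names=list(predictor_names),
        r_squared=r2,
        sample_labels=samples,
    )


def _check_strata(samples, labels, p, marker_name) -> None:
    for lab in labels:
        size = int((samples == lab).sum())
        if size < p + 2:
            raise StratumSizeError(
                f"sample {lab!r} has {size} cells, fewer than "
                f"{p + 2} required for marker {marker_name!r}"
            )


def correct_marker(fit: ModelFit, spec: ModelSpec) -> np.ndarray:
    """Corrected values ``y* = O(j) + residual`` for one marker.

    With ``spec.keep_offset`` false, every per-sample offset is replaced
    by the unweighted mean of the offsets, discarding between-sample
    intercept differences.
    """
    return fit.offset_per_cell(spec.keep_offset) + fit.residuals


@dataclass
class CorrectedTable:
    """Corrected event table plus everything used to produce it."""

    table: EventTable
    fit_register: dict
    suc_matrix: SucMatrix
    pca: PcaResult | None


def correct_events(
    table: EventTable, panel: PanelConfig, spec: ModelSpec
) -> CorrectedTable:
    """Assemble surrogates, fit every marker, and return corrected values.

    Surrogate channels themselves are passed through uncorrected;
    markers listed as antibody/extra surrogates may not appear in
    ``markers_to_correct`` (self-regression returns a constant).
    """
    if table.transform_state != ASINH:
        raise StateError("correct_events expects an asinh-transformed table")
    markers = list(panel.markers_to_correct)
    if not markers:
        raise ConfigurationError("panel.markers_to_correct is empty")
    table.require_channels(markers)
    self_ref = set(markers) & set(panel.suc_channels)
    if self_ref:
        raise ConfigurationError(
            f"markers also listed as surrogate channels: {sorted(self_ref)}; "
            "refusing to correct a marker against itself"
        )

    sucs = assemble_sucs(table, panel, centering=spec.centering)
    pca: PcaResult | None = None
    if spec.predictors == "pcs":
        pca = pca_sucs(sucs, z_per_sample=(spec.centering == "per_sample"))
        n_pcs = len(sucs.suc_names) if spec.n_pcs is None else spec.n_pcs
        if n_pcs > len(sucs.suc_names):
            raise ConfigurationError(
                f"n_pcs={n_pcs} exceeds the {len(sucs.suc_names)} surrogate columns"
            )
        X = pca.scores[:, :n_pcs]
        pred_names = [f"PC{i + 1}" for i in range(n_pcs)]
    else:
        X = sucs.values
        pred_names = list(sucs.suc_names)

    out = table.copy()
    register: dict = {}
    for marker in markers:
        y = table.channel(marker)
        fit = fit_marker(
            y, X, table.sample_labels, spec,
            marker_name=marker, predictor_names=pred_names,
        )
        out.values[:, out.index_of(marker)] = correct_marker(fit, spec)
        register[marker] = fit
    return CorrectedTable(table=out, fit_register=register, suc_matrix=sucs, pca=pca)


def fits_to_frame(register: dict) -> pd.DataFrame:
    """Tidy (marker, sample, term, estimate) view of a fit register."""
    rows = []
    for marker, fit in register.items():
        for lab in fit.intercepts:
            rows.append((marker, lab, "intercept", fit.intercepts[lab]))
            for name, a in zip(fit.predictor_names, fit.slopes[lab]):
                rows.append((marker, lab, name, float(a)))
        rows.append((marker, "", "r_squared", fit.r_squared))
    return pd.DataFrame(rows, columns=["marker", "sample", "term", "estimate"])
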