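"""Synthetic confounded mass-cytometry generator and validation harness.

Generates ground-truth marker intensities (multivariate normal on the
asinh scale with a block correlation structure, two conditions, a planted
mean shift in a subset of markers), injects per-marker linear and
quadratic artefacts driven by a log-normal cell size, and emits four
surrogate proxy channels that load on the same size factor. The
validation loop corrupts, corrects, re-detects the planted markers, and
scores correlation recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from ._exceptions import ConfigurationError, DataError
from .io_panel import ASINH, EventTable
from .core_models import ModelSpec, correct_marker, fit_marker
from .preprocess import SucMatrix, pca_sucs

CONTROL = "control"
TREATED = "treated"

#: affine maps from centered log size to the four proxy channels
_SUC_INTERCEPTS = (3.0, 2.5, 4.0, 3.5)
_SUC_SLOPES = (1.0, 0.9, 0.8, 1.1)
SUC_PROXY_NAMES = ("size_proxy_1", "size_proxy_2", "size_proxy_3", "size_proxy_4")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one family of simulated datasets."""

    n_cells_per_condition: int = 5000
    n_markers: int = 20
    n_signif_markers: int = 4
    effect_size: float = 0.5
    #: ((block_size, within_block_r), ...) laid over the first markers;
    #: markers beyond the blocks are mutually uncorrelated
    marker_corr: tuple = ((4, 0.6), (4, 0.4))
    base_mean: float = 2.0
    base_sd: float = 0.5
    size_logmean: float = 0.0
    size_logsd: float = 0.4
    linear_coef_range: tuple = (0.2, 0.8)
    quad_coef_range: tuple = (0.02, 0.10)
    suc_noise_sd: float = 0.2
    n_datasets: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signif_markers > self.n_markers:
            raise ConfigurationError("n_signif_markers exceeds n_markers")
        if not self.size_logsd > 0:
            raise ConfigurationError("size_logsd must be positive")
        if sum(b for b, _ in self.marker_corr) > self.n_markers:
            raise ConfigurationError("correlation blocks exceed n_markers")
        self.correlation_matrix()  # raises if not positive definite

    def correlation_matrix(self) -> np.ndarray:
        corr = np.eye(self.n_markers)
        start = 0
        for size, r in self.marker_corr:
            block = np.full((size, size), float(r))
            np.fill_diagonal(block, 1.0)
            corr[start : start + size, start : start + size] = block
            start += size
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError(
                "marker correlation structure is not positive definite"
            ) from exc
        return corr


@dataclass
class SimTruth:
    """One simulated dataset with its ground truth and artefact recipe."""

    ground_truth: np.ndarray
    observed: np.ndarray
    condition_labels: np.ndarray
    cell_size: np.ndarray
    size_score: np.ndarray  # centered log cell size, the artefact driver
    artefact_coefs: np.ndarray  # (n_markers, 2): linear a_m, quadratic b_m
    signif_marker_ids: frozenset
    suc_channels: np.ndarray
    marker_names: list[str] = field(default_factory=list)


def simulate_dataset(config: SimConfig, dataset_index: int = 0) -> SimTruth:
    """Draw one dataset; deterministic given ``(config.seed, dataset_index)``."""
    rng = np.random.default_rng([config.seed, dataset_index])
    n_per, m = config.n_cells_per_condition, config.n_markers
    n = 2 * n_per

    chol = np.linalg.cholesky(config.correlation_matrix())
    truth = config.base_mean + config.base_sd * (rng.standard_normal((n, m)) @ chol.T)
    labels = np.array([CONTROL] * n_per + [TREATED] * n_per, dtype=object)
    signif = np.sort(rng.choice(m, size=config.n_signif_markers, replace=False))
    truth[n_per:, signif] += config.effect_size

    size = rng.lognormal(config.size_logmean, config.size_logsd, n)
    log_size = np.log(size)
    # centered (not standardized) so artefact strength scales with size spread
    s = log_size - log_size.mean()

    a = rng.uniform(*config.linear_coef_range, m)
    b = rng.uniform(*config.quad_coef_range, m)
    observed = truth + np.outer(s, a) + np.outer(s**2, b)

    sucs = np.empty((n, 4))
    for k in range(4):
        sucs[:, k] = (
            _SUC_INTERCEPTS[k]
            + _SUC_SLOPES[k] * s
            + rng.normal(0.0, config.suc_noise_sd, n)
        )

    return SimTruth(
        ground_truth=truth,
        observed=observed,
        condition_labels=labels,
        cell_size=size,
        size_score=s,
        artefact_coefs=np.column_stack([a, b]),
        signif_marker_ids=frozenset(int(i) for i in signif),
        suc_channels=sucs,
        marker_names=[f"m{i}" for i in range(m)],
    )


def to_event_table(sim: SimTruth, which: str = "observed") -> EventTable:
    """Pack a simulated dataset (markers + proxy channels) as an EventTable."""
    matrix = {"observed": sim.observed, "ground_truth": sim.ground_truth}[which]
    values = np.column_stack([matrix, sim.suc_channels])
    names = list(sim.marker_names) + list(SUC_PROXY_NAMES)
    return EventTable(values, names, sim.condition_labels, transform_state=ASINH)


def detect_significant_markers(
    table: EventTable,
    markers: list[str] | None = None,
    alpha: float = 0.05,
    min_effect: float = 0.2,
) -> set:
    """Markers differing between the two conditions.

    A marker is flagged when its Benjamini–Hochberg-adjusted Wilcoxon
    rank-sum p-value is below ``alpha`` and the absolute difference of
    condition means (asinh scale) is at least ``min_effect``.
    """
    conditions = table.samples()
    if len(conditions) != 2:
        raise DataError(
            f"detect_significant_markers needs exactly 2 conditions, got {len(conditions)}"
        )
    markers = list(markers) if markers is not None else list(table.channel_names)
    table.require_channels(markers)
    mask = table.sample_labels == conditions[0]
    pvals, effects = [], []
    for marker in markers:
        y = table.channel(marker)
        pvals.append(mannwhitneyu(y[mask], y[~mask], alternative="two-sided").pvalue)
        effects.append(abs(y[mask].mean() - y[~mask].mean()))
    if alpha <= 0:
        return set()
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return {
        m for m, r, e in zip(markers, reject, effects) if r and e >= min_effect
    }


def precision_recall(found: set, truth: set) -> tuple[float, float]:
    """Precision and recall of a detected set; empty ``found`` scores (1, 0)."""
    if not truth:
        raise ConfigurationError("precision_recall: truth set is empty")
    found, truth = set(found), set(truth)
    tp = len(found & truth)
    precision = 1.0 if not found else tp / len(found)
    return precision, tp / len(truth)


def _corr_rmse(x: np.ndarray, y: np.ndarray) -> float:
    """RMS difference of the upper-triangle marker correlation matrices."""
    cx = np.corrcoef(x, rowvar=False)
    cy = np.corrcoef(y, rowvar=False)
    iu = np.triu_indices_from(cx, k=1)
    return float(np.sqrt(np.mean((cx[iu] - cy[iu]) ** 2)))


def correct_simulated(sim: SimTruth, spec: ModelSpec) -> np.ndarray:
    """Regress artefacts out of the observed matrix using the proxy channels."""
    sucs = SucMatrix(
        sim.suc_channels - sim.suc_channels.mean(axis=0)
        if spec.centering == "global"
        else sim.suc_channels,
        list(SUC_PROXY_NAMES),
        "global" if spec.centering == "global" else "none",
        sim.condition_labels,
    )
    if spec.centering == "per_sample":
        values = sucs.values.copy()
        for lab in dict.fromkeys(sim.condition_labels):
            m = sim.condition_labels == lab
            values[m] -= values[m].mean(axis=0)
        sucs = SucMatrix(values, sucs.suc_names, "per_sample", sim.condition_labels)

    if spec.predictors == "pcs":
        pca = pca_sucs(sucs, z_per_sample=(spec.centering == "per_sample"))
        n_pcs = sucs.values.shape[1] if spec.n_pcs is None else spec.n_pcs
        X = pca.scores[:, :n_pcs]
        names = [f"PC{i + 1}" for i in range(n_pcs)]
    else:
        X = sucs.values
        names = list(SUC_PROXY_NAMES)

    corrected = np.empty_like(sim.observed)
    for j in range(sim.observed.shape[1]):
        fit = fit_marker(
            sim.observed[:, j], X, sim.condition_labels, spec,
            marker_name=sim.marker_names[j], predictor_names=names,
        )
        corrected[:, j] = correct_marker(fit, spec)
    return corrected


def run_validation(
    config: SimConfig,
    spec: ModelSpec | None = None,
    alpha: float = 0.05,
    min_effect: float = 0.2,
) -> pd.DataFrame:
    """Corrupt -> correct -> re-detect for each simulated dataset.

    Returns one row per dataset with precision/recall of marker
    detection on observed and corrected data and the RMS error of the
    marker correlation matrix relative to ground truth before and after
    correction.
    """
    if spec is None:
        spec = ModelSpec(form="simple", predictors="pcs", n_pcs=4, centering="global")
    rows = []
    for k in range(config.n_datasets):
        sim = simulate_dataset(config, k)
        corrected = correct_simulated(sim, spec)
        truth_ids = {sim.marker_names[i] for i in sim.signif_marker_ids}

        def detect(matrix: np.ndarray) -> set:
            tab = EventTable(
                matrix, sim.marker_names, sim.condition_labels, transform_state=ASINH
            )
            return detect_significant_markers(tab, alpha=alpha, min_effect=min_effect)

        p_obs, r_obs = precision_recall(detect(sim.observed), truth_ids)
        p_cor, r_cor = precision_recall(detect(corrected), truth_ids)
        rows.append(
            {
                "dataset": k,
                "precision": p_cor,
                "recall": r_cor,
                "precision_observed": p_obs,
                "recall_observed": r_obs,
                "corr_rmse_before": _corr_rmse(sim.ground_truth, sim.observed),
                "corr_rmse_after": _corr_rmse(sim.ground_truth, corrected),
            }
        )
    return pd.DataFrame(rows)
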