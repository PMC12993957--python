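"""Per-stratum linear-scale PCA, artifact-component removal, density filtering.

PCA runs on mean-centered but UNscaled, UNlogged normalized expression, so
pairwise distances are preserved; components correlated with mitochondrial or
artifact expression (|Pearson r| > 0.3) are dropped; a k-nearest-neighbor
density filter removes the sparsest 10% of cells in the first three PCs, and
PCA is refit on the survivors before any polytope fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .atlas_io_qc import Stratum

logger = logging.getLogger(__name__)


@dataclass
class PCSpace:
    """PCA representation of one stratum.

    ``scores`` has one column per retained component (retained order is the
    original component order); ``dropped_components`` records (component
    index, signal name, r) for components removed by the correlation filter.
    """

    loadings: np.ndarray             # genes x retained components
    scores: np.ndarray               # cells x retained components
    explained_variance: np.ndarray   # retained components
    retained_components: list
    dropped_components: list = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.scores.shape[1]


def pca_linear(X: np.ndarray, n_components: int = 10) -> PCSpace:
    """PCA of mean-centered, unscaled, unlogged expression.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive. Rank-deficient input yields fewer components with a
    warning rather than an error.
    """
    X = np.asarray(X, float)
    n, g = X.shape
    max_rank = min(n - 1, g)
    if n_components > max_rank:
        logger.warning("pca_linear: reducing n_components %d -> %d", n_components, max_rank)
        n_components = max_rank
    # randomized solver for large strata; seeded, so fully deterministic
    solver = "randomized" if min(n, g) > 150 and n_components <= min(n, g) // 3 else "full"
    pca = PCA(n_components=n_components, svd_solver=solver, random_state=0)
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()  # genes x comps
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    # drop numerically-null components of rank-deficient data
    keep = pca.explained_variance_ > max(1e-12, 1e-12 * pca.explained_variance_[0])
    if not keep.all():
        logger.warning("pca_linear: %d numerically-null components dropped", (~keep).sum())
    return PCSpace(
        loadings=loadings[:, keep],
        scores=scores[:, keep],
        explained_variance=pca.explained_variance_[keep],
        retained_components=list(np.flatnonzero(keep)),
    )


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0  # constant signal carries no correlation
    return float(pearsonr(x, y)[0])


def drop_correlated_components(
    pc: PCSpace,
    pct_mito: np.ndarray,
    pct_artifact: np.ndarray,
    r_threshold: float = 0.3,
) -> PCSpace:
    """Retain components with |Pearson r| <= threshold against BOTH QC signals.

    The inequality is strict per the stringent-threshold convention: a
    component at exactly |r| = 0.3 is retained.
    """
    keep, dropped = [], []
    for j, comp in enumerate(pc.retained_components):
        r_mito = _safe_pearson(pc.scores[:, j], np.asarray(pct_mito, float))
        r_art = _safe_pearson(pc.scores[:, j], np.asarray(pct_artifact, float))
        offenders = [("mito", r_mito), ("artifact", r_art)]
        worst = max(offenders, key=lambda s: abs(s[1]))
        if abs(worst[1]) > r_threshold:
            dropped.append((comp, worst[0], worst[1]))
        else:
            keep.append(j)
    if dropped:
        logger.info("drop_correlated_components: dropped %s", dropped)
    return PCSpace(
        loadings=pc.loadings[:, keep],
        scores=pc.scores[:, keep],
        explained_variance=pc.explained_variance[keep],
        retained_components=[pc.retained_components[j] for j in keep],
        dropped_components=pc.dropped_components + dropped,
    )


def knn_density(points: np.ndarray, k: int | None = None) -> np.ndarray:
    """k-NN density: 1 / distance to the ceil(sqrt(n))-th neighbor by default."""
    n = points.shape[0]
    if k is None:
        k = int(np.ceil(np.sqrt(n)))
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(points)
    dist, _ = nn.kneighbors(points)
    d_k = dist[:, -1]
    return 1.0 / np.maximum(d_k, 1e-300)


def density_filter(
    scores: np.ndarray,
    n_components_for_density: int = 3,
    drop_fraction: float = 0.10,
) -> np.ndarray:
    """Keep-mask removing exactly floor(drop_fraction * n) lowest-density cells.

    Density is estimated in the first ``n_components_for_density`` columns
    (all columns if fewer are available); ties are broken by cell index.
    """
    n = scores.shape[0]
    n_drop = int(np.floor(drop_fraction * n))
    keep = np.ones(n, dtype=bool)
    if n_drop == 0:
        return keep
    sub = scores[:, : min(n_components_for_density, scores.shape[1])]
    density = knn_density(sub)
    order = np.lexsort((np.arange(n), density))  # ascending density, ties by index
    keep[order[:n_drop]] = False
    return keep


@dataclass
class StratumGeometry:
    """Final fit-space geometry of one stratum."""

    pc: PCSpace
    keep_mask: np.ndarray    # over the stratum's cells (density filter)
    skipped_reason: str | None = None


def compute_stratum_geometry(
    stratum: Stratum,
    n_components: int = 10,
    r_threshold: float = 0.3,
    drop_fraction: float = 0.10,
) -> StratumGeometry:
    """Full geometry pass for one stratum.

    Order: initial PCA -> density filter on the first 3 computed PCs ->
    PCA refit on surviving cells -> correlation-based component drop. The
    stratum's raw matrix is never modified; only scores change. A stratum
    whose components are all dropped is flagged skipped.
    """
    pc0 = pca_linear(stratum.X, n_components)
    keep = density_filter(pc0.scores, drop_fraction=drop_fraction)
    pc1 = pca_linear(stratum.X[keep], n_components)
    pc2 = drop_correlated_components(
        pc1, stratum.pct_mito[keep], stratum.pct_artifact[keep], r_threshold
    )
    reason = None
    if pc2.n_retained < 2:
        reason = f"only {pc2.n_retained} retained components after correlation filter"
        logger.warning("stratum %s skipped: %s", stratum.stratum_id, reason)
    return StratumGeometry(pc=pc2, keep_mask=keep, skipped_reason=reason)
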