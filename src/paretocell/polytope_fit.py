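"""Simplex fitting, t-ratio shuffle testing, dimension sweep and bootstrap.

The fitting engine is archetypal-analysis alternating optimization: per-cell
convex weights are obtained by simplex-projected gradient steps, vertices by
ridge-stabilized least squares, initialized from extreme data points
(furthest-point selection) with restarts. A closed-form outward expansion
about the simplex centroid then scales the fitted vertices until at least 99%
of cells lie inside, honoring the convention of maximal polytopes that lie
within the data.

Significance compares the goodness of fit of observed and column-shuffled PC
scores (the PCs are shuffled, not the genes). Goodness is measured through
the t-ratio geometry — data hull volume versus fitted simplex volume in the
first k-1 principal components — using the within-data fit's fill fraction
(simplex volume / hull volume, the reciprocal of its t-ratio) as the test
statistic, since it does not depend on the most extreme cells. Values near 1
indicate simplex-like data. The p-value uses the add-one permutation
convention. For k = 2 the statistic is the fraction of total variance lying
along the fitted segment direction (shuffling one column alone is a no-op).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import ConvexHull, QhullError

from ._kernels import _aa_fit, _furthest_point_indices

logger = logging.getLogger(__name__)

INSIDE_TOL = 1e-9
EXPANSION_COVERAGE = 0.99


@dataclass
class FitResult:
    """One fitted simplex: expanded vertices plus the raw AA solution."""

    vertices: np.ndarray       # k x d, after outward expansion
    vertices_raw: np.ndarray   # k x d, the archetypal-analysis optimum
    weights: np.ndarray        # n x k convex weights of the AA solution
    sse: float
    sst: float

    @property
    def explained_variance(self) -> float:
        return 1.0 - self.sse / self.sst if self.sst > 0 else 0.0


@dataclass
class SimplexFit:
    """Full per-stratum fit record from the dimension sweep."""

    stratum_id: str
    dimension: int
    n_vertices: int
    vertices: np.ndarray
    ev_curve: dict
    t_ratio: float                # hull/simplex of the final expanded fit (k>=3)
    statistic: float              # shuffle-test statistic (fill fraction / line stat)
    p_value: float
    n_shuffles: int
    significant: bool
    all_p_values: list            # (dimension, k, p) for every dimension tested
    pct_inside: float = float("nan")
    bootstrap: list | None = None  # per-vertex (mean, covariance)


def _affine_coords(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Barycentric-style affine coordinates (rows sum to 1), least squares.

    Exact barycentric coordinates when k = d + 1; otherwise coordinates of
    the orthogonal projection onto the simplex's affine hull.
    """
    k, d = vertices.shape
    M = np.vstack([vertices.T, np.ones(k)])          # (d+1) x k
    Y = np.vstack([points.T, np.ones(points.shape[0])])
    if k == d + 1:
        return np.linalg.solve(M, Y).T
    return np.linalg.lstsq(M, Y, rcond=None)[0].T


def _expand_vertices(points: np.ndarray, vertices: np.ndarray,
                     coverage: float = EXPANSION_COVERAGE) -> np.ndarray:
    """Scale vertices outward about their centroid until ``coverage`` of cells
    lie inside. Closed form: with centroid c and affine coordinates
    b = 1/k + delta, a point is inside the gamma-scaled simplex iff
    gamma >= -k * min(delta)."""
    k = vertices.shape[0]
    delta = _affine_coords(points, vertices) - 1.0 / k
    gamma_needed = np.maximum(1.0, -k * delta.min(axis=1))
    g = np.sort(gamma_needed)
    idx = min(int(np.ceil(coverage * len(g))), len(g)) - 1
    gamma = g[max(idx, 0)]
    centroid = vertices.mean(axis=0)
    return centroid + gamma * (vertices - centroid)


def _hull_basis(X: np.ndarray) -> np.ndarray:
    """Indices of X's convex-hull vertices (sorted), or all indices when the
    hull is unavailable (tiny n, 1-D, or degenerate geometry)."""
    n, d = X.shape
    if n <= 50 or d < 2:
        return np.arange(n)
    try:
        return np.sort(np.unique(ConvexHull(X).vertices))
    except QhullError:
        return np.arange(n)


def _nearest_distinct_indices(X: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Index of the nearest data point to each target row, all distinct."""
    taken: set[int] = set()
    idx = np.empty(targets.shape[0], np.int64)
    for j, t in enumerate(targets):
        order = np.argsort(((X - t) ** 2).sum(axis=1), kind="stable")
        for i in order:
            if int(i) not in taken:
                taken.add(int(i))
                idx[j] = i
                break
    return idx


def fit_simplex(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    expand: bool = True,
    coverage: float = EXPANSION_COVERAGE,
    w_iters: int = 8,
    b_iters: int = 8,
    max_outer: int = 40,
    tol: float = 1e-6,
    init_vertices: np.ndarray | None = None,
    basis_indices: np.ndarray | None = None,
) -> FitResult:
    """Fit a k-vertex simplex minimizing sum_i ||x_i - V w_i||^2, w_i convex.

    Vertices are constrained to convex combinations of data points
    (principal-convex-hull form), keeping the raw polytope within the data;
    the expansion step then scales it outward. Since conv(X) equals the
    convex hull of X's hull vertices, the vertex factor is restricted to the
    hull vertices — a lossless support reduction that dominates the
    runtime. Restarts vary the furthest-point-selection anchor; the best
    (lowest-SSE) solution wins. Deterministic given the seed.
    ``init_vertices`` adds a warm-start candidate (used by the
    explained-variance curve), snapped to the nearest distinct basis points;
    ``basis_indices`` lets a caller reuse a precomputed hull.
    """
    X = np.ascontiguousarray(points, float)
    n, d = X.shape
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    if k > d + 1:
        raise ValueError(f"k={k} vertices require at least {k - 1} dimensions, got {d}")
    centered = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-10 * max(1.0, np.abs(centered).max()))
    if rank < k - 1:
        raise ValueError(f"degenerate input: rank {rank} < k-1 = {k - 1}")
    sst = float((centered**2).sum())

    if basis_indices is None:
        basis_indices = _hull_basis(X)
    if len(basis_indices) < k:
        basis_indices = np.arange(n)
    Xb = np.ascontiguousarray(X[basis_indices])
    m = Xb.shape[0]
    rng = np.random.default_rng(seed)
    dists = (centered[basis_indices] ** 2).sum(axis=1)
    anchors = [int(np.argmax(dists))]
    if n_restarts > 1:
        anchors += [int(a) for a in rng.integers(0, m, size=n_restarts - 1)]
    inits = [_furthest_point_indices(Xb, k, a) for a in anchors]
    if init_vertices is not None:
        inits.append(_nearest_distinct_indices(Xb, np.asarray(init_vertices, float)))
    best = None
    for idx in inits:
        V, W, sse = _aa_fit(X, Xb, idx, k, w_iters, b_iters, max_outer, tol)
        if best is None or sse < best[2]:
            best = (V, W, sse)
    V, W, sse = best
    V_out = _expand_vertices(X, V, coverage) if expand else V.copy()
    return FitResult(vertices=V_out, vertices_raw=V, weights=W, sse=float(sse), sst=sst)


def estimate_archetypes(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    smooth_neighbors: int = 5,
    bin_fraction: float = 0.05,
    **fit_kwargs,
) -> np.ndarray:
    """Denoised archetype position estimate (k x d).

    The convex mixture model is preserved exactly under k-NN smoothing (a
    smoothed cell equals the smoothed weights times the same vertices, with
    noise averaged down by sqrt(m)), so the simplex is fitted on smoothed
    points and each vertex is then re-estimated by extrapolating through the
    mean fitted weights of its top-weight cell bin: solve Wbar V = Xbar.
    This removes most of the outward selection bias a raw fit inherits from
    extreme noisy cells.
    """
    from sklearn.neighbors import NearestNeighbors

    X = np.asarray(points, float)
    n = X.shape[0]
    m = min(smooth_neighbors, n - 1)
    if m >= 2:
        _, idx = NearestNeighbors(n_neighbors=m).fit(X).kneighbors(X)
        Xs = X[idx].mean(axis=1)
    else:
        Xs = X
    fit = fit_simplex(Xs, k, seed=seed, n_restarts=n_restarts, expand=False, **fit_kwargs)
    W = fit.weights
    m_bin = min(max(5, int(round(bin_fraction * n))), n)
    Wbar = np.empty((k, k))
    Xbar = np.empty((k, X.shape[1]))
    for j in range(k):
        top = np.argsort(-W[:, j], kind="stable")[:m_bin]
        Wbar[j] = W[top].mean(axis=0)
        Xbar[j] = Xs[top].mean(axis=0)
    try:
        return np.linalg.solve(Wbar + 1e-9 * np.eye(k), Xbar)
    except np.linalg.LinAlgError:
        logger.warning("estimate_archetypes: singular bin-weight matrix; returning raw fit")
        return fit.vertices_raw


def explained_variance_curve(
    points: np.ndarray,
    k_range=None,
    seed: int = 0,
    n_restarts: int = 3,
) -> dict:
    """EV(k) = 1 - SSE(k)/SST over ``k_range`` (default 2..d+1).

    Each k+1 fit is warm-started from the k solution plus the
    worst-residual data point, which makes the curve non-decreasing up to
    optimizer noise (enforced by a final running maximum).
    """
    X = np.asarray(points, float)
    d = X.shape[1]
    if k_range is None:
        k_range = range(2, d + 2)
    curve: dict[int, float] = {}
    prev_fit: FitResult | None = None
    best_ev = 0.0
    for k in k_range:
        init = None
        if prev_fit is not None and prev_fit.vertices_raw.shape[0] == k - 1:
            resid = ((X - prev_fit.weights @ prev_fit.vertices_raw) ** 2).sum(axis=1)
            init = np.vstack([prev_fit.vertices_raw, X[np.argmax(resid)]])
        fit = fit_simplex(
            X, k, seed=seed + k, n_restarts=n_restarts, expand=False, init_vertices=init
        )
        best_ev = max(best_ev, fit.explained_variance)
        curve[k] = best_ev
        prev_fit = fit
    return curve


def find_elbow(ev_curve: dict) -> int:
    """Elbow of the EV curve: k maximizing perpendicular distance to the
    endpoint chord in the (k, EV) plane; ties and flat curves go to smaller k."""
    ks = sorted(ev_curve)
    if len(ks) < 3:
        raise ValueError("elbow selection needs at least 3 curve points")
    p0 = np.array([ks[0], ev_curve[ks[0]]])
    p1 = np.array([ks[-1], ev_curve[ks[-1]]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    best_k, best_d = ks[0], -1.0
    for k in ks[1:-1]:
        v = np.array([k, ev_curve[k]]) - p0
        dist = abs(v[0] * chord[1] - v[1] * chord[0]) / norm if norm > 0 else 0.0
        if dist > best_d + 1e-12:
            best_d, best_k = dist, k
    if best_d <= 1e-9:
        logger.warning("find_elbow: curve is linear; returning smallest k")
        return ks[0]
    return best_k


# ---------------------------------------------------------------------------
# volumes and the t-ratio
# ---------------------------------------------------------------------------


def hull_volume(points: np.ndarray) -> float:
    """Exact convex-hull volume (area in 2-D) via Qhull facet enumeration."""
    points = np.asarray(points, float)
    n, m = points.shape
    if n < m + 1:
        raise ValueError("need at least m+1 points for an m-dimensional hull")
    try:
        return float(ConvexHull(points).volume)
    except QhullError as e:
        rank = np.linalg.matrix_rank(points - points.mean(axis=0))
        raise ValueError(f"degenerate point set (affine rank {rank} in {m}-D)") from e


def simplex_volume(vertices: np.ndarray) -> float:
    """Volume |det(v_1-v_0, ..., v_{k-1}-v_0)| / (k-1)! of k vertices in k-1 dims."""
    vertices = np.asarray(vertices, float)
    k = vertices.shape[0]
    if vertices.shape[1] != k - 1:
        raise ValueError("simplex_volume expects k vertices in k-1 dimensions")
    edges = vertices[1:] - vertices[0]
    return abs(float(np.linalg.det(edges))) / math.factorial(k - 1)


def t_ratio(points: np.ndarray, vertices: np.ndarray) -> float:
    """Hull volume over simplex volume, both projected to the first k-1 columns.

    Near 1 for simplex-like data enclosed by the fitted simplex (the enclosing
    convention makes the ratio <= 1 + epsilon).
    """
    k = vertices.shape[0]
    if k < 3:
        raise ValueError("t_ratio requires k >= 3; use line_statistic for k = 2")
    P = np.asarray(points, float)[:, : k - 1]
    V = np.asarray(vertices, float)[:, : k - 1]
    sv = simplex_volume(V)
    if sv <= 0:
        return float("inf")
    return hull_volume(P) / sv


def line_statistic(points: np.ndarray, vertices: np.ndarray) -> float:
    """k=2 surrogate: fraction of total variance along the fitted segment."""
    u = vertices[1] - vertices[0]
    nu = np.linalg.norm(u)
    if nu == 0:
        return 0.0
    u = u / nu
    centered = points - points.mean(axis=0)
    total = (centered**2).sum()
    if total == 0:
        return 0.0
    along = ((centered @ u) ** 2).sum()
    return float(along / total)


#: reduced optimization budget used inside the shuffle test (identically for
#: the observed and every shuffled refit, preserving procedural symmetry)
SHUFFLE_FIT_BUDGET = dict(w_iters=3, b_iters=3, max_outer=8, tol=1e-5)


def _fit_statistic(
    points: np.ndarray, k: int, seed: int, n_restarts: int, budget: dict
) -> tuple:
    """Goodness-of-fit statistic for the shuffle test; larger = more simplex-like.

    For k >= 3: the fill fraction simplex_volume / hull_volume of the raw
    within-data fit (the reciprocal of the t-ratio of that fit), which is far
    more stable than statistics based on the expanded polytope because it does
    not depend on the most extreme 1% of cells. For k = 2: the variance
    fraction along the fitted segment.
    """
    hull = None
    basis = None
    if k >= 3 and points.shape[1] == k - 1:
        # fitting space == statistic space: one hull serves both the
        # vertex-factor basis and the volume denominator
        try:
            hull = ConvexHull(points)
            basis = np.sort(np.unique(hull.vertices))
        except QhullError:
            pass
    fit = fit_simplex(
        points, k, seed=seed, n_restarts=n_restarts, expand=False,
        basis_indices=basis, **budget,
    )
    if k == 2:
        stat = line_statistic(points, fit.vertices_raw)
    else:
        P = points[:, : k - 1]
        V = fit.vertices_raw[:, : k - 1]
        hv = hull.volume if hull is not None else hull_volume(P)
        stat = simplex_volume(V) / hv if hv > 0 else 0.0
    return stat, fit


@dataclass
class ShuffleTestResult:
    p_value: float
    t_observed: float
    t_shuffled: np.ndarray
    fit: FitResult
    n_shuffles: int


def shuffle_test(
    points: np.ndarray,
    k: int,
    n_shuffles: int = 1000,
    seed: int = 0,
    n_restarts: int = 1,
) -> ShuffleTestResult:
    """Permutation test of simplex-likeness against column-shuffled PC scores.

    Every shuffle independently permutes each PC column across cells, refits
    the simplex and recomputes the statistic; larger statistics mean better
    fits, and p = (1 + #{shuffled >= observed}) / (1 + n_shuffles). The same
    restart count and reduced optimization budget are used for the observed
    and every shuffled refit so the procedure is exchangeable under the null
    (empirically verified: asymmetric budgets skew the null p distribution).
    """
    if n_shuffles <= 0:
        raise ValueError("n_shuffles must be positive")
    X = np.asarray(points, float)
    n, d = X.shape
    rng = np.random.default_rng(seed)
    budget = SHUFFLE_FIT_BUDGET
    t_obs, fit = _fit_statistic(X, k, int(rng.integers(2**31)), n_restarts, budget)
    t_shuf = np.empty(n_shuffles)
    Xs = np.empty_like(X)
    for s in range(n_shuffles):
        for j in range(d):
            Xs[:, j] = X[rng.permutation(n), j]
        t_shuf[s], _ = _fit_statistic(
            Xs, k, int(rng.integers(2**31)), n_restarts, budget
        )
    count = int((t_shuf >= t_obs - 1e-12).sum())
    p = (1 + count) / (1 + n_shuffles)
    return ShuffleTestResult(
        p_value=p, t_observed=t_obs, t_shuffled=t_shuf, fit=fit, n_shuffles=n_shuffles
    )


def percent_inside(points: np.ndarray, vertices: np.ndarray) -> float:
    """Fraction of points with all barycentric coordinates >= -1e-9.

    Requires k vertices in k-1 dimensions (a full simplex); boundary points
    count as inside.
    """
    vertices = np.asarray(vertices, float)
    points = np.asarray(points, float)
    k, d = vertices.shape
    if d != k - 1:
        raise ValueError("percent_inside expects k vertices in k-1 dimensions")
    if simplex_volume(vertices) <= 0:
        raise ValueError("degenerate simplex")
    bary = _affine_coords(points, vertices)
    return float((bary >= -INSIDE_TOL).all(axis=1).mean())


def sweep_dimensions(
    scores: np.ndarray,
    stratum_id: str = "",
    dims=(5, 4, 3, 2),
    alpha: float = 0.05,
    n_shuffles: int = 1000,
    seed: int = 0,
    n_restarts_test: int = 1,
    n_restarts_final: int = 10,
) -> SimplexFit:
    """Sweep PC dimensions high to low, stopping at the first significant fit.

    For each dimension d: take the first d retained PCs, build the EV curve
    over k = 2..d+1, pick k* by elbow, and run the shuffle test at k*. The
    test fits the simplex in the first k*-1 PCs where it is full-dimensional
    (a d-PC sweep step yields an up-to-(d+1)-vertex simplex; testing a
    k-vertex simplex inside a higher-dimensional fitting space dilutes the
    statistic with pure-noise components). For k* = 2 the segment is fitted
    in all d PCs and tested with the variance-fraction statistic. All
    computed p-values are recorded for cell-type aggregation regardless of
    where the sweep stops. If nothing is significant the highest-dimension
    fit is returned flagged non-significant.
    """
    scores = np.asarray(scores, float)
    n_retained = scores.shape[1]
    if n_retained < 2:
        raise ValueError("sweep_dimensions requires at least 2 retained components")
    seen, use_dims = set(), []
    for d in dims:
        d_eff = min(d, n_retained)
        if d_eff >= 2 and d_eff not in seen:
            seen.add(d_eff)
            use_dims.append(d_eff)
    rng = np.random.default_rng(seed)
    all_p, first_record = [], None
    for d in use_dims:
        Xd = scores[:, :d]
        ev = explained_variance_curve(Xd, range(2, d + 2), seed=int(rng.integers(2**31)))
        if len(ev) < 3:
            # d = 2 yields only k = 2, 3; anchor the chord at the trivial
            # one-vertex fit (EV(1) = 0 by definition) for elbow selection
            k_star = find_elbow({1: 0.0, **ev})
            k_star = max(k_star, 2)
        else:
            k_star = find_elbow(ev)
        Xt = Xd if k_star == 2 else scores[:, : k_star - 1]
        res = shuffle_test(
            Xt, k_star, n_shuffles=n_shuffles, seed=int(rng.integers(2**31)),
            n_restarts=n_restarts_test,
        )
        all_p.append((d, k_star, res.p_value))
        record = (Xt.shape[1], k_star, ev, res, Xt)
        if first_record is None:
            first_record = record
        if res.p_value < alpha:
            return _build_fit(
                stratum_id, record, all_p, alpha, n_shuffles, seed, n_restarts_final
            )
    return _build_fit(
        stratum_id, first_record, all_p, alpha, n_shuffles, seed, n_restarts_final
    )


def _build_fit(stratum_id, record, all_p, alpha, n_shuffles, seed, n_restarts) -> SimplexFit:
    d, k, ev, res, Xd = record
    # the reported vertices are the denoised archetype estimate from a
    # full-budget refit; the test statistic and p-value stay those of the
    # (budget-symmetric) shuffle test. pct_inside describes the expanded
    # (maximal-within-data) polytope of that refit.
    verts = estimate_archetypes(Xd, k, seed=seed + 7, n_restarts=n_restarts)
    expanded = fit_simplex(Xd, k, seed=seed + 7, n_restarts=n_restarts).vertices
    if k >= 3:
        try:
            pct = percent_inside(Xd[:, : k - 1], expanded[:, : k - 1])
        except ValueError:
            pct = float("nan")
    else:
        # a segment has zero 2-D measure; report coverage along its direction
        bary = _affine_coords(Xd, expanded)
        pct = float((bary >= -INSIDE_TOL).all(axis=1).mean())
    if k >= 3:
        try:
            tr = t_ratio(Xd, expanded)
        except ValueError:
            tr = float("nan")
    else:
        tr = float("nan")
    return SimplexFit(
        stratum_id=stratum_id,
        dimension=d,
        n_vertices=k,
        vertices=verts,
        ev_curve=ev,
        t_ratio=tr,
        statistic=res.t_observed,
        p_value=res.p_value,
        n_shuffles=n_shuffles,
        significant=res.p_value < alpha,
        all_p_values=all_p,
        pct_inside=pct,
    )


def bootstrap_vertices(
    points: np.ndarray,
    k: int,
    n_boot: int = 100,
    seed: int = 0,
    reference: np.ndarray | None = None,
    n_restarts: int = 3,
) -> tuple[list, int]:
    """Bootstrap vertex confidence regions.

    Resamples cells with replacement, refits, matches replicate vertices to
    the reference via minimum-total-distance (Hungarian) assignment, and
    returns per-vertex (mean, covariance) plus the count of discarded
    rank-degenerate replicates.
    """
    X = np.asarray(points, float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = fit_simplex(X, k, seed=int(rng.integers(2**31))).vertices
    samples: list[list[np.ndarray]] = [[] for _ in range(k)]
    discarded = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            fit = fit_simplex(
                X[idx], k, seed=int(rng.integers(2**31)), n_restarts=n_restarts
            )
        except ValueError:
            discarded += 1
            continue
        cost = np.linalg.norm(reference[:, None, :] - fit.vertices[None, :, :], axis=2)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            samples[r].append(fit.vertices[c])
    out = []
    for vs in samples:
        arr = np.asarray(vs)
        mean = arr.mean(axis=0)
        cov = np.cov(arr.T) if len(arr) > 1 else np.zeros((X.shape[1], X.shape[1]))
        out.append((mean, np.atleast_2d(cov)))
    return out, discarded
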