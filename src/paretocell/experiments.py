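"""Validation experiments on synthetic data with planted ground truth.

Each driver generates its own data from a seed, runs the relevant pipeline
stages, and returns summary statistics: shuffle-test calibration on null
strata, planted-simplex power and vertex recovery, enrichment FDR and
sensitivity, alignment recovery, and end-to-end cell-type discrimination.
They are used by the numbered analysis scripts, the acceptance script and
the acceptance test suite alike.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import kstest

from .atlas_io_qc import TARGET_SUM, run_qc, stratify
from .polytope_fit import estimate_archetypes, shuffle_test, sweep_dimensions
from .significance_aggregation import aggregate_cell_types
from .stratum_geometry import compute_stratum_geometry, pca_linear
from .synthetic_atlas import (
    generate_atlas,
    generate_null_stratum,
    generate_simplex_cloud,
    generate_stratum,
    random_archetype_spec,
)

logger = logging.getLogger(__name__)


def _null_scores(n_cells: int, n_genes: int, seed: int, n_components: int = 10) -> np.ndarray:
    """PC scores of a null stratum, straight from the counts.

    The calibration target is the permutation test itself, whose null
    premise is independent PC columns; the generator's genes are independent
    by construction, so PCA of the raw counts is the cleanest realization of
    that null. The preprocessing steps deliberately left out here each add
    mild cross-PC dependence that is a property of the data pipeline, not of
    the test — normalization couples genes compositionally, and the density
    filter trims joint outliers that column shuffling then re-creates,
    making the test measurably conservative (never anticonservative).
    End-to-end null behavior with the full preprocessing chain is exercised
    by the discrimination experiment."""
    counts = generate_null_stratum(n_cells, n_genes, seed=seed)
    X = np.asarray(counts.todense(), float)
    X = X[X.sum(axis=1) > 0]
    return pca_linear(X, n_components).scores


def shuffle_calibration(
    n_strata: int = 200,
    n_cells: int = 500,
    n_genes: int = 300,
    n_shuffles: int = 200,
    seed: int = 0,
    test_dim: int = 3,
) -> dict:
    """Null calibration of the shuffle test.

    Each stratum has independent log-normal-rate Poisson genes; the test uses
    the first ``test_dim`` PCs with elbow-selected vertex count, one test per
    stratum. Returns the rejection rate at alpha = 0.05 and the KS p-value
    against uniformity.
    """
    rng = np.random.default_rng(seed)
    p_values = []
    for i in range(n_strata):
        scores = _null_scores(n_cells, n_genes, seed=int(rng.integers(2**31)))
        fit = sweep_dimensions(
            scores[:, :test_dim],
            stratum_id=f"null{i}",
            dims=(test_dim,),
            n_shuffles=n_shuffles,
            seed=int(rng.integers(2**31)),
        )
        p_values.append(fit.p_value)
    p_values = np.asarray(p_values)
    return {
        "p_values": p_values,
        "rejection_rate": float((p_values < 0.05).mean()),
        "ks_uniformity_p": float(kstest(p_values, "uniform").pvalue),
        "n_strata": n_strata,
    }


def matched_vertex_error(true_vertices: np.ndarray, estimated: np.ndarray) -> float:
    """Mean Hungarian-matched vertex distance as a fraction of simplex diameter."""
    cost = np.linalg.norm(true_vertices[:, None] - estimated[None], axis=2)
    rows, cols = linear_sum_assignment(cost)
    diam = max(
        np.linalg.norm(a - b) for i, a in enumerate(true_vertices) for b in true_vertices[i + 1:]
    )
    return float(cost[rows, cols].mean() / diam)


def simplex_recovery(
    n_strata: int = 50,
    n_points: int = 1000,
    noise_edge_fraction: float = 0.05,
    n_shuffles: int = 200,
    edge: float = 4.0,
    seed: int = 0,
) -> dict:
    """Power and vertex recovery on planted triangles and tetrahedra.

    Strata alternate k = 3 (2-D) and k = 4 (3-D) regular corner simplices of
    the given edge scale, with Gaussian point noise sigma = 5% of edge by
    default. Returns the fraction reaching p <= 0.05 and the mean matched
    vertex error as a fraction of simplex diameter.
    """
    rng = np.random.default_rng(seed)
    sigma = noise_edge_fraction * edge
    hits, errors, p_values = 0, [], []
    for i in range(n_strata):
        k = 3 if i % 2 == 0 else 4
        vertices = np.vstack([np.zeros(k - 1), edge * np.eye(k - 1)])
        pts, _ = generate_simplex_cloud(
            n_points, vertices, noise_sigma=sigma, seed=int(rng.integers(2**31))
        )
        res = shuffle_test(pts, k, n_shuffles=n_shuffles, seed=int(rng.integers(2**31)))
        p_values.append(res.p_value)
        hits += res.p_value <= 0.05
        est = estimate_archetypes(pts, k, seed=int(rng.integers(2**31)))
        errors.append(matched_vertex_error(vertices, est))
    return {
        "power": hits / n_strata,
        "mean_vertex_error_frac": float(np.mean(errors)),
        "p_values": np.asarray(p_values),
        "n_strata": n_strata,
    }


def enrichment_power_fdr(
    n_reps: int = 50,
    n_cells: int = 500,
    n_genes: int = 500,
    markers_per_archetype: int = 10,
    marker_fold: float = 4.0,
    fdr_cap: float = 0.10,
    seed: int = 0,
) -> dict:
    """Marker recovery of the vertex-enrichment stage.

    Each replicate plants a k = 2 stratum with 10 markers per archetype
    (20 true markers among ``n_genes``), fits the segment in PC space, and
    calls genes at q <= ``fdr_cap`` with positive effect at either vertex.
    Returns pooled empirical FDR and per-marker sensitivity.
    """
    from .vertex_enrichment import enrich_fit, top_markers

    rng = np.random.default_rng(seed)
    n_true = n_false = detected = 0
    total_markers = 0
    for _ in range(n_reps):
        spec = random_archetype_spec(
            2,
            n_genes,
            markers_per_archetype=markers_per_archetype,
            marker_fold=marker_fold,
            seed=int(rng.integers(2**31)),
        )
        counts, truth = generate_stratum(n_cells, n_genes, spec, seed=int(rng.integers(2**31)))
        X = np.asarray(counts.todense(), float)
        X = X[X.sum(axis=1) > 0]
        Xn = X / X.sum(axis=1, keepdims=True) * TARGET_SUM
        pc = pca_linear(Xn, 3)
        vertices = estimate_archetypes(pc.scores, 2, seed=int(rng.integers(2**31)))
        gene_ids = np.arange(n_genes)
        result = enrich_fit(pc.scores, vertices, Xn, gene_ids, "rep")
        marker_set = {g for genes in spec.marker_genes for g in genes}
        called = set()
        for v in range(2):
            called |= set(top_markers(result, v, n=n_genes, fdr_cap=fdr_cap))
        n_true += len(called & marker_set)
        n_false += len(called - marker_set)
        detected += len(called & marker_set)
        total_markers += len(marker_set)
    n_calls = n_true + n_false
    return {
        "empirical_fdr": n_false / n_calls if n_calls else 0.0,
        "sensitivity": detected / total_markers,
        "n_reps": n_reps,
    }


def alignment_recovery(
    n_archetypes: int = 4,
    donors: int = 3,
    tissues: int = 2,
    noise_fraction: float = 0.0,
    seed: int = 0,
) -> dict:
    """ARI of Louvain alignment against planted archetype identity, plus
    donor coverage and consensus-gene agreement of accepted clusters."""
    from sklearn.metrics import adjusted_rand_score

    from .archetype_alignment import VertexNode, align_cell_type, build_vertex_graph, cluster_vertices
    from .synthetic_atlas import generate_marker_lists

    dicts = generate_marker_lists(
        n_archetypes,
        [f"D{i}" for i in range(donors)],
        [f"T{i}" for i in range(tissues)],
        noise_fraction=noise_fraction,
        seed=seed,
    )
    nodes = [
        VertexNode(d["stratum_id"], d["vertex_index"], d["donor"], d["tissue"], tuple(d["markers"]))
        for d in dicts
    ]
    labels = cluster_vertices(build_vertex_graph(nodes), seed=seed)
    ari = adjusted_rand_score(
        [d["archetype"] for d in dicts], [labels[n.node_id] for n in nodes]
    )
    clusters, _ = align_cell_type(nodes, "ct", donors_available=donors, seed=seed)
    accepted = [c for c in clusters if c.accepted]
    coverages = [c.donor_coverage for c in accepted]
    truth_lists = {}
    for d in dicts:
        truth_lists.setdefault(d["archetype"], frozenset(d["markers"]))
    consensus_match = sum(
        frozenset(g for g, _ in c.consensus_genes) in truth_lists.values() for c in accepted
    )
    return {
        "ari": float(ari),
        "n_accepted": len(accepted),
        "mean_donor_coverage": float(np.mean(coverages)) if coverages else 0.0,
        "n_consensus_exact": consensus_match,
    }


def make_discrimination_atlas(seed: int, n_genes: int = 300):
    """2 polytopal cell types (k = 3, 4) + 1 null across 4 donors x 2 tissues."""
    rng = np.random.default_rng(seed)
    cell_types = {
        "polytopal_k3": random_archetype_spec(3, n_genes, seed=int(rng.integers(2**31))),
        "polytopal_k4": random_archetype_spec(4, n_genes, seed=int(rng.integers(2**31))),
        "null": None,
    }
    return generate_atlas(4, 2, cell_types, seed=int(rng.integers(2**31)))


def discriminate_one_atlas(seed: int, n_shuffles: int = 200) -> dict:
    """QC -> geometry -> dimension sweep -> cell-type aggregation for one
    synthetic atlas; returns the accepted set versus planted truth.

    Enrichment/bootstrap are skipped: acceptance of cell types depends only
    on the recorded p-values.
    """
    atlas, truth = make_discrimination_atlas(seed)
    rng = np.random.default_rng(seed + 1)
    norm, _ = run_qc(atlas)
    records: dict[str, list] = {}
    for stratum in stratify(norm, seed=int(rng.integers(2**31))):
        geom = compute_stratum_geometry(stratum)
        if geom.skipped_reason:
            continue
        fit = sweep_dimensions(
            geom.pc.scores,
            stratum_id=stratum.stratum_id,
            n_shuffles=n_shuffles,
            seed=int(rng.integers(2**31)),
        )
        records.setdefault(stratum.cell_type, []).append(
            {
                "donor": stratum.donor,
                "tissue": stratum.tissue,
                "p_values": [p for _, _, p in fit.all_p_values],
            }
        )
    summary, _ = aggregate_cell_types(records)
    accepted = set(summary[summary["accepted"]]["cell_type"])
    expected = set(truth.polytopal_cell_types)
    return {
        "accepted": accepted,
        "expected": expected,
        "exact": accepted == expected,
        "summary": summary,
    }


def discrimination_experiment(n_atlases: int = 10, n_shuffles: int = 200, seed: int = 0) -> dict:
    """End-to-end discrimination over replicate atlases."""
    rng = np.random.default_rng(seed)
    results = [
        discriminate_one_atlas(int(rng.integers(2**31)), n_shuffles=n_shuffles)
        for _ in range(n_atlases)
    ]
    n_exact = sum(r["exact"] for r in results)
    logger.info("discrimination: %d/%d atlases exactly right", n_exact, n_atlases)
    return {"n_exact": n_exact, "n_atlases": n_atlases, "results": results}
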