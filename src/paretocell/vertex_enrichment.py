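"""Per-vertex gene enrichment with Benjamini-Hochberg control.

For each fitted vertex, cells are ranked by Euclidean distance in the fit's
PC space; the nearest bin (default 10% of cells, minimum 10) is compared to
the remaining cells gene-by-gene with a one-sided Mann-Whitney U test
(nearest > rest) on normalized expression over ALL genes, including
mitochondrial and artifact genes — so artifactual vertices are detectable.
The effect size is the difference of mean normalized expression
(nearest bin minus rest), keeping everything on the linear scale. q-values
are BH step-up per vertex across genes, with significance called at
q <= 0.10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ENRICHMENT_FDR = 0.10


def rank_cells_by_vertex_distance(scores: np.ndarray, vertex: np.ndarray) -> np.ndarray:
    """Cell indices by ascending Euclidean distance to the vertex, ties by index."""
    d = np.linalg.norm(np.asarray(scores, float) - np.asarray(vertex, float), axis=1)
    return np.argsort(d, kind="stable")


def enrich_vertex(
    all_genes_matrix: np.ndarray,
    ordering: np.ndarray,
    bin_fraction: float = 0.10,
    min_bin: int = 10,
) -> pd.DataFrame:
    """One-sided Mann-Whitney (nearest bin > rest) per gene.

    Returns a DataFrame with columns effect_size and p (one row per gene
    column). Constant genes get p = 1, effect 0. The bin holds
    round(bin_fraction * n) cells, floored at ``min_bin``.
    """
    X = np.asarray(all_genes_matrix, float)
    n = X.shape[0]
    n_bin = min(max(int(round(bin_fraction * n)), min_bin), n - min_bin)
    if n_bin < min_bin:
        raise ValueError(f"too few cells ({n}) for a {min_bin}-cell nearest bin")
    near = X[ordering[:n_bin]]
    rest = X[ordering[n_bin:]]
    effect = near.mean(axis=0) - rest.mean(axis=0)
    p = np.ones(X.shape[1])
    constant = X.max(axis=0) == X.min(axis=0)
    if (~constant).any():
        res = mannwhitneyu(
            near[:, ~constant], rest[:, ~constant], alternative="greater", axis=0
        )
        p[~constant] = res.pvalue
    effect[constant] = 0.0
    return pd.DataFrame({"effect_size": effect, "p": p})


def bh_correct(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i}(p_(j) m / j), capped at 1."""
    pvalues = np.asarray(pvalues, float)
    if pvalues.size == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="fdr_bh")[1]


@dataclass
class VertexEnrichmentTable:
    """Tidy per-(vertex, gene) enrichment table for one stratum."""

    stratum_id: str
    table: pd.DataFrame  # stratum_id, vertex_index, gene_id, effect_size, p, q, rank
    flagged_vertices: list  # vertices with zero significant genes


def enrich_fit(
    scores: np.ndarray,
    vertices: np.ndarray,
    all_genes_matrix: np.ndarray,
    gene_ids,
    stratum_id: str = "",
    bin_fraction: float = 0.10,
    fdr_cap: float = ENRICHMENT_FDR,
) -> VertexEnrichmentTable:
    """Enrichment across every vertex of one fit, BH-corrected per vertex."""
    rows = []
    flagged = []
    gene_ids = np.asarray(gene_ids)
    for v in range(vertices.shape[0]):
        order = rank_cells_by_vertex_distance(scores, vertices[v])
        df = enrich_vertex(all_genes_matrix, order, bin_fraction)
        df["q"] = bh_correct(df["p"].to_numpy())
        df["stratum_id"] = stratum_id
        df["vertex_index"] = v
        df["gene_id"] = gene_ids
        df = df.sort_values(
            ["q", "effect_size", "gene_id"], ascending=[True, False, True]
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        if not ((df["q"] <= fdr_cap) & (df["effect_size"] > 0)).any():
            flagged.append(v)
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)[
        ["stratum_id", "vertex_index", "gene_id", "effect_size", "p", "q", "rank"]
    ]
    if flagged:
        logger.info("stratum %s: vertices with no enriched genes: %s", stratum_id, flagged)
    return VertexEnrichmentTable(stratum_id=stratum_id, table=table, flagged_vertices=flagged)


def top_markers(
    enrichment: VertexEnrichmentTable,
    vertex: int,
    n: int = 10,
    fdr_cap: float = ENRICHMENT_FDR,
) -> list:
    """Up to ``n`` significant (q <= cap, effect > 0) genes by descending effect.

    Returns an empty list when the vertex has no significant genes (such a
    vertex is a candidate false-positive polytope and is flagged upstream).
    """
    df = enrichment.table
    sub = df[
        (df["vertex_index"] == vertex) & (df["q"] <= fdr_cap) & (df["effect_size"] > 0)
    ]
    sub = sub.sort_values(["effect_size", "gene_id"], ascending=[False, True])
    return list(sub["gene_id"].head(n))
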