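"""Cross-replicate archetype alignment by shared enriched genes.

Within each cell type, every fitted vertex (a specialist phenotype) carries
a ranked list of up to 10 enriched genes. Vertices are joined in a weighted
graph whose edge weights count shared genes, clustered by seeded Louvain
community detection, and clusters covering at least half of the cell type's
available donors are accepted as reproducible archetypes. A consensus gene
list keeps genes appearing in at least two member lists, ranked by
frequency; archetype expression profiles average the normalized expression
of the consensus genes over each member vertex's closest 5% of cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .vertex_enrichment import rank_cells_by_vertex_distance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VertexNode:
    """One specialist phenotype: a stratum vertex with its marker list."""

    stratum_id: str
    vertex_index: int
    donor: str
    tissue: str
    markers: tuple

    @property
    def node_id(self) -> str:
        return f"{self.stratum_id}#v{self.vertex_index}"


@dataclass
class ArchetypeCluster:
    cell_type: str
    cluster_id: int
    members: list                       # VertexNode
    donor_coverage: float
    consensus_genes: list               # (gene, frequency), frequency >= 2
    accepted: bool
    annotation: str = "unannotated"

    @property
    def donors(self) -> set:
        return {m.donor for m in self.members}


def build_vertex_graph(nodes: list[VertexNode]) -> nx.Graph:
    """Weighted graph over specialist phenotypes; weight = #shared marker genes.

    Zero-overlap pairs carry no edge. Nodes with empty marker lists must be
    excluded by the caller (they cannot share genes).
    """
    if len(nodes) < 2:
        raise ValueError("need at least 2 vertex nodes to build a graph")
    G = nx.Graph()
    for node in nodes:
        if not node.markers:
            raise ValueError(f"node {node.node_id} has an empty marker list")
        G.add_node(node.node_id, node=node)
    for i, u in enumerate(nodes):
        su = set(u.markers)
        for v in nodes[i + 1 :]:
            w = len(su & set(v.markers))
            if w > 0:
                G.add_edge(u.node_id, v.node_id, weight=w)
    return G


def cluster_vertices(G: nx.Graph, seed: int = 0, resolution: float = 1.0) -> dict:
    """Seeded Louvain communities on the weighted graph -> node_id -> label.

    Singletons are allowed; redundant vertices from a single donor-tissue may
    co-cluster (they are de-duplicated later by counting distinct donors).
    """
    communities = nx.community.louvain_communities(
        G, weight="weight", resolution=resolution, seed=seed
    )
    labels: dict[str, int] = {}
    for label, members in enumerate(sorted(communities, key=lambda c: sorted(c)[0])):
        for node_id in members:
            labels[node_id] = label
    return labels


def consensus_genes(members: list[VertexNode]) -> list:
    """Genes by descending frequency across member lists, frequency-1 dropped.

    Ties break by gene id. An all-frequency-1 cluster yields an empty list
    (flagged by the caller).
    """
    if len(members) < 2:
        raise ValueError("consensus requires at least 2 members")
    freq: dict[str, int] = {}
    for m in members:
        for g in m.markers:
            freq[g] = freq.get(g, 0) + 1
    ranked = sorted(
        ((g, c) for g, c in freq.items() if c >= 2), key=lambda gc: (-gc[1], gc[0])
    )
    return ranked


def coverage_filter(
    clusters: list[ArchetypeCluster],
    donors_available: int,
    threshold: float = 0.5,
) -> list[ArchetypeCluster]:
    """Mark clusters accepted iff distinct-donor coverage >= threshold.

    The default 0.5 implements the at-least-half-of-donors reproducibility
    rule; 2/3 reproduces the stricter headline filter.
    """
    for c in clusters:
        c.donor_coverage = len(c.donors) / donors_available if donors_available else 0.0
        c.accepted = c.donor_coverage >= threshold
    return [c for c in clusters if c.accepted]


def align_cell_type(
    nodes: list[VertexNode],
    cell_type: str,
    donors_available: int,
    coverage_threshold: float = 0.5,
    seed: int = 0,
    annotate=None,
) -> tuple[list[ArchetypeCluster], list[VertexNode]]:
    """Full alignment for one cell type.

    Returns (all clusters with coverage/acceptance marked, excluded nodes
    with empty marker lists). ``annotate`` is an optional hook mapping a gene
    list to a label string; the default labels every archetype
    "unannotated".
    """
    usable = [n for n in nodes if n.markers]
    excluded = [n for n in nodes if not n.markers]
    if excluded:
        logger.info("align %s: %d vertices had no markers", cell_type, len(excluded))
    if len(usable) < 2:
        return [], excluded
    G = build_vertex_graph(usable)
    labels = cluster_vertices(G, seed=seed)
    clusters = []
    for label in sorted(set(labels.values())):
        members = [n for n in usable if labels[n.node_id] == label]
        cons = consensus_genes(members) if len(members) >= 2 else []
        clusters.append(
            ArchetypeCluster(
                cell_type=cell_type,
                cluster_id=label,
                members=members,
                donor_coverage=0.0,
                consensus_genes=cons,
                accepted=False,
            )
        )
    coverage_filter(clusters, donors_available, coverage_threshold)
    if annotate is not None:
        for c in clusters:
            if c.accepted:
                c.annotation = annotate([g for g, _ in c.consensus_genes])
    return clusters, excluded


def archetype_expression_profile(
    cluster: ArchetypeCluster,
    stratum_data: dict,
    closest_fraction: float = 0.05,
) -> pd.DataFrame:
    """Mean normalized expression of consensus genes near each member vertex.

    ``stratum_data`` maps stratum_id -> dict with keys ``scores`` (cells x
    PCs of the fit space), ``vertices`` (k x PCs), ``X_all`` (cells x all
    genes, normalized) and ``gene_ids``. For each member vertex the closest
    ``closest_fraction`` of cells (at least 1) are pooled across members and
    averaged per consensus gene. Returns a one-row-per-gene DataFrame.
    """
    genes = [g for g, _ in cluster.consensus_genes]
    if not genes:
        return pd.DataFrame(columns=["gene_id", "mean_expression"])
    pooled = []
    for m in cluster.members:
        data = stratum_data[m.stratum_id]
        gene_index = pd.Index(data["gene_ids"])
        cols = gene_index.get_indexer(genes)
        if (cols < 0).any():
            missing = [g for g, c in zip(genes, cols) if c < 0]
            raise KeyError(f"genes missing from stratum {m.stratum_id}: {missing}")
        order = rank_cells_by_vertex_distance(
            data["scores"], data["vertices"][m.vertex_index]
        )
        n_close = max(1, int(round(closest_fraction * len(order))))
        pooled.append(np.asarray(data["X_all"])[order[:n_close]][:, cols])
    mat = np.vstack(pooled)
    return pd.DataFrame({"gene_id": genes, "mean_expression": mat.mean(axis=0)})


def archetype_profile_matrix(
    clusters: list[ArchetypeCluster],
    stratum_data: dict,
    closest_fraction: float = 0.05,
) -> pd.DataFrame:
    """Archetype x gene matrix of profiles: each accepted archetype's consensus
    genes measured in its own cells AND in every other archetype's cells."""
    accepted = [c for c in clusters if c.accepted]
    all_genes = sorted({g for c in accepted for g, _ in c.consensus_genes})
    rows = {}
    for c in accepted:
        probe = ArchetypeCluster(
            cell_type=c.cell_type,
            cluster_id=c.cluster_id,
            members=c.members,
            donor_coverage=c.donor_coverage,
            consensus_genes=[(g, 2) for g in all_genes],
            accepted=True,
        )
        prof = archetype_expression_profile(probe, stratum_data, closest_fraction)
        rows[f"archetype_{c.cluster_id}"] = prof.set_index("gene_id")["mean_expression"]
    return pd.DataFrame(rows).T
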