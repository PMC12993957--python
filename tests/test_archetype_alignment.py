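"""Alignment recovery of planted archetype identity across donor-tissues,
graph construction oracles, and the coverage/consensus rules."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from paretocell import (
    align_cell_type,
    build_vertex_graph,
    cluster_vertices,
    consensus_genes,
    coverage_filter,
)
from paretocell.archetype_alignment import (
    ArchetypeCluster,
    VertexNode,
    archetype_expression_profile,
)
from paretocell.synthetic_atlas import generate_marker_lists


def _nodes_from_dicts(dicts):
    return [
        VertexNode(
            stratum_id=d["stratum_id"],
            vertex_index=d["vertex_index"],
            donor=d["donor"],
            tissue=d["tissue"],
            markers=tuple(d["markers"]),
        )
        for d in dicts
    ]


class TestBuildVertexGraph:
    def test_intersection_weight(self):
        u = VertexNode("s1", 0, "D1", "T1", tuple("ABCDEFGHIJ"))
        v = VertexNode("s2", 0, "D2", "T1", tuple("ABCDE") + tuple("KLMNO"))
        G = build_vertex_graph([u, v])
        assert G[u.node_id][v.node_id]["weight"] == 5

    def test_disjoint_lists_carry_no_edge(self):
        u = VertexNode("s1", 0, "D1", "T1", ("A", "B"))
        v = VertexNode("s2", 0, "D2", "T1", ("C", "D"))
        G = build_vertex_graph([u, v])
        assert G.number_of_edges() == 0

    def test_symmetric_zero_diagonal_matches_double_loop(self):
        rng = np.random.default_rng(0)
        pool = [f"g{i}" for i in range(30)]
        nodes = [
            VertexNode(f"s{i}", 0, f"D{i}", "T1",
                       tuple(rng.choice(pool, size=8, replace=False)))
            for i in range(6)
        ]
        G = build_vertex_graph(nodes)
        for i, u in enumerate(nodes):
            assert not G.has_edge(u.node_id, u.node_id)
            for v in nodes[i + 1:]:
                w = len(set(u.markers) & set(v.markers))
                if w:
                    assert G[u.node_id][v.node_id]["weight"] == w
                    assert G[v.node_id][u.node_id]["weight"] == w
                else:
                    assert not G.has_edge(u.node_id, v.node_id)

    def test_empty_marker_list_rejected(self):
        with pytest.raises(ValueError, match="empty marker"):
            build_vertex_graph(
                [VertexNode("s1", 0, "D1", "T1", ()), VertexNode("s2", 0, "D2", "T1", ("A",))]
            )


class TestClusterVertices:
    def test_disconnected_blocks_form_two_clusters(self):
        a = [VertexNode(f"a{i}", 0, f"D{i}", "T1", tuple("ABCDEFGHIJ")) for i in range(3)]
        b = [VertexNode(f"b{i}", 0, f"D{i}", "T1", tuple("KLMNOPQRST")) for i in range(3)]
        G = build_vertex_graph(a + b)
        labels = cluster_vertices(G, seed=0)
        assert len({labels[n.node_id] for n in a}) == 1
        assert len({labels[n.node_id] for n in b}) == 1
        assert labels[a[0].node_id] != labels[b[0].node_id]

    def _ari(self, noise_fraction, seed=0):
        dicts = generate_marker_lists(
            4, [f"D{i}" for i in range(3)], ["T1", "T2"],
            noise_fraction=noise_fraction, seed=seed,
        )
        nodes = _nodes_from_dicts(dicts)
        G = build_vertex_graph(nodes)
        labels = cluster_vertices(G, seed=1)
        truth = [d["archetype"] for d in dicts]
        pred = [labels[n.node_id] for n in nodes]
        return adjusted_rand_score(truth, pred)

    def test_zero_jitter_perfect_recovery(self):
        assert self._ari(0.0) == 1.0

    def test_moderate_marker_noise_still_recovers(self):
        """3 of 10 genes scrambled per list across 6 donor-tissues."""
        aris = [self._ari(0.3, seed=s) for s in range(5)]
        assert np.mean(aris) >= 0.9


class TestCoverageAndConsensus:
    def _cluster(self, donors):
        members = [
            VertexNode(f"s{i}", 0, d, "T1", ("A", "B")) for i, d in enumerate(donors)
        ]
        return ArchetypeCluster(
            cell_type="ct", cluster_id=0, members=members,
            donor_coverage=0.0, consensus_genes=[], accepted=False,
        )

    def test_half_coverage_boundary_accepted(self):
        c = self._cluster(["D1", "D2"])
        accepted = coverage_filter([c], donors_available=4, threshold=0.5)
        assert accepted and c.donor_coverage == 0.5

    def test_two_thirds_threshold_rejects_half(self):
        c = self._cluster(["D1", "D2"])
        assert coverage_filter([c], donors_available=4, threshold=2 / 3) == []

    def test_redundant_vertices_from_one_donor_do_not_inflate_coverage(self):
        c = self._cluster(["D1", "D1", "D1"])
        coverage_filter([c], donors_available=3, threshold=0.5)
        assert c.donor_coverage == pytest.approx(1 / 3)
        assert not c.accepted

    def test_consensus_drops_frequency_one(self):
        members = [
            VertexNode("s1", 0, "D1", "T1", ("A", "B", "C")),
            VertexNode("s2", 0, "D2", "T1", ("A", "B")),
            VertexNode("s3", 0, "D3", "T1", ("A",)),
        ]
        assert consensus_genes(members) == [("A", 3), ("B", 2)]

    def test_identical_lists_all_at_full_frequency(self):
        markers = tuple(f"g{i}" for i in range(10))
        members = [VertexNode(f"s{i}", 0, f"D{i}", "T1", markers) for i in range(5)]
        cons = consensus_genes(members)
        assert len(cons) == 10 and all(f == 5 for _, f in cons)


class TestAlignCellType:
    def test_zero_jitter_end_to_end_clusters_and_consensus(self):
        dicts = generate_marker_lists(3, ["D1", "D2", "D3"], ["T1", "T2"], seed=4)
        nodes = _nodes_from_dicts(dicts)
        clusters, excluded = align_cell_type(nodes, "ct", donors_available=3, seed=0)
        assert excluded == []
        accepted = [c for c in clusters if c.accepted]
        assert len(accepted) == 3
        by_arch = {}
        for d in dicts:
            by_arch.setdefault(d["archetype"], set(d["markers"]))
        for c in accepted:
            assert c.donor_coverage == 1.0
            cons = {g for g, _ in c.consensus_genes}
            assert cons in by_arch.values()

    def test_permutation_invariance(self):
        dicts = generate_marker_lists(3, ["D1", "D2"], ["T1", "T2"], seed=5)
        nodes = _nodes_from_dicts(dicts)
        c1, _ = align_cell_type(nodes, "ct", donors_available=2, seed=0)
        c2, _ = align_cell_type(list(reversed(nodes)), "ct", donors_available=2, seed=0)
        sets1 = sorted(frozenset(m.node_id for m in c.members) for c in c1)
        sets2 = sorted(frozenset(m.node_id for m in c.members) for c in c2)
        assert sets1 == sets2


class TestExpressionProfile:
    def _setup(self):
        rng = np.random.default_rng(0)
        n, g = 100, 12
        gene_ids = [f"g{i}" for i in range(g)]
        scores = rng.normal(size=(n, 2))
        vertices = np.array([[3.0, 0.0], [-3.0, 0.0]])
        X = rng.poisson(5.0, size=(n, g)).astype(float)
        near0 = np.argsort(np.linalg.norm(scores - vertices[0], axis=1))[:20]
        X[near0, :3] *= 6  # markers g0..g2 elevated near vertex 0
        data = {"s1": {"scores": scores, "vertices": vertices, "X_all": X, "gene_ids": gene_ids}}
        members = [VertexNode("s1", 0, "D1", "T1", ("g0", "g1", "g2"))]
        other = [VertexNode("s1", 1, "D1", "T1", ("g5", "g6"))]
        mk = lambda mem: ArchetypeCluster(
            "ct", 0, mem, 1.0, [("g0", 2), ("g1", 2), ("g2", 2)], True
        )
        return data, mk(members), mk(other)

    def test_own_archetype_mean_exceeds_other(self):
        data, own, other = self._setup()
        p_own = archetype_expression_profile(own, data, closest_fraction=0.05)
        p_other = archetype_expression_profile(other, data, closest_fraction=0.05)
        assert (p_own["mean_expression"].to_numpy() > p_other["mean_expression"].to_numpy()).all()

    def test_full_fraction_equals_stratum_mean(self):
        data, own, _ = self._setup()
        prof = archetype_expression_profile(own, data, closest_fraction=1.0)
        X = data["s1"]["X_all"]
        assert np.allclose(prof["mean_expression"], X[:, :3].mean(axis=0))
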