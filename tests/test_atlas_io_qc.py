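"""QC filters against brute-force oracles and the stated boundary conventions."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from paretocell import (
    compute_qc_metrics,
    filter_rare_genes,
    filter_upper_decile,
    normalize_and_strip,
    read_atlas,
    run_qc,
    stratify,
    write_atlas,
)
from paretocell.atlas_io_qc import ExpressionAtlas, assert_min_protein_coding


def _dense(atlas):
    return np.asarray(atlas.counts.todense())


class TestRareGeneFilter:
    def test_gene_in_four_cells_removed_at_threshold_five(self, tiny_atlas):
        counts = _dense(tiny_atlas)
        counts[:, 0] = 0
        counts[:4, 0] = 7  # expressed in exactly 4 cells
        atlas = ExpressionAtlas(sp.csr_matrix(counts), tiny_atlas.cell_meta, tiny_atlas.gene_meta)
        out = filter_rare_genes(atlas, min_cells=5)
        assert "g0" not in out.gene_meta.index

    def test_zero_threshold_is_identity(self, tiny_atlas):
        out = filter_rare_genes(tiny_atlas, min_cells=0)
        assert out.n_genes == tiny_atlas.n_genes

    def test_survivors_match_hand_enumeration(self, tiny_atlas):
        support = (_dense(tiny_atlas) > 0).sum(axis=0)
        out = filter_rare_genes(tiny_atlas, min_cells=5)
        expected = tiny_atlas.gene_meta.index[support >= 5]
        assert list(out.gene_meta.index) == list(expected)


class TestQCMetrics:
    def test_fraction_arithmetic(self):
        counts = np.zeros((1, 6), int)
        counts[0, 3] = 5   # mito gene
        counts[0, 0] = 15  # protein coding
        meta = pd.DataFrame({"donor": ["D"], "tissue": ["T"], "cell_type": ["a"]},
                            index=pd.Index(["c0"], name="cell_id"))
        gm = pd.DataFrame(
            {
                "is_protein_coding": [True] * 5 + [False],
                "is_mitochondrial": [False] * 3 + [True, False, False],
                "is_artifact": [False] * 4 + [True, False],
            },
            index=pd.Index([f"g{i}" for i in range(6)], name="gene_id"),
        )
        qc = compute_qc_metrics(ExpressionAtlas(sp.csr_matrix(counts), meta, gm))
        assert qc.loc["c0", "pct_mito"] == 0.25
        assert qc.loc["c0", "protein_coding_counts_ex_mito_artifact"] == 15

    def test_all_zero_cell_flagged_with_zero_fractions(self, tiny_atlas):
        qc = compute_qc_metrics(tiny_atlas)
        assert qc.loc["c9", "is_zero_total"]
        assert qc.loc["c9", "pct_mito"] == 0.0
        assert qc.loc["c9", "pct_artifact"] == 0.0

    def test_matches_dense_loop_oracle(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 30, size=(20, 8))
        meta = pd.DataFrame(
            {"donor": ["D"] * 20, "tissue": ["T"] * 20, "cell_type": ["a"] * 20},
            index=pd.Index([f"c{i}" for i in range(20)], name="cell_id"),
        )
        mito = np.array([False, True, False, False, True, False, False, False])
        art = np.array([False, False, False, True, False, False, False, False])
        gm = pd.DataFrame(
            {"is_protein_coding": [True] * 8, "is_mitochondrial": mito, "is_artifact": art},
            index=pd.Index([f"g{i}" for i in range(8)], name="gene_id"),
        )
        qc = compute_qc_metrics(ExpressionAtlas(sp.csr_matrix(counts), meta, gm))
        for i in range(20):
            row = counts[i]
            assert qc.iloc[i]["total_counts"] == row.sum()
            assert qc.iloc[i]["pct_mito"] == pytest.approx(row[mito].sum() / row.sum())
            assert qc.iloc[i]["pct_artifact"] == pytest.approx(row[art].sum() / row.sum())
            assert qc.iloc[i]["n_genes_expressed"] == (row > 0).sum()
            assert qc.iloc[i]["protein_coding_counts_ex_mito_artifact"] == row[~mito & ~art].sum()


class TestUpperDecileFilter:
    def _metrics(self, **cols):
        n = len(next(iter(cols.values())))
        base = {m: np.zeros(n) for m in
                ("pct_mito", "pct_artifact", "n_genes_expressed", "total_counts", "n_umi")}
        base.update(cols)
        return pd.DataFrame(base)

    def test_top_of_ten_removed_under_linear_interpolation(self):
        # 90th percentile of 1..10 is 9.1; only the value-10 cell exceeds it
        m = self._metrics(pct_mito=np.arange(1.0, 11.0))
        keep = filter_upper_decile(m)
        assert keep.sum() == 9 and not keep[9]

    def test_constant_metric_removes_nothing(self):
        m = self._metrics(total_counts=np.full(20, 7.0))
        assert filter_upper_decile(m).all()

    def test_union_of_disjoint_top_cells_removed(self):
        a = np.zeros(20); a[3] = 10.0
        b = np.zeros(20); b[17] = 10.0
        keep = filter_upper_decile(self._metrics(pct_mito=a, pct_artifact=b))
        assert not keep[3] and not keep[17] and keep.sum() == 18


class TestProteinCodingFloor:
    def test_boundary_inclusive_at_threshold(self):
        m = pd.DataFrame(
            {"protein_coding_counts_ex_mito_artifact": [100, 101, 5]},
            index=["a", "b", "c"],
        )
        assert assert_min_protein_coding(m, 100) == ["a", "c"]

    def test_clean_synthetic_atlas_has_no_violations(self, small_synthetic_atlas):
        atlas, _ = small_synthetic_atlas
        qc = compute_qc_metrics(atlas)
        assert assert_min_protein_coding(qc, 100) == []


class TestNormalization:
    def test_worked_example_scales_to_ten_thousand(self):
        counts = np.array([[1, 2, 2]])
        meta = pd.DataFrame({"donor": ["D"], "tissue": ["T"], "cell_type": ["a"]},
                            index=pd.Index(["c0"], name="cell_id"))
        gm = pd.DataFrame(
            {"is_protein_coding": [True] * 3, "is_mitochondrial": [False] * 3,
             "is_artifact": [False] * 3},
            index=pd.Index(["g0", "g1", "g2"], name="gene_id"),
        )
        norm = normalize_and_strip(ExpressionAtlas(sp.csr_matrix(counts), meta, gm))
        assert np.allclose(norm.X_model.todense(), [[2000, 4000, 4000]])

    def test_row_sums_and_proportions_preserved(self, small_synthetic_atlas):
        atlas, _ = small_synthetic_atlas
        norm = normalize_and_strip(atlas)
        sums = np.asarray(norm.X_model.sum(axis=1)).ravel()
        assert np.allclose(sums, 10_000, atol=1e-6)
        # within-cell proportions of retained genes are unchanged
        model_cols = atlas.gene_meta.index.get_indexer(norm.model_gene_ids)
        raw = np.asarray(atlas.counts[:, model_cols].todense(), float)
        raw = raw[raw.sum(axis=1) > 0]
        expected = raw / raw.sum(axis=1, keepdims=True) * 10_000
        assert np.allclose(np.asarray(norm.X_model.todense()), expected, atol=1e-8)

    def test_mito_artifact_stripped_from_model_kept_in_all(self, tiny_atlas):
        norm = normalize_and_strip(tiny_atlas)
        assert list(norm.model_gene_ids) == ["g0", "g1", "g2"]
        assert norm.X_all.shape[1] == 6
        # all-genes matrix shares the per-cell scale factor of the model matrix
        x_model = np.asarray(norm.X_model.todense())
        x_all = np.asarray(norm.X_all.todense())
        assert np.allclose(x_all[:, :3], x_model)


class TestStratify:
    def _norm_atlas(self, sizes, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        donors = []
        for i, (donor, size) in enumerate(sizes.items()):
            donors += [donor] * size
        n = len(donors)
        counts = rng.integers(1, 9, size=(n, 5))
        meta = pd.DataFrame(
            {"donor": donors, "tissue": ["T"] * n, "cell_type": ["a"] * n},
            index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"),
        )
        gm = pd.DataFrame(
            {"is_protein_coding": [True] * 5, "is_mitochondrial": [False] * 5,
             "is_artifact": [False] * 5},
            index=pd.Index([f"g{i}" for i in range(5)], name="gene_id"),
        )
        return normalize_and_strip(ExpressionAtlas(sp.csr_matrix(counts), meta, gm))

    def test_forty_nine_cell_group_excluded(self):
        norm = self._norm_atlas({"D1": 49, "D2": 60})
        strata = stratify(norm, min_cells=50)
        assert [s.donor for s in strata] == ["D2"]

    def test_oversized_group_downsampled_reproducibly(self):
        norm = self._norm_atlas({"D1": 1500})
        s1 = stratify(norm, max_cells=1000, seed=42)[0]
        s2 = stratify(norm, max_cells=1000, seed=42)[0]
        s3 = stratify(norm, max_cells=1000, seed=43)[0]
        assert s1.n_cells == 1000 and s1.n_cells_original == 1500
        assert list(s1.cell_ids) == list(s2.cell_ids)
        assert list(s1.cell_ids) != list(s3.cell_ids)

    def test_stratum_count_matches_planted_truth(self, small_synthetic_atlas):
        atlas, truth = small_synthetic_atlas
        norm = normalize_and_strip(atlas)
        strata = stratify(norm, min_cells=50)
        eligible = [s for s in truth.strata if s.n_cells >= 50]
        assert len(strata) == len(eligible)


def test_roundtrip_and_full_qc_order(tmp_path, small_synthetic_atlas):
    atlas, _ = small_synthetic_atlas
    write_atlas(atlas, tmp_path)
    back = read_atlas(tmp_path / "matrix.mtx", tmp_path / "cells.tsv", tmp_path / "genes.tsv")
    assert (back.counts != atlas.counts).nnz == 0
    assert list(back.cell_meta.columns) == list(atlas.cell_meta.columns)
    norm, log = run_qc(back)
    assert log["n_cells_out"] <= log["n_cells_in"]
    assert np.allclose(np.asarray(norm.X_model.sum(axis=1)).ravel(), 10_000, atol=1e-6)
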