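"""Atlas container, I/O, quality-control filters, normalization and stratification.

The analysis unit downstream of this module is the *stratum*: all cells from
one donor-tissue-cell-type, with a modeling matrix restricted to
protein-coding genes (mitochondrial and dissociation-artifact genes removed)
and normalized to 10,000 counts per cell, plus a parallel all-genes normalized
matrix (same per-cell scale factors) retained for vertex enrichment.

Filters are order-dependent and applied in this fixed order:
rare-gene filter -> upper-decile QC filter -> protein-coding floor ->
gene stripping + normalization -> stratification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

CELL_META_COLUMNS = ("donor", "tissue", "cell_type")
GENE_META_COLUMNS = ("is_protein_coding", "is_mitochondrial", "is_artifact")

#: the five per-cell metrics screened by the upper-decile outlier filter
DECILE_METRICS = (
    "pct_mito",
    "pct_artifact",
    "n_genes_expressed",
    "total_counts",
    "n_umi",
)


@dataclass
class ExpressionAtlas:
    """Sparse cells x genes count matrix with cell and gene metadata.

    ``cell_meta`` is indexed by cell id with columns donor / tissue /
    cell_type; ``gene_meta`` is indexed by gene id with boolean columns
    is_protein_coding / is_mitochondrial / is_artifact.
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cell_meta), len(self.gene_meta)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match metadata "
                f"({len(self.cell_meta)} cells, {len(self.gene_meta)} genes)"
            )
        for col in CELL_META_COLUMNS:
            if col not in self.cell_meta.columns:
                raise ValueError(f"cell_meta missing column {col!r}")
        for col in GENE_META_COLUMNS:
            if col not in self.gene_meta.columns:
                raise ValueError(f"gene_meta missing column {col!r}")
            self.gene_meta[col] = self.gene_meta[col].astype(bool)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset(self, cell_mask=None, gene_mask=None) -> "ExpressionAtlas":
        """Return a new atlas restricted to the given boolean masks."""
        counts = self.counts
        cell_meta, gene_meta = self.cell_meta, self.gene_meta
        if cell_mask is not None:
            cell_mask = np.asarray(cell_mask, bool)
            counts = counts[cell_mask]
            cell_meta = cell_meta.loc[cell_mask]
        if gene_mask is not None:
            gene_mask = np.asarray(gene_mask, bool)
            counts = counts[:, gene_mask]
            gene_meta = gene_meta.loc[gene_mask]
        return ExpressionAtlas(counts.copy(), cell_meta.copy(), gene_meta.copy())

    def to_anndata(self):
        """Convenience view as an :class:`anndata.AnnData` (optional dependency)."""
        import anndata

        return anndata.AnnData(
            X=self.counts.copy(), obs=self.cell_meta.copy(), var=self.gene_meta.copy()
        )


def read_atlas(mtx_path, cells_path, genes_path) -> ExpressionAtlas:
    """Read an atlas from Matrix Market counts plus two TSV metadata tables.

    NA-sniffing is disabled so labels like "null" or "NA" survive as literal
    donor/tissue/cell-type names; gene flags accept booleans or the strings
    "True"/"False".
    """
    counts = sp.csr_matrix(mmread(str(mtx_path)))
    cell_meta = pd.read_csv(cells_path, sep="\t", index_col=0, keep_default_na=False)
    gene_meta = pd.read_csv(genes_path, sep="\t", index_col=0, keep_default_na=False)
    for col in GENE_META_COLUMNS:
        if col in gene_meta.columns and gene_meta[col].dtype == object:
            gene_meta[col] = gene_meta[col].map(
                {"True": True, "False": False, True: True, False: False}
            )
    return ExpressionAtlas(counts, cell_meta, gene_meta)


def write_atlas(atlas: ExpressionAtlas, outdir) -> None:
    """Write counts (.mtx), cells.tsv and genes.tsv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(atlas.counts))
    atlas.cell_meta.to_csv(outdir / "cells.tsv", sep="\t", index_label="cell_id")
    atlas.gene_meta.to_csv(outdir / "genes.tsv", sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_rare_genes(atlas: ExpressionAtlas, min_cells: int = 5) -> ExpressionAtlas:
    """Remove genes with nonzero counts in fewer than ``min_cells`` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    n_expressing = np.asarray((atlas.counts > 0).sum(axis=0)).ravel()
    keep = n_expressing >= min_cells
    if not keep.any():
        raise ValueError("rare-gene filter removed every gene")
    logger.info("filter_rare_genes: removed %d/%d genes", (~keep).sum(), atlas.n_genes)
    return atlas.subset(gene_mask=keep)


def compute_qc_metrics(atlas: ExpressionAtlas) -> pd.DataFrame:
    """Per-cell QC metrics.

    pct_mito / pct_artifact are fractions of total counts; cells with zero
    total counts get fraction 0 and ``is_zero_total`` set. ``n_umi`` duplicates
    ``total_counts`` for pure-UMI count matrices but is reported separately to
    mirror the five-metric screen.
    """
    counts = atlas.counts
    total = np.asarray(counts.sum(axis=1)).ravel()
    mito = np.asarray(counts[:, atlas.gene_meta["is_mitochondrial"].to_numpy()].sum(axis=1)).ravel()
    art = np.asarray(counts[:, atlas.gene_meta["is_artifact"].to_numpy()].sum(axis=1)).ravel()
    pc_mask = (
        atlas.gene_meta["is_protein_coding"]
        & ~atlas.gene_meta["is_mitochondrial"]
        & ~atlas.gene_meta["is_artifact"]
    ).to_numpy()
    pc_counts = np.asarray(counts[:, pc_mask].sum(axis=1)).ravel()
    zero = total == 0
    safe = np.where(zero, 1, total)
    return pd.DataFrame(
        {
            "pct_mito": np.where(zero, 0.0, mito / safe),
            "pct_artifact": np.where(zero, 0.0, art / safe),
            "n_genes_expressed": np.asarray((counts > 0).sum(axis=1)).ravel(),
            "total_counts": total,
            "n_umi": total,
            "protein_coding_counts_ex_mito_artifact": pc_counts,
            "is_zero_total": zero,
        },
        index=atlas.cell_meta.index,
    )


def filter_upper_decile(metrics: pd.DataFrame, metric_names=DECILE_METRICS) -> np.ndarray:
    """Keep-mask removing cells strictly above the 90th percentile on ANY metric.

    The percentile uses the linear-interpolation convention; removal is by
    strict inequality, so a constant metric removes nothing.
    """
    keep = np.ones(len(metrics), dtype=bool)
    for name in metric_names:
        values = metrics[name].to_numpy(float)
        keep &= values <= np.quantile(values, 0.9)
    logger.info("filter_upper_decile: removed %d/%d cells", (~keep).sum(), len(keep))
    return keep


def assert_min_protein_coding(metrics: pd.DataFrame, threshold: int = 100) -> list:
    """Cells with <= ``threshold`` protein-coding counts (excl. mito/artifact).

    The study's cutoff was non-binding on its data; here violators are listed
    so the pipeline can remove and log them.
    """
    bad = metrics["protein_coding_counts_ex_mito_artifact"] <= threshold
    violations = list(metrics.index[bad])
    if violations:
        logger.info("assert_min_protein_coding: %d violating cells", len(violations))
    return violations


# ---------------------------------------------------------------------------
# normalization / stratification
# ---------------------------------------------------------------------------

TARGET_SUM = 10_000.0


@dataclass
class NormalizedAtlas:
    """QC-filtered atlas with the modeling and all-genes normalized matrices.

    ``X_model`` covers protein-coding genes with mito/artifact stripped; every
    row sums to 10,000. ``X_all`` covers all genes, scaled by the *same*
    per-cell factors so enrichment sees mito/artifact genes on a comparable
    scale.
    """

    X_model: sp.csr_matrix
    X_all: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    model_gene_ids: pd.Index
    qc: pd.DataFrame


def normalize_and_strip(atlas: ExpressionAtlas, qc: pd.DataFrame | None = None) -> NormalizedAtlas:
    """Strip mito/artifact genes from the modeling matrix and normalize.

    Scale factors are computed on the stripped protein-coding matrix
    (10,000 / stripped total) and applied to both matrices. Cells with zero
    stripped counts are removed with a log entry.
    """
    if qc is None:
        qc = compute_qc_metrics(atlas)
    gm = atlas.gene_meta
    model_mask = (
        gm["is_protein_coding"] & ~gm["is_mitochondrial"] & ~gm["is_artifact"]
    ).to_numpy()
    stripped = atlas.counts[:, model_mask]
    totals = np.asarray(stripped.sum(axis=1)).ravel()
    nonzero = totals > 0
    if (~nonzero).any():
        logger.info("normalize_and_strip: removed %d zero-count cells", (~nonzero).sum())
    stripped = stripped[nonzero]
    scale = TARGET_SUM / totals[nonzero]
    D = sp.diags(scale)
    X_model = sp.csr_matrix(D @ stripped.astype(float))
    X_all = sp.csr_matrix(D @ atlas.counts[nonzero].astype(float))
    return NormalizedAtlas(
        X_model=X_model,
        X_all=X_all,
        cell_meta=atlas.cell_meta.loc[nonzero].copy(),
        gene_meta=atlas.gene_meta.copy(),
        model_gene_ids=atlas.gene_meta.index[model_mask],
        qc=qc.loc[atlas.cell_meta.index[nonzero]].copy(),
    )


@dataclass
class Stratum:
    """One donor-tissue-cell-type slice, dense, ready for geometry."""

    donor: str
    tissue: str
    cell_type: str
    cell_ids: np.ndarray
    X: np.ndarray        # cells x modeling genes, normalized
    X_all: np.ndarray    # cells x all genes, normalized (same scale factors)
    model_gene_ids: pd.Index
    all_gene_ids: pd.Index
    pct_mito: np.ndarray
    pct_artifact: np.ndarray
    n_cells_original: int

    @property
    def stratum_id(self) -> str:
        return f"{self.donor}|{self.tissue}|{self.cell_type}"

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]


def stratify(
    norm: NormalizedAtlas,
    min_cells: int = 50,
    max_cells: int = 1000,
    seed: int = 0,
) -> list[Stratum]:
    """Split into donor-tissue-cell-type strata.

    Groups with fewer than ``min_cells`` cells are logged and skipped; groups
    above ``max_cells`` are uniformly subsampled without replacement to exactly
    ``max_cells`` (seeded, reproducible per stratum).
    """
    strata: list[Stratum] = []
    groups = norm.cell_meta.groupby(list(CELL_META_COLUMNS), sort=True, observed=True)
    rng = np.random.default_rng(seed)
    for (donor, tissue, cell_type), sub in groups:
        n = len(sub)
        if n < min_cells:
            logger.info("stratify: skipping %s|%s|%s (%d cells)", donor, tissue, cell_type, n)
            continue
        idx = norm.cell_meta.index.get_indexer(sub.index)
        if n > max_cells:
            idx = np.sort(rng.choice(idx, size=max_cells, replace=False))
        strata.append(
            Stratum(
                donor=str(donor),
                tissue=str(tissue),
                cell_type=str(cell_type),
                cell_ids=norm.cell_meta.index.to_numpy()[idx],
                X=np.asarray(norm.X_model[idx].todense(), float),
                X_all=np.asarray(norm.X_all[idx].todense(), float),
                model_gene_ids=norm.model_gene_ids,
                all_gene_ids=norm.gene_meta.index,
                pct_mito=norm.qc["pct_mito"].to_numpy()[idx],
                pct_artifact=norm.qc["pct_artifact"].to_numpy()[idx],
                n_cells_original=n,
            )
        )
    return strata


def run_qc(
    atlas: ExpressionAtlas,
    min_cells_per_gene: int = 5,
    protein_coding_floor: int = 100,
) -> tuple[NormalizedAtlas, dict]:
    """Apply the QC filters in canonical order and normalize.

    Returns the normalized atlas plus a log dict of removal counts. Inputs are
    never mutated.
    """
    log: dict[str, int] = {"n_cells_in": atlas.n_cells, "n_genes_in": atlas.n_genes}
    atlas = filter_rare_genes(atlas, min_cells_per_gene)
    log["n_genes_after_rare_filter"] = atlas.n_genes

    qc = compute_qc_metrics(atlas)
    keep = filter_upper_decile(qc)
    log["n_cells_removed_decile"] = int((~keep).sum())
    atlas = atlas.subset(cell_mask=keep)
    qc = qc.loc[keep]

    violations = assert_min_protein_coding(qc, protein_coding_floor)
    log["n_cells_removed_pc_floor"] = len(violations)
    if violations:
        keep2 = ~atlas.cell_meta.index.isin(violations)
        atlas = atlas.subset(cell_mask=keep2)
        qc = qc.loc[keep2]

    norm = normalize_and_strip(atlas, qc)
    log["n_cells_out"] = norm.X_model.shape[0]
    log["n_model_genes"] = len(norm.model_gene_ids)
    return norm, log
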