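"""End-to-end pipeline: QC -> stratify -> geometry -> fit -> enrich ->
aggregate -> align, with seeded determinism and per-stage logging.

Every stage writes its artifact tables when an output directory is given;
the final report is assembled purely from those stage artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import pearsonr, spearmanr

from .archetype_alignment import (
    ArchetypeCluster,
    VertexNode,
    align_cell_type,
    archetype_profile_matrix,
)
from .atlas_io_qc import ExpressionAtlas, run_qc, stratify
from .polytope_fit import bootstrap_vertices, sweep_dimensions
from .significance_aggregation import aggregate_cell_types
from .stratum_geometry import compute_stratum_geometry
from .vertex_enrichment import VertexEnrichmentTable, enrich_fit, top_markers

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable thresholds of the analysis, with the study defaults."""

    alpha: float = 0.05
    enrichment_fdr_cap: float = 0.10
    celltype_fdr_cap: float = 0.10
    r_threshold: float = 0.3
    dims: tuple = (5, 4, 3, 2)
    n_shuffles: int = 1000
    n_boot: int = 100
    bin_fraction: float = 0.10
    closest_fraction: float = 0.05
    coverage_threshold: float = 0.5
    min_cells: int = 50
    max_cells: int = 1000
    min_cells_per_gene: int = 5
    protein_coding_floor: int = 100
    n_components: int = 10
    density_drop_fraction: float = 0.10
    n_restarts_test: int = 1
    n_restarts_final: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "enrichment_fdr_cap", "celltype_fdr_cap",
                     "bin_fraction", "closest_fraction", "coverage_threshold",
                     "density_drop_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        dims = tuple(int(d) for d in self.dims)
        if any(d < 2 or d > 5 for d in dims):
            raise ValueError("dims must lie within [2, 5]")
        if any(later >= earlier for later, earlier in zip(dims[1:], dims)):
            raise ValueError("dims must be strictly decreasing")
        self.dims = dims
        if self.n_shuffles < 1 or self.min_cells < 1:
            raise ValueError("n_shuffles and min_cells must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class PipelineResult:
    config: PipelineConfig
    qc_log: dict
    manifest: pd.DataFrame
    fits: dict                      # stratum_id -> SimplexFit
    fits_table: pd.DataFrame
    enrichment: dict                # stratum_id -> VertexEnrichmentTable
    celltype_summary: pd.DataFrame
    fdr_cdf: pd.DataFrame
    clusters: dict                  # cell_type -> list[ArchetypeCluster]
    archetype_table: pd.DataFrame
    profile_matrices: dict          # cell_type -> DataFrame
    qc_report: pd.DataFrame
    stratum_data: dict = field(default_factory=dict)


def run_pipeline(
    atlas: ExpressionAtlas,
    config: PipelineConfig | None = None,
    outdir=None,
) -> PipelineResult:
    """Execute the full analysis on an atlas; reproducible given config.seed."""
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)

    norm, qc_log = run_qc(atlas, cfg.min_cells_per_gene, cfg.protein_coding_floor)
    strata = stratify(norm, cfg.min_cells, cfg.max_cells, seed=int(rng.integers(2**31)))
    logger.info("pipeline: %d strata after QC/stratification", len(strata))

    manifest_rows, fits, fit_rows = [], {}, []
    enrichment: dict[str, VertexEnrichmentTable] = {}
    stratum_data: dict[str, dict] = {}
    celltype_records: dict[str, list] = {}
    celltype_donors: dict[str, set] = {}

    for stratum in strata:
        sid = stratum.stratum_id
        stratum_seed = int(rng.integers(2**31))
        celltype_donors.setdefault(stratum.cell_type, set()).add(stratum.donor)
        geom = compute_stratum_geometry(
            stratum,
            n_components=cfg.n_components,
            r_threshold=cfg.r_threshold,
            drop_fraction=cfg.density_drop_fraction,
        )
        manifest_rows.append(
            {
                "stratum_id": sid,
                "donor": stratum.donor,
                "tissue": stratum.tissue,
                "cell_type": stratum.cell_type,
                "n_cells_original": stratum.n_cells_original,
                "n_cells_fit": int(geom.keep_mask.sum()),
                "n_retained_components": geom.pc.n_retained,
                "skipped": geom.skipped_reason or "",
            }
        )
        if geom.skipped_reason:
            logger.warning("stage=fit stratum=%s skipped: %s", sid, geom.skipped_reason)
            continue
        try:
            fit = sweep_dimensions(
                geom.pc.scores,
                stratum_id=sid,
                dims=cfg.dims,
                alpha=cfg.alpha,
                n_shuffles=cfg.n_shuffles,
                seed=stratum_seed,
                n_restarts_test=cfg.n_restarts_test,
                n_restarts_final=cfg.n_restarts_final,
            )
        except ValueError as e:
            raise RuntimeError(f"stage=fit stratum={sid}: {e}") from e
        fits[sid] = fit
        celltype_records.setdefault(stratum.cell_type, []).append(
            {
                "donor": stratum.donor,
                "tissue": stratum.tissue,
                "p_values": [p for _, _, p in fit.all_p_values],
            }
        )
        logger.info(
            "stage=fit stratum=%s d=%d k=%d p=%.4g significant=%s",
            sid, fit.dimension, fit.n_vertices, fit.p_value, fit.significant,
        )
        if fit.significant:
            if cfg.n_boot > 0:
                fit.bootstrap, _ = bootstrap_vertices(
                    geom.pc.scores[:, : fit.dimension],
                    fit.n_vertices,
                    n_boot=cfg.n_boot,
                    seed=stratum_seed + 1,
                    reference=fit.vertices,
                )
            X_all_kept = stratum.X_all[geom.keep_mask]
            enrichment[sid] = enrich_fit(
                geom.pc.scores[:, : fit.dimension],
                fit.vertices,
                X_all_kept,
                stratum.all_gene_ids,
                stratum_id=sid,
                bin_fraction=cfg.bin_fraction,
                fdr_cap=cfg.enrichment_fdr_cap,
            )
            stratum_data[sid] = {
                "scores": geom.pc.scores[:, : fit.dimension],
                "vertices": fit.vertices,
                "X_all": X_all_kept,
                "gene_ids": list(stratum.all_gene_ids),
                "donor": stratum.donor,
                "tissue": stratum.tissue,
                "cell_type": stratum.cell_type,
            }
        fit_rows.append(
            {
                "stratum_id": sid,
                "cell_type": stratum.cell_type,
                "donor": stratum.donor,
                "tissue": stratum.tissue,
                "dimension": fit.dimension,
                "n_vertices": fit.n_vertices,
                "t_ratio": fit.t_ratio,
                "statistic": fit.statistic,
                "p_value": fit.p_value,
                "significant": fit.significant,
                "pct_inside": fit.pct_inside,
                "n_p_values": len(fit.all_p_values),
                "mean_pct_mito": float(stratum.pct_mito[geom.keep_mask].mean()),
                "mean_pct_artifact": float(stratum.pct_artifact[geom.keep_mask].mean()),
            }
        )

    manifest = pd.DataFrame(manifest_rows)
    fits_table = pd.DataFrame(fit_rows)

    summary, fdr_cdf = aggregate_cell_types(
        celltype_records, alpha=cfg.alpha, fdr_cap=cfg.celltype_fdr_cap
    ) if celltype_records else (pd.DataFrame(), pd.DataFrame())

    clusters: dict[str, list[ArchetypeCluster]] = {}
    archetype_rows = []
    profile_matrices: dict[str, pd.DataFrame] = {}
    accepted_types = set(summary[summary.get("accepted", False) == True]["cell_type"]) if len(summary) else set()
    for cell_type in sorted(accepted_types):
        nodes = []
        for sid, table in sorted(enrichment.items()):
            data = stratum_data[sid]
            if data["cell_type"] != cell_type:
                continue
            for v in range(data["vertices"].shape[0]):
                nodes.append(
                    VertexNode(
                        stratum_id=sid,
                        vertex_index=v,
                        donor=data["donor"],
                        tissue=data["tissue"],
                        markers=tuple(top_markers(table, v, fdr_cap=cfg.enrichment_fdr_cap)),
                    )
                )
        cts, _excluded = align_cell_type(
            nodes,
            cell_type,
            donors_available=len(celltype_donors[cell_type]),
            coverage_threshold=cfg.coverage_threshold,
            seed=cfg.seed,
        )
        clusters[cell_type] = cts
        for c in cts:
            archetype_rows.append(
                {
                    "cell_type": cell_type,
                    "cluster_id": c.cluster_id,
                    "n_members": len(c.members),
                    "donor_coverage": c.donor_coverage,
                    "accepted": c.accepted,
                    "annotation": c.annotation,
                    "members": ";".join(m.node_id for m in c.members),
                    "consensus_genes": ";".join(f"{g}:{f}" for g, f in c.consensus_genes),
                }
            )
        if any(c.accepted for c in cts):
            profile_matrices[cell_type] = archetype_profile_matrix(
                cts, stratum_data, cfg.closest_fraction
            )
    archetype_table = pd.DataFrame(archetype_rows)

    qc_report = qc_significance_report(fits_table)

    result = PipelineResult(
        config=cfg,
        qc_log=qc_log,
        manifest=manifest,
        fits=fits,
        fits_table=fits_table,
        enrichment=enrichment,
        celltype_summary=summary,
        fdr_cdf=fdr_cdf,
        clusters=clusters,
        archetype_table=archetype_table,
        profile_matrices=profile_matrices,
        qc_report=qc_report,
        stratum_data=stratum_data,
    )
    if outdir is not None:
        write_result(result, outdir)
    return result


def qc_significance_report(fits_table: pd.DataFrame) -> pd.DataFrame:
    """Correlations of per-stratum QC summaries with fit outcomes.

    Pearson and Spearman r of each QC metric against the fit p-value and the
    percent of cells inside the fitted polytope; constant columns are
    reported as not-applicable (NaN).
    """
    if len(fits_table) < 3:
        return pd.DataFrame(
            columns=["metric", "against", "pearson_r", "spearman_r", "note"]
        )
    metrics = ["mean_pct_mito", "mean_pct_artifact"]
    if "n_cells_fit" in fits_table.columns:
        metrics.append("n_cells_fit")
    rows = []
    for against in ("p_value", "pct_inside"):
        y = fits_table[against].to_numpy(float)
        for m in metrics:
            if m not in fits_table.columns:
                continue
            x = fits_table[m].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            note = ""
            if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                pr = sr = float("nan")
                note = "not-applicable (constant or insufficient)"
            else:
                pr = float(pearsonr(x[ok], y[ok])[0])
                sr = float(spearmanr(x[ok], y[ok])[0])
            rows.append(
                {"metric": m, "against": against, "pearson_r": pr, "spearman_r": sr, "note": note}
            )
    return pd.DataFrame(rows)


def write_result(result: PipelineResult, outdir) -> None:
    """Write every stage artifact as TSV/JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.config.to_file(outdir / "config.yaml")
    result.manifest.to_csv(outdir / "strata_manifest.tsv", sep="\t", index=False)
    result.fits_table.to_csv(outdir / "fits.tsv", sep="\t", index=False)
    result.celltype_summary.to_csv(outdir / "celltype_summary.tsv", sep="\t", index=False)
    result.fdr_cdf.to_csv(outdir / "fdr_cdf.tsv", sep="\t", index=False)
    result.archetype_table.to_csv(outdir / "archetypes.tsv", sep="\t", index=False)
    result.qc_report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    if result.enrichment:
        pd.concat([e.table for _, e in sorted(result.enrichment.items())]).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False
        )
    for cell_type, mat in result.profile_matrices.items():
        safe = cell_type.replace("/", "_").replace(" ", "_")
        mat.to_csv(outdir / f"profiles_{safe}.tsv", sep="\t")
    fit_json = {
        sid: {
            "dimension": f.dimension,
            "n_vertices": f.n_vertices,
            "vertices": np.asarray(f.vertices).tolist(),
            "ev_curve": {str(k): v for k, v in f.ev_curve.items()},
            "t_ratio": f.t_ratio,
            "statistic": f.statistic,
            "p_value": f.p_value,
            "significant": bool(f.significant),
            "pct_inside": f.pct_inside,
            "all_p_values": [[int(d), int(k), p] for d, k, p in f.all_p_values],
        }
        for sid, f in sorted(result.fits.items())
    }
    (outdir / "fits.json").write_text(json.dumps(fit_json, indent=1, sort_keys=True))
    (outdir / "qc_log.json").write_text(json.dumps(result.qc_log, indent=1, sort_keys=True))
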