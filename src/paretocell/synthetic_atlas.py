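"""Synthetic single-cell atlases with planted archetypal (simplex) structure.

Cells of a polytopal cell type are convex mixtures of k archetype expression
profiles (mixture weights ~ Dirichlet), with planted marker genes elevated at
exactly one archetype, per-cell library-size variation, and Poisson or
negative-binomial count noise. Null cell types have mutually independent
genes (log-normal rate -> Poisson) and no low-dimensional structure. Donor x
tissue replicate strata of a cell type share the archetype/marker identity
(optionally with per-stratum vertex jitter), so cross-replicate alignment is
testable against planted truth. A configurable fraction of cells receives
inflated mitochondrial/artifact counts to exercise the QC filters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .atlas_io_qc import ExpressionAtlas, write_atlas as _write_counts

__all__ = [
    "ArchetypeSpec",
    "PlantedTruth",
    "AtlasTruth",
    "random_archetype_spec",
    "generate_stratum",
    "generate_null_stratum",
    "generate_simplex_cloud",
    "generate_marker_lists",
    "generate_atlas",
    "write_synthetic_atlas",
]

#: inflation applied to mito/artifact counts of contaminated cells
QC_INFLATION_FACTOR = 20.0


@dataclass
class ArchetypeSpec:
    """Generative description of one polytopal cell type.

    ``vertex_profiles`` holds the mean linear-scale expression of each
    archetype (k x genes); ``marker_genes`` lists, per archetype, the gene
    indices whose profile entry was fold-elevated at that archetype (each
    marker belongs to exactly one archetype). ``dirichlet_alpha`` is the
    symmetric concentration of the per-cell mixture weights. ``noise_model``
    is "poisson", "negative_binomial" (with ``nb_dispersion`` > 0; variance
    mu + dispersion * mu^2) or "none" (deterministic expectation, used only
    for degenerate-limit checks). ``library_size_sigma`` is the sigma of the
    log-normal per-cell size factor later removed by normalization.
    """

    n_archetypes: int
    vertex_profiles: np.ndarray
    marker_genes: tuple = ()
    dirichlet_alpha: float = 0.65
    noise_model: str = "poisson"
    nb_dispersion: float = 0.5
    library_size_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.vertex_profiles = np.asarray(self.vertex_profiles, float)
        k = self.n_archetypes
        if k < 2:
            raise ValueError("need at least 2 archetypes")
        if self.vertex_profiles.shape[0] != k:
            raise ValueError("vertex_profiles must have n_archetypes rows")
        if k > self.vertex_profiles.shape[1]:
            raise ValueError("more archetypes than genes")
        if (self.vertex_profiles < 0).any():
            raise ValueError("vertex_profiles must be non-negative")
        if (self.vertex_profiles.sum(axis=1) <= 0).any():
            raise ValueError("each vertex profile must have positive total expression")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")
        if self.noise_model not in ("poisson", "negative_binomial", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_model == "negative_binomial" and self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        seen: set[int] = set()
        for genes in self.marker_genes:
            for g in genes:
                if g in seen:
                    raise ValueError(f"marker gene {g} assigned to more than one archetype")
                seen.add(g)

    @property
    def n_genes(self) -> int:
        return self.vertex_profiles.shape[1]


@dataclass
class PlantedTruth:
    """Ground truth for one generated stratum (parameter-recovery oracle)."""

    vertex_profiles: np.ndarray
    weights: np.ndarray          # cells x k convex mixture weights
    marker_genes: tuple
    polytopal: bool


def random_archetype_spec(
    n_archetypes: int,
    n_genes: int,
    markers_per_archetype: int = 10,
    marker_fold: float = 4.0,
    base_log_mean: float = 0.7,
    base_log_sigma: float = 0.8,
    seed: int = 0,
    **kwargs,
) -> ArchetypeSpec:
    """Draw a random spec: log-normal base profiles, fold-elevated markers.

    Marker elevation multiplies the vertex-profile entry (scale-free effect
    size); marker blocks of different archetypes are disjoint.
    """
    if marker_fold <= 1:
        raise ValueError("marker_fold must exceed 1")
    if markers_per_archetype * n_archetypes > n_genes:
        raise ValueError("not enough genes for disjoint marker blocks")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(base_log_mean, base_log_sigma, size=n_genes)
    profiles = np.tile(base, (n_archetypes, 1))
    marker_pool = rng.permutation(n_genes)[: markers_per_archetype * n_archetypes]
    markers = []
    for a in range(n_archetypes):
        genes = np.sort(marker_pool[a * markers_per_archetype : (a + 1) * markers_per_archetype])
        profiles[a, genes] *= marker_fold
        markers.append(tuple(int(g) for g in genes))
    return ArchetypeSpec(
        n_archetypes=n_archetypes,
        vertex_profiles=profiles,
        marker_genes=tuple(markers),
        seed=seed,
        **kwargs,
    )


def _draw_counts(mean: np.ndarray, spec: ArchetypeSpec, rng) -> np.ndarray:
    if spec.noise_model == "poisson":
        return rng.poisson(mean)
    if spec.noise_model == "negative_binomial":
        # gamma-poisson mixture: var = mu + dispersion * mu^2
        shape = 1.0 / spec.nb_dispersion
        lam = rng.gamma(shape, np.maximum(mean, 1e-300) / shape)
        return rng.poisson(np.where(mean > 0, lam, 0.0))
    return np.rint(mean).astype(np.int64)  # "none": deterministic limit


def generate_stratum(
    n_cells: int,
    n_genes: int,
    spec: ArchetypeSpec,
    seed: int | None = None,
    weights: np.ndarray | None = None,
) -> tuple[sp.csr_matrix, PlantedTruth]:
    """Generate one polytopal stratum: counts (cells x genes) plus truth.

    Cell i's expected expression is ``size_i * sum_a w_ia * vertex_profiles[a]``;
    ``weights`` overrides the Dirichlet draw (rows must be convex weights).
    Deterministic given the seed (defaults to ``spec.seed``).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if n_genes != spec.n_genes:
        raise ValueError("n_genes does not match spec.vertex_profiles")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    k = spec.n_archetypes
    if weights is None:
        weights = rng.dirichlet(np.full(k, spec.dirichlet_alpha), size=n_cells)
    else:
        weights = np.asarray(weights, float)
        if weights.shape != (n_cells, k):
            raise ValueError("weights must be cells x n_archetypes")
        if (weights < 0).any() or np.abs(weights.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("weight rows must be convex combinations")
    mean = weights @ spec.vertex_profiles
    if spec.library_size_sigma > 0 and spec.noise_model != "none":
        mean = mean * rng.lognormal(0.0, spec.library_size_sigma, size=n_cells)[:, None]
    counts = sp.csr_matrix(_draw_counts(mean, spec, rng))
    truth = PlantedTruth(
        vertex_profiles=spec.vertex_profiles.copy(),
        weights=weights,
        marker_genes=spec.marker_genes,
        polytopal=True,
    )
    return counts, truth


def generate_null_stratum(n_cells: int, n_genes: int, seed: int = 0) -> sp.csr_matrix:
    """Stratum with mutually independent genes and no planted polytope.

    Per-gene rates are log-normal (mu=0.5, sigma=1), counts Poisson i.i.d.
    across cells, so gene-gene correlations are null.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    rates = rng.lognormal(0.5, 1.0, size=n_genes)
    return sp.csr_matrix(rng.poisson(np.tile(rates, (n_cells, 1))))


def generate_simplex_cloud(
    n_points: int,
    vertices: np.ndarray,
    dirichlet_alpha: float = 0.65,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Points near a simplex in geometric (PC-like) space: W @ V + Gaussian noise.

    Returns (points, weights); used for direct parameter-recovery experiments
    on the fitting engine without the count layer.
    """
    rng = np.random.default_rng(seed)
    vertices = np.asarray(vertices, float)
    k = vertices.shape[0]
    weights = rng.dirichlet(np.full(k, dirichlet_alpha), size=n_points)
    points = weights @ vertices
    if noise_sigma > 0:
        points = points + rng.normal(0.0, noise_sigma, size=points.shape)
    return points, weights


def generate_marker_lists(
    n_archetypes: int,
    donors: list[str],
    tissues: list[str],
    gene_pool: int = 500,
    markers_per_archetype: int = 10,
    noise_fraction: float = 0.0,
    seed: int = 0,
) -> list[dict]:
    """Synthetic per-vertex marker lists replicated across donor-tissues.

    Emulates the alignment input: one vertex node per (donor, tissue,
    archetype) carrying the archetype's marker list, with ``noise_fraction``
    of each list's genes scrambled to random pool genes. Returns dicts with
    keys stratum_id, vertex_index, donor, tissue, markers, archetype (truth).
    """
    rng = np.random.default_rng(seed)
    blocks = rng.permutation(gene_pool)[: n_archetypes * markers_per_archetype]
    truth_lists = [
        sorted(int(g) for g in blocks[a * markers_per_archetype : (a + 1) * markers_per_archetype])
        for a in range(n_archetypes)
    ]
    n_noise = int(round(noise_fraction * markers_per_archetype))
    nodes = []
    for donor in donors:
        for tissue in tissues:
            order = rng.permutation(n_archetypes)  # vertex indexing varies per stratum
            for v, a in enumerate(order):
                genes = list(truth_lists[a])
                if n_noise:
                    swap = rng.choice(markers_per_archetype, size=n_noise, replace=False)
                    for s in swap:
                        genes[s] = int(rng.integers(gene_pool))
                nodes.append(
                    {
                        "stratum_id": f"{donor}|{tissue}",
                        "vertex_index": v,
                        "donor": donor,
                        "tissue": tissue,
                        "markers": [f"G{g:05d}" for g in dict.fromkeys(genes)],
                        "archetype": int(a),
                    }
                )
    return nodes


# ---------------------------------------------------------------------------
# whole-atlas generation
# ---------------------------------------------------------------------------


@dataclass
class StratumTruth:
    donor: str
    tissue: str
    cell_type: str
    polytopal: bool
    n_cells: int
    n_archetypes: int
    marker_gene_ids: tuple
    truth: PlantedTruth | None


@dataclass
class AtlasTruth:
    """Planted truth for a whole synthetic atlas."""

    strata: list = field(default_factory=list)
    polytopal_cell_types: tuple = ()
    null_cell_types: tuple = ()

    def to_json(self, path) -> None:
        payload = {
            "polytopal_cell_types": list(self.polytopal_cell_types),
            "null_cell_types": list(self.null_cell_types),
            "strata": [
                {
                    "donor": s.donor,
                    "tissue": s.tissue,
                    "cell_type": s.cell_type,
                    "polytopal": s.polytopal,
                    "n_cells": s.n_cells,
                    "n_archetypes": s.n_archetypes,
                    "marker_gene_ids": [list(m) for m in s.marker_gene_ids],
                }
                for s in self.strata
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _jitter_spec(spec: ArchetypeSpec, jitter: float, rng) -> ArchetypeSpec:
    if jitter <= 0:
        return spec
    profiles = spec.vertex_profiles * np.exp(
        rng.normal(0.0, jitter, size=spec.vertex_profiles.shape)
    )
    return ArchetypeSpec(
        n_archetypes=spec.n_archetypes,
        vertex_profiles=profiles,
        marker_genes=spec.marker_genes,
        dirichlet_alpha=spec.dirichlet_alpha,
        noise_model=spec.noise_model,
        nb_dispersion=spec.nb_dispersion,
        library_size_sigma=spec.library_size_sigma,
        seed=spec.seed,
    )


def generate_atlas(
    n_donors: int,
    n_tissues: int,
    cell_types: dict,
    qc_contamination: float = 0.0,
    cells_per_stratum: tuple[int, int] = (200, 600),
    n_mito_genes: int = 10,
    n_artifact_genes: int = 10,
    n_noncoding_genes: int = 5,
    vertex_jitter: float = 0.05,
    seed: int = 0,
) -> tuple[ExpressionAtlas, AtlasTruth]:
    """Assemble a donor x tissue x cell-type atlas with planted truth.

    ``cell_types`` maps name -> :class:`ArchetypeSpec` (polytopal) or ``None``
    (null); at least one cell type must be null so the pipeline's specificity
    is always exercised. All specs must share the same protein-coding gene
    count; a cell type keeps its archetype/marker identity across donors and
    tissues (with per-stratum multiplicative ``vertex_jitter`` on profiles).
    Flagged mito/artifact genes (plus a few non-coding genes) are appended to
    the gene universe with baseline expression; a ``qc_contamination``
    fraction of cells per stratum gets those counts inflated 20-fold.
    Per-stratum seeds derive deterministically from the atlas seed.
    """
    if n_donors < 1:
        raise ValueError("need at least one donor")
    if not 0 <= qc_contamination <= 1:
        raise ValueError("qc_contamination must be in [0, 1]")
    lo, hi = cells_per_stratum
    if not (50 <= lo <= hi <= 2000):
        raise ValueError("cells_per_stratum must lie within [50, 2000]")
    specs = {name: s for name, s in cell_types.items() if s is not None}
    if len(specs) == len(cell_types):
        raise ValueError("at least one cell type must be null (spec None)")
    widths = {s.n_genes for s in specs.values()}
    if len(widths) > 1:
        raise ValueError("all specs must share the same number of protein-coding genes")
    n_pc = widths.pop() if widths else 300

    rng = np.random.default_rng(seed)
    seed_counter = int(rng.integers(2**31 - 10**6))  # per-stratum seed base

    n_extra = n_mito_genes + n_artifact_genes + n_noncoding_genes
    gene_ids = (
        [f"G{i:05d}" for i in range(n_pc)]
        + [f"MT-{i}" for i in range(n_mito_genes)]
        + [f"ART-{i}" for i in range(n_artifact_genes)]
        + [f"NC-{i}" for i in range(n_noncoding_genes)]
    )
    gene_meta = pd.DataFrame(
        {
            "is_protein_coding": [True] * (n_pc + n_mito_genes + n_artifact_genes)
            + [False] * n_noncoding_genes,
            "is_mitochondrial": [False] * n_pc + [True] * n_mito_genes
            + [False] * (n_artifact_genes + n_noncoding_genes),
            "is_artifact": [False] * (n_pc + n_mito_genes) + [True] * n_artifact_genes
            + [False] * n_noncoding_genes,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    extra_rates = rng.lognormal(0.0, 0.5, size=n_extra)  # modest baseline mito/artifact/nc rates

    blocks, meta_rows, truth = [], [], AtlasTruth(
        polytopal_cell_types=tuple(sorted(specs)),
        null_cell_types=tuple(sorted(set(cell_types) - set(specs))),
    )
    cell_counter = 0
    for d in range(n_donors):
        donor = f"D{d + 1}"
        for t in range(n_tissues):
            tissue = f"T{t + 1}"
            for name in sorted(cell_types):
                seed_counter += 1
                srng = np.random.default_rng(seed_counter)
                n_cells = int(srng.integers(lo, hi + 1))
                spec = cell_types[name]
                if spec is None:
                    pc_counts = generate_null_stratum(n_cells, n_pc, seed=seed_counter)
                    planted, k, marker_ids = None, 0, ()
                else:
                    jittered = _jitter_spec(spec, vertex_jitter, srng)
                    pc_counts, planted = generate_stratum(
                        n_cells, n_pc, jittered, seed=seed_counter
                    )
                    k = spec.n_archetypes
                    marker_ids = tuple(
                        tuple(gene_ids[g] for g in genes) for genes in spec.marker_genes
                    )
                extra = srng.poisson(np.tile(extra_rates, (n_cells, 1))).astype(float)
                if qc_contamination > 0:
                    n_bad = int(round(qc_contamination * n_cells))
                    if n_bad:
                        bad = srng.choice(n_cells, size=n_bad, replace=False)
                        flagged = n_mito_genes + n_artifact_genes
                        extra[np.ix_(bad, np.arange(flagged))] *= QC_INFLATION_FACTOR
                block = sp.hstack(
                    [pc_counts, sp.csr_matrix(np.rint(extra).astype(np.int64))]
                ).tocsr()
                blocks.append(block)
                for _ in range(n_cells):
                    meta_rows.append((f"cell{cell_counter:07d}", donor, tissue, name))
                    cell_counter += 1
                truth.strata.append(
                    StratumTruth(
                        donor=donor,
                        tissue=tissue,
                        cell_type=name,
                        polytopal=spec is not None,
                        n_cells=n_cells,
                        n_archetypes=k,
                        marker_gene_ids=marker_ids,
                        truth=planted,
                    )
                )
    counts = sp.vstack(blocks).tocsr()
    cell_meta = pd.DataFrame(
        meta_rows, columns=["cell_id", "donor", "tissue", "cell_type"]
    ).set_index("cell_id")
    return ExpressionAtlas(counts, cell_meta, gene_meta), truth


def write_synthetic_atlas(atlas: ExpressionAtlas, truth: AtlasTruth, outdir) -> None:
    """Write matrix.mtx + cells.tsv + genes.tsv + truth.json."""
    outdir = Path(outdir)
    _write_counts(atlas, outdir)
    truth.to_json(outdir / "truth.json")
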