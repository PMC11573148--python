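"""Synthetic paired single-cell / bulk RNA-seq data with planted ground truth.

The generator encodes the data-generating assumption the whole package
rests on: a bulk (whole-organ) RNA-seq profile is the mixture of its
composite cell types, weighted by both their abundance (the cell-type
ratios) and their relative transcriptome sizes — the total mRNA content
per cell. Per-cell CPM normalization of the single-cell data destroys
the size information, which is exactly what the weighting factors must
recover.

Concretely, each cell type ``k`` receives

* a CPM-scale expression profile ``profile_k`` with a planted block of
  marker genes strongly enriched in that type,
* a relative transcriptome size ``s_k`` (dimensionless),
* a true abundance ``ratio_k`` on the simplex.

Cells of type ``k`` are drawn with sequencing depth proportional to
``s_k`` (Poisson or negative-binomial counts) and then CPM-normalized.
Bulk replicates are the size- and ratio-weighted mixture
``sum_k ratio_k * s_k * profile_k`` perturbed by multiplicative
log-normal noise and CPM-normalized. Optionally a fraction of genes per
type is "cryptic": activated in the dissociated single cells but absent
from the intact-tissue bulk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import (
    BulkReplicates,
    CellAnnotation,
    CountMatrix,
    ReferenceRatios,
    cpm_normalize,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_dataset", "simulate_stage_cwfs"]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic organ.

    Defaults describe a small but realistic solid-organ fixture: four
    cell types with four-fold spread in transcriptome size, distinct
    marker blocks, moderate bulk replicate noise and 10x-like
    per-cell depths.
    """

    n_types: int = 4
    n_genes: int = 300
    cells_per_type: Sequence[int] = (200, 200, 200, 200)
    true_sizes: Sequence[float] = (1.0, 2.0, 4.0, 8.0)
    true_ratios: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    markers_per_type: int = 10
    marker_fold: float = 20.0
    noise_cv: float = 0.05
    n_bulk_replicates: int = 3
    cryptic_fraction: float = 0.0
    base_depth: float = 20_000.0
    count_model: str = "poisson"  # "poisson" | "nb" | "exact"
    nb_dispersion: float = 0.1
    profile_lognorm_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1 or self.n_genes < 1:
            raise ValueError("n_types and n_genes must be positive")
        if len(self.cells_per_type) != self.n_types:
            raise ValueError("cells_per_type length must equal n_types")
        if len(self.true_sizes) != self.n_types:
            raise ValueError("true_sizes length must equal n_types")
        if len(self.true_ratios) != self.n_types:
            raise ValueError("true_ratios length must equal n_types")
        if any(s <= 0 for s in self.true_sizes):
            raise ValueError("true transcriptome sizes must be positive")
        ratios = np.asarray(self.true_ratios, dtype=float)
        if np.any(ratios < 0) or abs(ratios.sum() - 1.0) > 1e-9:
            raise ValueError("true_ratios must lie on the probability simplex")
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValueError("marker blocks exceed the gene count")
        if self.count_model not in {"poisson", "nb", "exact"}:
            raise ValueError(f"unknown count_model {self.count_model!r}")


@dataclass
class GroundTruth:
    """Planted quantities the estimators are scored against."""

    sizes: dict[str, float]
    ratios: dict[str, float]
    markers: dict[str, list[str]]
    profiles: "np.ndarray"  # genes x types, CPM scale
    cell_types: list[str]
    gene_ids: list[str]
    cryptic_genes: dict[str, list[str]]
    profile_condition_number: float


def _type_profiles(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """CPM-scale expression profiles (genes x types) with marker blocks."""
    baseline = rng.gamma(shape=2.0, scale=1.0, size=cfg.n_genes) + 0.05
    jitter = rng.lognormal(0.0, cfg.profile_lognorm_sd, size=(cfg.n_genes, cfg.n_types))
    profiles = baseline[:, None] * jitter
    for k in range(cfg.n_types):
        block = slice(k * cfg.markers_per_type, (k + 1) * cfg.markers_per_type)
        profiles[block, :] *= 0.05
        profiles[block, k] *= cfg.marker_fold / 0.05
    return profiles / profiles.sum(axis=0, keepdims=True) * 1e6


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, CellAnnotation, BulkReplicates, GroundTruth]:
    """Generate a CPM-normalized single-cell matrix, its annotation, matched
    bulk replicates and the planted ground truth."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    types = [f"type{k}" for k in range(cfg.n_types)]
    profiles = _type_profiles(cfg, rng)

    markers = {
        types[k]: genes[k * cfg.markers_per_type : (k + 1) * cfg.markers_per_type]
        for k in range(cfg.n_types)
    }

    # cryptic genes: dissociation-induced expression seen only in single cells
    sc_profiles = profiles.copy()
    cryptic: dict[str, list[str]] = {t: [] for t in types}
    if cfg.cryptic_fraction > 0:
        n_cryptic = int(round(cfg.cryptic_fraction * cfg.n_genes))
        free = np.arange(cfg.n_types * cfg.markers_per_type, cfg.n_genes)
        for k in range(cfg.n_types):
            chosen = rng.choice(free, size=min(n_cryptic, free.size), replace=False)
            sc_profiles[chosen, k] += profiles[:, k].mean() * 5.0
            cryptic[types[k]] = [genes[i] for i in chosen]

    # single cells: depth proportional to transcriptome size, then CPM
    columns, cell_ids, labels = [], [], {}
    for k, cell_type in enumerate(types):
        p = sc_profiles[:, k] / sc_profiles[:, k].sum()
        depth = cfg.base_depth * cfg.true_sizes[k]
        for c in range(cfg.cells_per_type[k]):
            cell = f"{cell_type}_c{c:04d}"
            if cfg.count_model == "exact":
                counts = p * depth
            elif cfg.count_model == "poisson":
                counts = rng.poisson(p * depth).astype(float)
            else:  # negative binomial via gamma-Poisson mixture
                lam = rng.gamma(1.0 / cfg.nb_dispersion, cfg.nb_dispersion * p * depth)
                counts = rng.poisson(lam).astype(float)
            if counts.sum() <= 0:  # pragma: no cover - astronomically unlikely
                counts = p * depth
            columns.append(counts)
            cell_ids.append(cell)
            labels[cell] = cell_type
    sc = CountMatrix(tuple(genes), tuple(cell_ids), np.column_stack(columns), False)
    sc = cpm_normalize(sc)

    # bulk replicates: size- and ratio-weighted mixture of intact-tissue profiles
    mixture = profiles @ (
        np.asarray(cfg.true_ratios, dtype=float) * np.asarray(cfg.true_sizes, dtype=float)
    )
    reps = []
    for _ in range(cfg.n_bulk_replicates):
        if cfg.noise_cv > 0:
            sigma = np.sqrt(np.log1p(cfg.noise_cv**2))
            noise = rng.lognormal(-(sigma**2) / 2.0, sigma, size=cfg.n_genes)
        else:
            noise = 1.0
        reps.append(mixture * noise)
    bulk = BulkReplicates(
        tuple(genes),
        tuple(f"bulk_rep{i}" for i in range(cfg.n_bulk_replicates)),
        np.column_stack(reps),
        False,
    )
    bulk = cpm_normalize(bulk)

    truth = GroundTruth(
        sizes=dict(zip(types, map(float, cfg.true_sizes))),
        ratios=dict(zip(types, map(float, cfg.true_ratios))),
        markers=markers,
        profiles=profiles,
        cell_types=types,
        gene_ids=genes,
        cryptic_genes=cryptic,
        profile_condition_number=float(np.linalg.cond(profiles)),
    )
    return sc, CellAnnotation(labels), bulk, truth


def simulate_stage_cwfs(
    n_types: int = 4,
    stages: Sequence[str] = ("3mo", "18mo", "24mo"),
    cwfs_per_type: int = 60,
    shifted_type: int = 0,
    shift_per_stage: float = 0.5,
    sigma: float = 0.15,
    seed: int = 0,
) -> tuple[dict[str, dict[str, np.ndarray]], str]:
    """Per-stage weighting-factor samples with one planted aging trend.

    Every type draws log-normal weighting factors around a stage-constant
    mean except ``shifted_type``, whose log-mean increases by
    ``shift_per_stage`` per stage — so every pairwise ratio involving that
    type shifts across stages while all other pairs stay put. Returns
    ``{stage: {cell_type: samples}}`` and the shifted type's name.
    """
    rng = np.random.default_rng(seed)
    types = [f"type{k}" for k in range(n_types)]
    base_mu = rng.uniform(-0.3, 0.3, size=n_types)
    out: dict[str, dict[str, np.ndarray]] = {}
    for s_idx, stage in enumerate(stages):
        stage_vals: dict[str, np.ndarray] = {}
        for k, cell_type in enumerate(types):
            mu = base_mu[k] + (shift_per_stage * s_idx if k == shifted_type else 0.0)
            stage_vals[cell_type] = rng.lognormal(mu, sigma, size=cwfs_per_type)
        out[stage] = stage_vals
    return out, types[shifted_type]
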