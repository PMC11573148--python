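"""Estimation of cell type-specific weighting factors (cWFs).

A cWF is a non-negative per-cell coefficient ``w_j`` scaling that cell's
CPM profile so that a ratio-preserving random combination of single
cells reconstitutes the bulk (whole-organ) profile:

    m * y_i  ~=  sum_j  w_j * x_j      (j in a combination C^m)

where ``y_i`` is a CPM bulk replicate, ``x_j`` a CPM single-cell profile
restricted to the signature genes, and ``m`` the combination size. Each
round draws a combination honoring the reference cell-type ratios (with
at least one cell per type) and solves the non-negative least-squares
problem

    argmin_{w >= 0}  sum_i || m*y_i - sum_j w_j x_j ||^2 .

Rounds repeat until every cell in the sampling pool has accumulated more
than ``min_samples`` weighting factors; per-cell Gaussian summaries
(mean, unbiased variance) then feed the Bayesian deconvolution priors.
Because per-cell normalization erased the transcriptome size, the cWFs
recover it (relatively, within one organ and bulk dataset).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import nnls

from .data_model import BulkReplicates, CellAnnotation, CountMatrix, ReferenceRatios
from .signatures import SignatureGeneSet

__all__ = [
    "SubjectCombination",
    "CWFSet",
    "apportion_quotas",
    "sample_subject_combination",
    "solve_weights",
    "estimate_cwfs",
    "summarize_per_type",
]

NEGATIVITY_TOL = 1e-9


@dataclass(frozen=True)
class SubjectCombination:
    """An ordered draw of cell identifiers honoring the reference ratios."""

    subjects: tuple[str, ...]
    quotas: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("combination contains duplicate subjects")
        object.__setattr__(self, "quotas", dict(self.quotas))

    @property
    def m(self) -> int:
        return len(self.subjects)


@dataclass
class CWFSet:
    """Sampled weighting factors per cell, with Gaussian summaries."""

    samples: dict[str, np.ndarray]
    cell_types: dict[str, str]

    def __post_init__(self) -> None:
        self.samples = {s: np.asarray(v, dtype=float) for s, v in self.samples.items()}
        for subject, values in self.samples.items():
            if np.any(values < 0):
                raise ValueError(f"negative weighting factor for {subject}")
            if subject not in self.cell_types:
                raise ValueError(f"subject {subject} lacks a cell-type label")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.samples.keys())

    def mean(self, subject: str) -> float:
        return float(self.samples[subject].mean())

    def variance(self, subject: str) -> float:
        """Unbiased (n-1) sample variance of the subject's cWFs."""
        values = self.samples[subject]
        return float(values.var(ddof=1)) if values.size > 1 else 0.0

    def pooled_by_type(self) -> dict[str, np.ndarray]:
        pools: dict[str, list[np.ndarray]] = {}
        for subject, values in self.samples.items():
            pools.setdefault(self.cell_types[subject], []).append(values)
        return {t: np.concatenate(v) for t, v in pools.items()}

    def type_means(self) -> dict[str, float]:
        return {t: float(v.mean()) for t, v in self.pooled_by_type().items()}


# ---------------------------------------------------------------------------
# ratio-preserving combination sampling
# ---------------------------------------------------------------------------

def apportion_quotas(ratios: ReferenceRatios, m: int) -> dict[str, int]:
    """Integer per-type quotas: largest-remainder apportionment of
    ``m * ratio`` with a floor of one cell per type.

    Leftover slots go to the largest fractional remainders (ties to the
    larger ratio, then label order). If the floor forces a type up to
    one, the slot is taken from the currently largest quota.
    """
    types = ratios.cell_types
    if m < len(types):
        raise ValueError(f"m={m} is smaller than the number of cell types {len(types)}")
    raw = {t: m * ratios[t] for t in types}
    quotas = {t: int(np.floor(raw[t])) for t in types}
    leftover = m - sum(quotas.values())
    order = sorted(
        types, key=lambda t: (-(raw[t] - quotas[t]), -ratios[t], types.index(t))
    )
    for t in order[:leftover]:
        quotas[t] += 1
    for t in types:  # floor of 1: every type is represented
        while quotas[t] == 0:
            donor = max(types, key=lambda u: quotas[u])
            if quotas[donor] <= 1:
                raise ValueError("cannot honor one-cell-per-type floor")
            quotas[donor] -= 1
            quotas[t] += 1
    return quotas


def sample_subject_combination(
    annotation: CellAnnotation,
    ratios: ReferenceRatios,
    m: int = 100,
    rng: np.random.Generator | int | None = None,
    coverage: Mapping[str, int] | None = None,
) -> SubjectCombination:
    """Draw ``m`` cells without replacement, per-type counts at the
    ratio-apportioned quotas.

    With ``coverage`` (subject -> number of cWFs accumulated so far) the
    draw is biased to the least-covered cells of each type (random
    tie-break), which guarantees the accumulation loop terminates;
    without it the draw is uniform within type.
    """
    rng = np.random.default_rng(rng)
    quotas = apportion_quotas(ratios, m)
    chosen: list[str] = []
    for cell_type, quota in quotas.items():
        pool = annotation.cells_of_type(cell_type)
        if quota > len(pool):
            raise ValueError(
                f"quota {quota} for cell type {cell_type!r} exceeds its "
                f"{len(pool)} available cells; reduce m or merge labels"
            )
        if coverage is None:
            picks = rng.choice(len(pool), size=quota, replace=False)
            chosen.extend(pool[i] for i in picks)
        else:
            keys = rng.random(len(pool))
            ranked = sorted(
                range(len(pool)), key=lambda i: (coverage.get(pool[i], 0), keys[i])
            )
            chosen.extend(pool[i] for i in ranked[:quota])
    return SubjectCombination(tuple(chosen), quotas)


# ---------------------------------------------------------------------------
# the non-negative quadratic problem
# ---------------------------------------------------------------------------

def _subset_bulk(bulk: BulkReplicates, genes: Sequence[str]) -> BulkReplicates:
    index = {g: i for i, g in enumerate(bulk.gene_ids)}
    rows = [index[g] for g in genes]
    return BulkReplicates(tuple(genes), bulk.sample_ids, bulk.values[rows, :], False)

def solve_weights(
    bulk: BulkReplicates,
    subjects: SubjectCombination,
    sc: CountMatrix,
    signature: SignatureGeneSet | None = None,
) -> dict[str, float]:
    """Solve for the combination's weighting factors by NNLS.

    Minimizes ``sum_i || m*y_i - X w ||^2`` over ``w >= 0`` where the
    columns of ``X`` are the drawn cells' profiles on the signature
    genes. Summing squared residuals over replicates is equivalent to a
    single NNLS against ``m`` times the replicate-mean profile.
    """
    if signature is not None:
        sc = sc.subset_genes(signature.genes)
        bulk = _subset_bulk(bulk, signature.genes)
    if sc.gene_ids != bulk.gene_ids:
        raise ValueError("single-cell and bulk matrices are not gene-aligned")
    X = sc.subset_samples(subjects.subjects).values
    target = subjects.m * bulk.values.mean(axis=1)
    solution, _ = nnls(X, target)
    if np.any(solution < -NEGATIVITY_TOL):
        raise RuntimeError("NNLS returned a negative weighting factor")
    solution = np.clip(solution, 0.0, None)
    return dict(zip(subjects.subjects, solution.tolist()))


# ---------------------------------------------------------------------------
# the recursive accumulation loop
# ---------------------------------------------------------------------------

def estimate_cwfs(
    bulk: BulkReplicates,
    sc: CountMatrix,
    annotation: CellAnnotation,
    ratios: ReferenceRatios,
    signature: SignatureGeneSet,
    m: int = 100,
    min_samples: int = 100,
    rng_seed: int | np.random.Generator = 0,
    max_iterations: int | None = None,
) -> CWFSet:
    """Accumulate > ``min_samples`` weighting factors for every cell.

    The sampling pool is fixed up front as all annotated cells (each
    type's quota must not exceed its pool). Each round draws a
    ratio-preserving combination biased toward under-covered cells,
    solves the NNLS problem and appends each cell's solution to its
    sample list. Gaussian summaries are recomputable from the stored
    samples via :meth:`CWFSet.mean` / :meth:`CWFSet.variance`.
    """
    rng = np.random.default_rng(rng_seed)
    quotas = apportion_quotas(ratios, m)
    pool: dict[str, list[str]] = {}
    for cell_type, quota in quotas.items():
        cells = annotation.cells_of_type(cell_type)
        if quota > len(cells):
            raise ValueError(
                f"quota {quota} for cell type {cell_type!r} exceeds its "
                f"{len(cells)} available cells"
            )
        pool[cell_type] = cells
    pool_cells = [c for cells in pool.values() for c in cells]

    if max_iterations is None:
        worst = max(
            int(np.ceil(len(cells) * (min_samples + 1) / quotas[t]))
            for t, cells in pool.items()
        )
        max_iterations = 2 * worst + 10

    sc_sig = sc.subset_genes(signature.genes)
    bulk_sig = _subset_bulk(bulk, signature.genes)

    samples: dict[str, list[float]] = {c: [] for c in pool_cells}
    coverage = {c: 0 for c in pool_cells}
    for _ in range(max_iterations):
        combination = sample_subject_combination(
            annotation, ratios, m, rng, coverage=coverage
        )
        weights = solve_weights(bulk_sig, combination, sc_sig)
        for subject, w in weights.items():
            samples[subject].append(w)
            coverage[subject] += 1
        if min(coverage.values()) > min_samples:
            break
    else:
        short = min(coverage, key=coverage.get)
        raise RuntimeError(
            f"iteration budget {max_iterations} exhausted before every pooled "
            f"cell reached {min_samples} weighting factors (worst: {short} with "
            f"{coverage[short]}); restrict the pool or reduce min_samples"
        )

    return CWFSet(
        samples={c: np.asarray(v) for c, v in samples.items()},
        cell_types={c: annotation.label_of(c) for c in pool_cells},
    )


def summarize_per_type(cwfs: CWFSet) -> dict[str, dict[str, float]]:
    """Box-plot-ready per-type statistics pooled over that type's cells."""
    summary = {}
    for cell_type, values in cwfs.pooled_by_type().items():
        q1, median, q3 = np.percentile(values, [25, 50, 75])
        summary[cell_type] = {
            "mean": float(values.mean()),
            "q1": float(q1),
            "median": float(median),
            "q3": float(q3),
            "n": int(values.size),
        }
    return summary
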