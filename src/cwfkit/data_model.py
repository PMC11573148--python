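"""Core data containers and preprocessing for bulk / single-cell RNA-seq.

This module holds the shared currency of the package: count matrices
(genes x cells or genes x bulk replicates), cell-type annotations and
reference cell-type composition tables, together with the preprocessing
steps every downstream stage assumes:

* counts-per-million (CPM) normalization of each cell / replicate to 1e6,
* removal of spike-in (``ERCC-*``) and known artifact genes
  (``Rn45s``, ``Akap5``, ``Lrrc17``),
* merging of fine-grained cell-type labels into coarser classes via
  wildcard patterns,
* restriction of single-cell and bulk matrices to their common gene set,
* proportional re-adjustment of reference cell-type fractions when some
  fractions are pinned to externally known values (e.g. cardiomyocytes
  at 30% of the heart),
* an iterative zero-intercept linear filter that discards genes behaving
  inconsistently between two sequencing platforms.

Matrices are stored genes-as-rows throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse
from scipy.stats import pearsonr

__all__ = [
    "CountMatrix",
    "CellAnnotation",
    "ReferenceRatios",
    "BulkReplicates",
    "DEFAULT_EXCLUDED_GENES",
    "cpm_normalize",
    "filter_excluded_genes",
    "merge_cell_labels",
    "align_genes",
    "adjust_reference_ratios",
    "iterative_linear_gene_filter",
    "read_dense_counts",
    "read_mtx_counts",
    "write_dense_counts",
    "read_reference_ratios",
    "read_merge_map",
    "read_annotation",
]

CPM_TOTAL = 1_000_000.0

#: genes removed unconditionally before any analysis: rRNA-repeat and probe
#: artifacts that dominate total counts without being mRNA signal.
DEFAULT_EXCLUDED_GENES = frozenset({"Rn45s", "Akap5", "Lrrc17"})

#: spike-in prefix; any gene symbol starting with this is dropped.
SPIKE_IN_PREFIX = "ERCC"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountMatrix:
    """A genes x samples matrix of non-negative counts or CPM values.

    Parameters
    ----------
    gene_ids
        Unique gene symbols, one per row.
    sample_ids
        Unique cell / replicate identifiers, one per column.
    values
        Non-negative array of shape ``(len(gene_ids), len(sample_ids))``.
    normalized
        ``True`` once every column sums to one million (CPM scale).
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples array")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.any(values < 0):
            raise ValueError("count matrix contains negative entries")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if self.normalized:
            totals = values.sum(axis=0)
            if not np.allclose(totals, CPM_TOTAL, rtol=1e-6):
                raise ValueError("normalized matrix has columns not summing to 1e6")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        """Restrict to ``genes`` in the given order.

        Subsetting drops the ``normalized`` flag because the retained rows
        of a CPM column no longer sum to one million.
        """
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return CountMatrix(tuple(genes), self.sample_ids, self.values[rows, :], False)

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        cols = [index[s] for s in samples]
        return CountMatrix(
            self.gene_ids, tuple(samples), self.values[:, cols], self.normalized
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class CellAnnotation:
    """Mapping of cell identifier to its cell-type label."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        labels = dict(self.labels)
        for cell, label in labels.items():
            if not label:
                raise ValueError(f"cell {cell!r} has an empty label")
        object.__setattr__(self, "labels", labels)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.labels.keys())

    @property
    def cell_types(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def cells_of_type(self, cell_type: str) -> list[str]:
        return [c for c, t in self.labels.items() if t == cell_type]

    def label_of(self, cell_id: str) -> str:
        return self.labels[cell_id]

    def subset(self, cell_ids: Iterable[str]) -> "CellAnnotation":
        return CellAnnotation({c: self.labels[c] for c in cell_ids})


@dataclass(frozen=True)
class ReferenceRatios:
    """Reference cell-type composition; fractions on the probability simplex."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        fractions = {k: float(v) for k, v in self.fractions.items()}
        if any(v < 0 for v in fractions.values()):
            raise ValueError("reference fractions must be non-negative")
        total = sum(fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"reference fractions sum to {total}, expected 1")
        object.__setattr__(self, "fractions", fractions)

    @property
    def cell_types(self) -> list[str]:
        return list(self.fractions.keys())

    def __getitem__(self, cell_type: str) -> float:
        return self.fractions[cell_type]

    def as_vector(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.fractions[t] for t in order], dtype=float)


class BulkReplicates(CountMatrix):
    """A CountMatrix whose columns are whole-organ RNA-seq replicates."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.n_samples < 1:
            raise ValueError("at least one bulk replicate required")

    @property
    def n_replicates(self) -> int:
        return self.n_samples


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def cpm_normalize(matrix: CountMatrix) -> CountMatrix:
    """Scale every column so its total is one million (CPM).

    Normalizing an already-normalized matrix is a no-op up to floating
    point. Columns with zero total are an error rather than silently
    dropped, so quality control stays explicit.
    """
    totals = matrix.values.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        bad = [matrix.sample_ids[i] for i in zero[:5]]
        raise ValueError(f"cannot CPM-normalize zero-total column(s): {bad}")
    values = matrix.values * (CPM_TOTAL / totals)
    cls = BulkReplicates if isinstance(matrix, BulkReplicates) else CountMatrix
    return cls(matrix.gene_ids, matrix.sample_ids, values, normalized=True)


def filter_excluded_genes(
    matrix: CountMatrix, extra_exclusions: Iterable[str] = ()
) -> CountMatrix:
    """Drop spike-in (``ERCC*``) rows, known artifact genes and any
    caller-supplied symbols, preserving the order of the survivors."""
    excluded = DEFAULT_EXCLUDED_GENES | set(extra_exclusions)
    keep = [
        i
        for i, g in enumerate(matrix.gene_ids)
        if not g.startswith(SPIKE_IN_PREFIX) and g not in excluded
    ]
    if not keep:
        warnings.warn("gene exclusion removed every gene", stacklevel=2)
    genes = tuple(matrix.gene_ids[i] for i in keep)
    cls = BulkReplicates if isinstance(matrix, BulkReplicates) else CountMatrix
    return cls(genes, matrix.sample_ids, matrix.values[keep, :], False)


def merge_cell_labels(
    annotation: CellAnnotation, merge_map: Mapping[str, str]
) -> CellAnnotation:
    """Rewrite cell-type labels according to pattern -> merged-label rules.

    A pattern ending in ``***`` matches any label with that prefix
    (e.g. ``"Muscle cell_***"``); otherwise the match is exact. Labels
    matching no pattern pass through unchanged; a label matching patterns
    that map to two different merged labels is an error.
    """

    def matches(label: str, pattern: str) -> bool:
        if pattern.endswith("***"):
            return label.startswith(pattern[:-3])
        return label == pattern

    merged = {}
    for cell, label in annotation.labels.items():
        targets = {m for p, m in merge_map.items() if matches(label, p)}
        if len(targets) > 1:
            raise ValueError(
                f"label {label!r} matches multiple merged labels: {sorted(targets)}"
            )
        merged[cell] = targets.pop() if targets else label
    return CellAnnotation(merged)


def align_genes(
    sc: CountMatrix, bulk: BulkReplicates
) -> tuple[CountMatrix, BulkReplicates]:
    """Restrict both matrices to their common genes, in the single-cell
    matrix's row order."""
    bulk_genes = set(bulk.gene_ids)
    common = [g for g in sc.gene_ids if g in bulk_genes]
    if not common:
        raise ValueError("no genes shared between single-cell and bulk matrices")
    sc_out = sc.subset_genes(common)
    bulk_idx = {g: i for i, g in enumerate(bulk.gene_ids)}
    rows = [bulk_idx[g] for g in common]
    bulk_out = BulkReplicates(
        tuple(common), bulk.sample_ids, bulk.values[rows, :], False
    )
    return sc_out, bulk_out


def adjust_reference_ratios(
    ratios: ReferenceRatios, fixed: Mapping[str, float]
) -> ReferenceRatios:
    """Pin some cell-type fractions and rescale the rest proportionally.

    The non-fixed labels share the residual mass ``1 - sum(fixed)`` while
    keeping their mutual proportions, mirroring e.g. setting cardiac
    muscle to 30% of the heart and dividing the remaining 70% among the
    non-muscle types at their observed relative abundances.
    """
    fixed = {k: float(v) for k, v in fixed.items()}
    unknown = set(fixed) - set(ratios.fractions)
    if unknown:
        raise KeyError(f"fixed labels absent from reference: {sorted(unknown)}")
    fixed_total = sum(fixed.values())
    if fixed_total > 1 + 1e-12:
        raise ValueError(f"fixed fractions sum to {fixed_total} > 1")
    free = {k: v for k, v in ratios.fractions.items() if k not in fixed}
    free_total = sum(free.values())
    residual = 1.0 - fixed_total
    out = dict(fixed)
    if free:
        if free_total <= 0:
            raise ValueError("non-fixed labels have zero total mass to rescale")
        out.update({k: v * residual / free_total for k, v in free.items()})
    # preserve the original label order
    return ReferenceRatios({k: out[k] for k in ratios.fractions})


def iterative_linear_gene_filter(
    bulk_profile: np.ndarray,
    sc_mean_profile: np.ndarray,
    gene_ids: Sequence[str],
    r_threshold: float = 0.9,
    sd_mult: float = 3.0,
    max_iterations: int = 100,
) -> list[str]:
    """Iteratively discard cross-platform outlier genes.

    Repeats {fit a zero-intercept linear model of the single-cell mean
    profile on the bulk profile; drop genes whose residual lies more than
    ``sd_mult`` standard deviations from the residual mean; recompute the
    Pearson correlation} until the correlation exceeds ``r_threshold``.
    Returns the surviving gene symbols.
    """
    bulk_profile = np.asarray(bulk_profile, dtype=float)
    sc_mean_profile = np.asarray(sc_mean_profile, dtype=float)
    if bulk_profile.shape != sc_mean_profile.shape:
        raise ValueError("profiles must share a gene set")
    if len(gene_ids) != bulk_profile.size:
        raise ValueError("gene_ids length does not match profiles")
    keep = np.arange(bulk_profile.size)

    for _ in range(max_iterations):
        x = bulk_profile[keep]
        y = sc_mean_profile[keep]
        if keep.size < 3:
            raise ValueError("fewer than 3 genes remain during linear filtering")
        denom = float(x @ x)
        if denom <= 0 or np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("degenerate profiles: zero-intercept fit undefined")
        r = pearsonr(x, y).statistic
        if r > r_threshold:
            return [gene_ids[i] for i in keep]
        slope = float(x @ y) / denom
        resid = y - slope * x
        bound = sd_mult * resid.std()
        inliers = np.abs(resid - resid.mean()) <= bound
        if inliers.all():
            # nothing removable but correlation still below threshold
            raise ValueError(
                f"linear gene filter stalled at r={r:.3f} <= {r_threshold}"
            )
        keep = keep[inliers]
    raise ValueError(f"linear gene filter exceeded {max_iterations} iterations")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_dense_counts(
    path: str | Path,
    sep: str | None = None,
    genes_as_rows: bool = True,
    bulk: bool = False,
) -> CountMatrix:
    """Read a dense CSV/TSV count table (first column = identifiers)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if not genes_as_rows:
        frame = frame.T
    cls = BulkReplicates if bulk else CountMatrix
    return cls(
        tuple(frame.index.astype(str)),
        tuple(frame.columns.astype(str)),
        frame.to_numpy(dtype=float),
        False,
    )


def read_mtx_counts(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> CountMatrix:
    """Read a 10x-style trio: MatrixMarket counts + feature and barcode TSVs.

    Features files may have one column (symbol) or the 10x two/three column
    layout (id, symbol[, type]); the symbol column is used.
    """
    matrix = spio.mmread(str(mtx_path))
    if sparse.issparse(matrix):
        matrix = matrix.toarray()
    features = pd.read_csv(features_path, sep="\t", header=None)
    symbol_col = 1 if features.shape[1] > 1 else 0
    genes = tuple(features.iloc[:, symbol_col].astype(str))
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)
    cells = tuple(barcodes.iloc[:, 0].astype(str))
    return CountMatrix(genes, cells, np.asarray(matrix, dtype=float), False)


def write_dense_counts(matrix: CountMatrix, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    matrix.to_frame().to_csv(path, sep=sep, index_label="gene")


def read_annotation(path: str | Path) -> CellAnnotation:
    """Read a two-column (cell_id, cell_type) CSV/TSV annotation table."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    frame = pd.read_csv(path, sep=sep)
    cells = frame.iloc[:, 0].astype(str)
    labels = frame.iloc[:, 1].astype(str)
    return CellAnnotation(dict(zip(cells, labels)))


def read_reference_ratios(path: str | Path) -> ReferenceRatios:
    """Read cell-type fractions from YAML (mapping) or two-column CSV."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return ReferenceRatios({str(k): float(v) for k, v in data.items()})
    frame = pd.read_csv(path)
    return ReferenceRatios(
        dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(float)))
    )


def read_merge_map(path: str | Path) -> dict[str, str]:
    """Read a label-merge map from YAML (pattern -> merged label) or CSV."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return {str(k): str(v) for k, v in data.items()}
    frame = pd.read_csv(path)
    return dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(str)))
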