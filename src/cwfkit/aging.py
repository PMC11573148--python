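"""Aging-stage analysis of pairwise weighting-factor ratios.

Weighting factors are relative within one organ and bulk dataset, so
comparisons across conditions (aging stages) are made on *pairwise
ratios*: for a type pair (X, Y) at one stage, the full cross product
w_X / w_Y over all cells of both types forms a ratio distribution.
Stage-to-stage changes of these distributions are tested with two-sided
Mann-Whitney U tests (gate p < 0.01), and the distributions of the
surviving pairs feed a gradient-boosted (LightGBM) stage classifier
evaluated with macro metrics computed exactly from the per-stage
confusion counts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.model_selection import train_test_split

import lightgbm as lgb

__all__ = [
    "RatioDistribution",
    "ConfusionCounts",
    "pairwise_ratio_distribution",
    "compare_stages",
    "significant_pairs",
    "build_feature_matrix",
    "train_stage_classifier",
    "classification_metrics",
    "confusion_from_predictions",
    "StageClassifierResult",
]

P_UNDERFLOW = 1e-308
SIGNIFICANCE_GATE = 0.01

#: the six LightGBM hyperparameters searched, with their ranges
TUNING_RANGES: dict[str, tuple[float, float]] = {
    "max_depth": (3, 12),
    "num_leaves": (2, 256),
    "subsample": (0.1, 1.0),
    "subsample_freq": (1, 7),
    "colsample_bytree": (0.1, 1.0),
    "min_child_samples": (5, 100),
}
_INTEGER_PARAMS = {"max_depth", "num_leaves", "subsample_freq", "min_child_samples"}


@dataclass(frozen=True)
class RatioDistribution:
    """All pairwise weighting-factor ratios of one type pair at one stage."""

    numerator_type: str
    denominator_type: str
    condition: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.size == 0:
            raise ValueError("ratio distribution is empty")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("ratios must be finite and non-negative")
        object.__setattr__(self, "values", values)

    @property
    def pair(self) -> str:
        return f"{self.numerator_type} vs {self.denominator_type}"


def _substitute_zeros(values: np.ndarray, label: str) -> np.ndarray:
    """Replace zeros by the list's second-smallest value (division guard)."""
    if not np.any(values == 0):
        return values
    positive = np.unique(values[values > 0])
    if positive.size == 0:
        raise ValueError(f"all weighting factors of {label!r} are zero")
    # the second-smallest distinct value of the full list: with zeros present
    # the smallest is 0, so the replacement is the smallest positive value
    return np.where(values == 0, positive[0], values)


def pairwise_ratio_distribution(
    cwfs_x: np.ndarray,
    cwfs_y: np.ndarray,
    numerator_type: str = "X",
    denominator_type: str = "Y",
    condition: str = "",
) -> RatioDistribution:
    """Cross product of ratios w_X / w_Y after zero substitution.

    Zeros in either list are replaced by that list's second-minimum
    value; the result has len(X) * len(Y) entries.
    """
    x = _substitute_zeros(np.asarray(cwfs_x, dtype=float), numerator_type)
    y = _substitute_zeros(np.asarray(cwfs_y, dtype=float), denominator_type)
    ratios = (x[:, None] / y[None, :]).ravel()
    return RatioDistribution(numerator_type, denominator_type, condition, ratios)


def compare_stages(dist_a: RatioDistribution, dist_b: RatioDistribution) -> float:
    """Two-sided Mann-Whitney U p-value between two ratio distributions.

    p-values below the double-precision lower bound (1e-308) are
    reported as exactly 0; identical constant samples give p = 1 with a
    warning.
    """
    a, b = dist_a.values, dist_b.values
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        warnings.warn("degenerate identical constant distributions; p = 1", stacklevel=2)
        return 1.0
    p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return 0.0 if p < P_UNDERFLOW else p


def significant_pairs(
    stage_distributions: Mapping[str, Mapping[str, RatioDistribution]],
) -> tuple[list[str], pd.DataFrame]:
    """Apply the p < 0.01 gate across all stage comparisons.

    ``stage_distributions`` maps stage -> pair name -> distribution.
    A pair is kept if any of the pairwise stage comparisons is
    significant. Returns the kept pair names and a tidy U-test table
    (pair, stage_a, stage_b, p).
    """
    stages = list(stage_distributions.keys())
    pairs = list(next(iter(stage_distributions.values())).keys())
    rows = []
    kept = []
    for pair in pairs:
        any_significant = False
        for stage_a, stage_b in itertools.combinations(stages, 2):
            p = compare_stages(
                stage_distributions[stage_a][pair], stage_distributions[stage_b][pair]
            )
            rows.append({"pair": pair, "stage_a": stage_a, "stage_b": stage_b, "p": p})
            any_significant = any_significant or p < SIGNIFICANCE_GATE
        if any_significant:
            kept.append(pair)
    return kept, pd.DataFrame(rows)


def build_feature_matrix(
    distributions: Mapping[str, RatioDistribution],
    n_samples: int = 100,
    rng_seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Sample an (n_samples x #pairs) feature matrix for one stage.

    Each column holds ``n_samples`` values drawn independently from that
    pair's ratio distribution (with replacement when the distribution is
    smaller than ``n_samples``), so rows are random recombinations
    rather than observed cells.
    """
    if not distributions:
        raise ValueError("no ratio distributions supplied")
    rng = np.random.default_rng(rng_seed)
    columns = {}
    for pair, dist in distributions.items():
        replace = dist.values.size < n_samples
        columns[pair] = rng.choice(dist.values, size=n_samples, replace=replace)
    return pd.DataFrame(columns)


# ---------------------------------------------------------------------------
# metrics, exactly as the printed per-stage formulas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """Per-stage binary confusion counts (one-vs-rest)."""

    counts: Mapping[str, tuple[int, int, int, int]]  # stage -> (TP, FP, TN, FN)

    def __post_init__(self) -> None:
        counts = {s: tuple(int(v) for v in c) for s, c in self.counts.items()}
        totals = {s: sum(c) for s, c in counts.items()}
        if len(set(totals.values())) > 1:
            raise ValueError("per-stage counts do not sum to a common test size")
        if any(v < 0 for c in counts.values() for v in c):
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)


def confusion_from_predictions(
    y_true: Sequence[str], y_pred: Sequence[str]
) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    counts = {}
    for stage in np.unique(y_true):
        tp = int(np.sum((y_true == stage) & (y_pred == stage)))
        fp = int(np.sum((y_true != stage) & (y_pred == stage)))
        tn = int(np.sum((y_true != stage) & (y_pred != stage)))
        fn = int(np.sum((y_true == stage) & (y_pred != stage)))
        counts[str(stage)] = (tp, fp, tn, fn)
    return ConfusionCounts(counts)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; component set to 0", stacklevel=3)
        return 0.0
    return num / den


def classification_metrics(confusion: ConfusionCounts) -> dict[str, float]:
    """Macro metrics averaged over stages from one-vs-rest counts.

    ``accuracy`` is the mean per-stage binary accuracy
    (TP+TN)/(TP+FP+TN+FN) — note this is not the conventional multiclass
    accuracy, which is also reported as ``overall_accuracy``. Precision,
    recall and F1 are macro-averaged with zero-denominator components
    defined as 0.
    """
    stages = list(confusion.counts.keys())
    k = len(stages)
    acc = prec = rec = f1 = 0.0
    correct = total = 0
    for stage in stages:
        tp, fp, tn, fn = confusion.counts[stage]
        acc += _safe_div(tp + tn, tp + fp + tn + fn, "accuracy")
        p = _safe_div(tp, tp + fp, "precision")
        r = _safe_div(tp, tp + fn, "recall")
        prec += p
        rec += r
        f1 += _safe_div(2.0 * p * r, p + r, "F1") if (p + r) > 0 else 0.0
        correct += tp
        total += tp + fn
    return {
        "accuracy": acc / k,
        "macro_precision": prec / k,
        "macro_recall": rec / k,
        "macro_f1": f1 / k,
        "overall_accuracy": _safe_div(correct, total, "overall accuracy"),
    }


# ---------------------------------------------------------------------------
# gradient-boosted stage classifier
# ---------------------------------------------------------------------------

@dataclass
class StageClassifierResult:
    model: "lgb.LGBMClassifier"
    metrics: dict[str, float]
    best_params: dict[str, float]
    feature_importance: pd.Series  # gain importance per feature
    confusion: ConfusionCounts


def _sample_params(rng: np.random.Generator) -> dict[str, float]:
    params = {}
    for name, (lo, hi) in TUNING_RANGES.items():
        if name in _INTEGER_PARAMS:
            params[name] = int(rng.integers(int(lo), int(hi) + 1))
        else:
            params[name] = float(rng.uniform(lo, hi))
    return params


def train_stage_classifier(
    features_per_stage: Mapping[str, pd.DataFrame],
    split_seed: int = 0,
    tuning_budget: int = 20,
    n_estimators: int = 100,
) -> StageClassifierResult:
    """Tune and fit a LightGBM aging-stage classifier.

    Rows from every stage's feature matrix are pooled, split 80:20
    stratified by stage, and ``tuning_budget`` random draws from the
    hyperparameter ranges are scored by macro-F1 on a validation split
    of the training data; the best model is refit on the full training
    split and evaluated on the held-out 20% with the macro metrics.
    Feature importances use LightGBM's gain.
    """
    stages = list(features_per_stage.keys())
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    frames = []
    for stage in stages:
        frame = features_per_stage[stage]
        if len(frame) < 10:
            raise ValueError(f"stage {stage!r} has fewer than 10 feature rows")
        frames.append(frame.assign(_stage=stage))
    data = pd.concat(frames, ignore_index=True)
    feature_names = [c for c in data.columns if c != "_stage"]
    X = data[feature_names].to_numpy()
    y = data["_stage"].to_numpy()

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.2, stratify=y, random_state=split_seed
    )

    rng = np.random.default_rng(split_seed)
    base = dict(
        n_estimators=n_estimators, random_state=split_seed, verbosity=-1, n_jobs=1
    )
    if tuning_budget < 1:
        warnings.warn("tuning budget 0; using LightGBM defaults", stacklevel=2)
        best_params: dict[str, float] = {}
    else:
        X_fit, X_val, y_fit, y_val = train_test_split(
            X_tr, y_tr, test_size=0.25, stratify=y_tr, random_state=split_seed
        )
        best_params, best_score = {}, -np.inf
        for _ in range(tuning_budget):
            params = _sample_params(rng)
            model = lgb.LGBMClassifier(**base, **params)
            model.fit(X_fit, y_fit)
            preds = model.predict(X_val)
            score = classification_metrics(
                confusion_from_predictions(y_val, preds)
            )["macro_f1"]
            if score > best_score:
                best_params, best_score = params, score

    model = lgb.LGBMClassifier(**base, **best_params)
    model.fit(X_tr, y_tr)
    preds = model.predict(X_te)
    confusion = confusion_from_predictions(y_te, preds)
    metrics = classification_metrics(confusion)
    gain = model.booster_.feature_importance(importance_type="gain")
    importance = pd.Series(gain, index=feature_names).sort_values(ascending=False)
    return StageClassifierResult(
        model=model,
        metrics=metrics,
        best_params=best_params,
        feature_importance=importance,
        confusion=confusion,
    )
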