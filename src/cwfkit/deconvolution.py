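"""Bayesian deconvolution of bulk profiles with weighting-factor priors.

The generative model: the bulk CPM vector ``y`` is a noisy mixture of
per-type "virtual transcriptomes" X = [x_1 ... x_K] (columns are
cWF-weighted type profiles) at cell-type ratios ``r`` on the simplex,

    y | X, r ~ N(Xr, beta I),      r ~ Dirichlet(alpha 1_K),
    x_k ~ N(mu'_k, S_k)            (diagonal, from the cWF summaries),

with half-normal(0, 1) hyperpriors on alpha and beta. The per-type prior
moments come directly from the weighting-factor Gaussian summaries:

    mu'_k = (1/N_k) sum_j mu_wj x_j
    S_k   = (1/N_k) sum_j sigma2_wj (x_j ⊙ x_j)

Sampling is restricted to the signature genes. Because the priors and
likelihood are Gaussian and diagonal, X is marginalized analytically
during Hamiltonian sampling — the NUTS chain moves only in
(r, alpha, beta) — and per-type virtual transcriptomes are recovered
exactly from their conditional Gaussian at each kept draw (negative
sampled elements clamped to zero before averaging). Convergence is
gated at R-hat < 1.1 over all sampled variables.

Non-signature genes are then filled in with the fixed-ratio analytic
update (hyperparameter ``gamma`` in place of 1/beta), iterated per gene
over all types until the inter-iteration RMSE drops below threshold,
with ``gamma`` chosen from a log grid by least RMSE between ``y`` and
the remixed estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from .cwf import CWFSet
from .data_model import CellAnnotation, CountMatrix
from .sampling import nuts_sample, split_rhat
from .signatures import SignatureGeneSet

__all__ = [
    "TypePrior",
    "SamplerConfig",
    "PosteriorSummary",
    "DeconvolutionResult",
    "build_type_priors",
    "sample_posterior",
    "infer_nonsignature",
    "rmse",
    "deconvolve",
    "SignatureEvaluation",
    "choose_optimal_signature_n",
    "DEFAULT_GAMMA_GRID",
]

RHAT_GATE = 1.1

#: gamma grid 1e-5 ... 1e5 in decade steps
DEFAULT_GAMMA_GRID = tuple(10.0**e for e in range(-5, 6))


@dataclass(frozen=True)
class TypePrior:
    """Per-type Gaussian prior over the cWF-weighted profile.

    ``variance`` stores the diagonal exactly as the weighting-factor
    summaries produce it; it enters the sampling prior as a variance and
    the non-signature analytic update in the precision slot, as printed
    (the two readings are not interchangeable and both are exposed).
    """

    cell_type: str
    mean: np.ndarray
    variance: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        variance = np.asarray(self.variance, dtype=float)
        if mean.shape != variance.shape or mean.ndim != 1:
            raise ValueError("mean and variance must be 1-D vectors of equal length")
        if np.any(variance < 0):
            raise ValueError("prior variances must be non-negative")
        if self.n_subjects < 1:
            raise ValueError("a type prior needs at least one subject")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "variance", variance)


def build_type_priors(
    sc: CountMatrix,
    annotation: CellAnnotation,
    cwfs: CWFSet,
    variance_convention: str = "pooled",
) -> list[TypePrior]:
    """Pool each type's per-cell weighting-factor summaries into a
    diagonal Gaussian prior over its weighted profile (full gene set).

    ``variance_convention`` selects the 1/N_k scaling of the prior
    diagonal: ``"pooled"`` (default) divides the summed per-cell
    variances by N_k once, as the model states; ``"sem"`` divides by
    N_k^2, the variance a mean of independent per-cell draws would have
    — useful for sensitivity analysis, since the pooled form leaves the
    prior's relative width independent of N_k.
    """
    if variance_convention not in {"pooled", "sem"}:
        raise ValueError(f"unknown variance convention {variance_convention!r}")
    priors = []
    for cell_type in annotation.cell_types:
        cells = [
            c for c in annotation.cells_of_type(cell_type) if c in cwfs.samples
        ]
        if not cells:
            raise ValueError(f"no weighting factors for cell type {cell_type!r}")
        X = sc.subset_samples(cells).values  # genes x N_k
        mu_w = np.array([cwfs.mean(c) for c in cells])
        var_w = np.array([cwfs.variance(c) for c in cells])
        n_k = len(cells)
        mean = (X * mu_w).sum(axis=1) / n_k
        denom = n_k if variance_convention == "pooled" else n_k**2
        variance = (X**2 * var_w).sum(axis=1) / denom
        priors.append(TypePrior(cell_type, mean, variance, n_k))
    return priors


# ---------------------------------------------------------------------------
# posterior sampling over (r, alpha, beta) with X marginalized
# ---------------------------------------------------------------------------

@dataclass
class SamplerConfig:
    """NUTS settings; defaults favor well-mixed chains on small problems."""

    n_chains: int = 4
    n_warmup: int = 1000
    n_samples: int = 1000
    target_accept: float = 0.9
    max_treedepth: int = 12
    seed: int = 0


@dataclass
class PosteriorSummary:
    """Posterior means and diagnostics from the signature-gene sampling."""

    cell_types: list[str]
    ratio_mean: np.ndarray
    x_signature_eap: np.ndarray  # genes x types, negatives clamped per draw
    alpha_mean: float
    beta_mean: float
    rhat_max: float
    converged: bool
    n_divergent: int
    ratio_draws: np.ndarray  # (total draws, K)


def _softmax_r(z: np.ndarray) -> np.ndarray:
    full = np.concatenate([[0.0], z])
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


def _make_logp_grad(y, M, S):
    """Log posterior and gradient in unconstrained (z, log alpha, log beta).

    ``M`` (genes x K) holds prior means, ``S`` prior variances; X is
    marginalized: y | r, beta ~ N(M r, beta + sum_k r_k^2 S_k) per gene.
    """
    n_genes, n_types = M.shape

    def logp_grad(theta):
        z = theta[: n_types - 1]
        a, b = theta[-2], theta[-1]
        if np.any(np.abs(theta) > 50):
            return -np.inf, np.zeros_like(theta)
        alpha, beta = np.exp(a), np.exp(b)
        r = _softmax_r(z)
        c = beta + S @ r**2  # per-gene marginal variance, >= beta > 0
        resid = y - M @ r
        logp = -0.5 * np.sum(np.log(2 * np.pi * c)) - 0.5 * np.sum(resid**2 / c)
        # Dirichlet(alpha 1_K) + softmax Jacobian sum(log r)
        logp += (
            gammaln(n_types * alpha)
            - n_types * gammaln(alpha)
            + alpha * np.sum(np.log(r))
        )
        # half-normal(0,1) hyperpriors with log-transform Jacobians
        logp += -0.5 * alpha**2 + a - 0.5 * beta**2 + b

        inv_c = 1.0 / c
        quad = resid**2 * inv_c**2
        # d logp / d r_k (likelihood + Dirichlet/Jacobian alpha/r term)
        g_r = (
            M.T @ (resid * inv_c)
            + r * (S.T @ (quad - inv_c))
            + alpha / r
        )
        # softmax chain rule, component 0 pinned
        g_z = r[1:] * (g_r[1:] - np.dot(g_r, r))
        g_a = alpha * (
            n_types * digamma(n_types * alpha)
            - n_types * digamma(alpha)
            + np.sum(np.log(r))
        ) - alpha**2 + 1.0
        g_b = beta * 0.5 * np.sum(quad - inv_c) - beta**2 + 1.0
        return logp, np.concatenate([g_z, [g_a, g_b]])

    return logp_grad


def _draw_x_conditional(y, M, S, r, beta, rng):
    """One exact draw of X from its per-gene conditional Gaussian.

    Per gene g the conditional of x_g given (y_g, r, beta) is Gaussian
    with covariance S_g - (S_g r)(S_g r)^T / (beta + r^T S_g r); drawn by
    batched Cholesky with a tiny jitter on degenerate coordinates.
    """
    n_genes, n_types = M.shape
    s_r = S * r  # genes x K
    denom = beta + s_r @ r
    gain = s_r / denom[:, None]
    mean = M + gain * (y - M @ r)[:, None]
    cov = np.zeros((n_genes, n_types, n_types))
    idx = np.arange(n_types)
    cov[:, idx, idx] = S
    cov -= gain[:, :, None] * s_r[:, None, :]
    cov[:, idx, idx] += 1e-12 + 1e-9 * S
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_genes, n_types))
    return mean + np.einsum("gij,gj->gi", chol, z)


def sample_posterior(
    y: np.ndarray,
    priors: Sequence[TypePrior],
    signature: SignatureGeneSet | None = None,
    gene_ids: Sequence[str] | None = None,
    config: SamplerConfig | None = None,
) -> PosteriorSummary:
    """NUTS sampling of cell-type ratios (and virtual signature profiles).

    ``y`` is the bulk CPM vector over ``gene_ids``; if a signature set is
    given, sampling is restricted to those genes. Returns posterior-mean
    ratios (always on the simplex), the per-draw-clamped EAP of the
    signature-gene virtual transcriptomes, and the worst R-hat over all
    sampled variables (gate at 1.1).
    """
    config = config or SamplerConfig()
    y = np.asarray(y, dtype=float)
    types = [p.cell_type for p in priors]
    n_types = len(types)

    if signature is not None:
        if gene_ids is None:
            raise ValueError("gene_ids required to restrict to signature genes")
        index = {g: i for i, g in enumerate(gene_ids)}
        rows = np.array([index[g] for g in signature.genes])
        y = y[rows]
        M = np.column_stack([p.mean[rows] for p in priors])
        S = np.column_stack([p.variance[rows] for p in priors])
    else:
        M = np.column_stack([p.mean for p in priors])
        S = np.column_stack([p.variance for p in priors])

    if n_types == 1:
        return PosteriorSummary(
            cell_types=types,
            ratio_mean=np.array([1.0]),
            x_signature_eap=np.clip(M, 0.0, None),
            alpha_mean=float("nan"),
            beta_mean=float("nan"),
            rhat_max=1.0,
            converged=True,
            n_divergent=0,
            ratio_draws=np.ones((1, 1)),
        )

    logp_grad = _make_logp_grad(y, M, S)
    dim = (n_types - 1) + 2
    rng = np.random.default_rng(config.seed)

    chains, divergences = [], 0
    for chain in range(config.n_chains):
        theta0 = np.concatenate(
            [0.1 * rng.standard_normal(n_types - 1), [0.0, 0.0]]
        )
        result = nuts_sample(
            logp_grad,
            theta0,
            n_warmup=config.n_warmup,
            n_samples=config.n_samples,
            seed=rng.integers(2**31 - 1),
            max_treedepth=config.max_treedepth,
            target_accept=config.target_accept,
        )
        chains.append(result.samples)
        divergences += result.n_divergent
    raw = np.stack(chains)  # (chains, draws, dim)

    # constrained-space draws: r on the simplex, alpha, beta positive
    flat = raw.reshape(-1, dim)
    r_draws = np.apply_along_axis(_softmax_r, 1, flat[:, : n_types - 1])
    alpha_draws = np.exp(flat[:, -2])
    beta_draws = np.exp(flat[:, -1])

    constrained = np.concatenate(
        [r_draws, alpha_draws[:, None], beta_draws[:, None]], axis=1
    ).reshape(config.n_chains, config.n_samples, n_types + 2)
    rhat_max = float(np.nanmax(split_rhat(constrained)))
    converged = rhat_max < RHAT_GATE
    if not converged:
        warnings.warn(
            f"sampler not converged: max R-hat {rhat_max:.3f} >= {RHAT_GATE}",
            stacklevel=2,
        )
    if divergences > 0.1 * config.n_chains * config.n_samples:
        raise RuntimeError(
            f"{divergences} divergent transitions "
            f"(> 10% of {config.n_chains * config.n_samples} draws); "
            "increase target_accept or reparametrize"
        )

    # EAP of X on signature genes: exact conditional draw per kept draw,
    # negatives clamped per draw before averaging
    x_sum = np.zeros_like(M)
    for r_i, beta_i in zip(r_draws, beta_draws):
        x_draw = _draw_x_conditional(y, M, S, r_i, beta_i, rng)
        x_sum += np.clip(x_draw, 0.0, None)
    x_eap = x_sum / len(r_draws)

    return PosteriorSummary(
        cell_types=types,
        ratio_mean=r_draws.mean(axis=0),
        x_signature_eap=x_eap,
        alpha_mean=float(alpha_draws.mean()),
        beta_mean=float(beta_draws.mean()),
        rhat_max=rhat_max,
        converged=converged,
        n_divergent=divergences,
        ratio_draws=r_draws,
    )


# ---------------------------------------------------------------------------
# analytic completion of the non-signature genes
# ---------------------------------------------------------------------------

def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square difference of two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rmse inputs differ in shape")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _analytic_update(y, M, P, r, gamma, x_prev):
    """One fixed-ratio analytic pass over all types (Jacobi iteration).

    Per gene g and type k:
    E[x_gk] = (gamma r_k^2 + P_gk)^-1 (gamma r_k y_g + P_gk mu_gk
              - gamma sum_{l != k} r_k r_l x_gl),
    where ``P`` holds the prior diagonal exactly as stored (precision
    slot, as printed). Each pass uses the previous iteration's x.
    """
    mix = x_prev @ r  # sum_l r_l x_gl
    x_new = np.empty_like(x_prev)
    for k, r_k in enumerate(r):
        denom = gamma * r_k**2 + P[:, k]
        cross = mix - r_k * x_prev[:, k]
        numer = gamma * r_k * y + P[:, k] * M[:, k] - gamma * r_k * cross
        with np.errstate(divide="ignore", invalid="ignore"):
            x_new[:, k] = np.where(denom > 0, numer / np.maximum(denom, 1e-300), M[:, k])
    return x_new


def infer_nonsignature(
    y: np.ndarray,
    ratio_mean: np.ndarray,
    priors: Sequence[TypePrior],
    x_signature: np.ndarray,
    signature: SignatureGeneSet,
    gene_ids: Sequence[str],
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    rmse_threshold: float = 1.0,
    max_iterations: int = 100,
) -> tuple[np.ndarray, float, float]:
    """Complete the virtual transcriptomes over the non-signature genes.

    With ratios fixed at their posterior mean, each candidate ``gamma``
    runs the analytic update until consecutive estimates differ by less
    than ``rmse_threshold`` (CPM scale) or ``max_iterations`` passes;
    negatives are zeroed in the result. The selected ``gamma`` minimizes
    the RMSE between ``y`` and the remixed estimate over all genes.
    Returns (full genes x types EAP, gamma_selected, fit_rmse).
    """
    if not len(gamma_grid):
        raise ValueError("gamma grid is empty")
    y = np.asarray(y, dtype=float)
    r = np.asarray(ratio_mean, dtype=float)
    sig_set = set(signature.genes)
    sig_rows = np.array([g in sig_set for g in gene_ids])
    nonsig = ~sig_rows

    M = np.column_stack([p.mean for p in priors])
    P = np.column_stack([p.variance for p in priors])

    best = None
    for gamma in gamma_grid:
        x = M[nonsig].copy()  # initial condition: the cWF-weighted profiles
        for _ in range(max_iterations if x.size else 0):
            x_next = _analytic_update(y[nonsig], M[nonsig], P[nonsig], r, gamma, x)
            step = rmse(x_next.ravel(), x.ravel())
            x = x_next
            if step < rmse_threshold:
                break
        x = np.clip(x, 0.0, None)
        full = np.empty((len(gene_ids), len(priors)))
        full[sig_rows] = x_signature
        full[nonsig] = x
        fit = rmse(y, full @ r)
        if best is None or fit < best[2]:
            best = (full, float(gamma), fit)
    return best


# ---------------------------------------------------------------------------
# orchestration and signature-number selection
# ---------------------------------------------------------------------------

@dataclass
class DeconvolutionResult:
    """Posterior ratios, virtual transcriptomes and diagnostics."""

    cell_types: list[str]
    ratios: dict[str, float]
    eap: pd.DataFrame  # genes x types virtual transcriptome
    var_printed: pd.DataFrame  # Eq-form gamma r_k^2 + prior diagonal, as stored
    rhat_max: float
    converged: bool
    gamma_selected: float
    fit_rmse: float
    posterior: PosteriorSummary = field(repr=False, default=None)


def deconvolve(
    y: np.ndarray,
    gene_ids: Sequence[str],
    priors: Sequence[TypePrior],
    signature: SignatureGeneSet,
    config: SamplerConfig | None = None,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
) -> DeconvolutionResult:
    """Full deconvolution of one bulk CPM vector: NUTS over the signature
    genes, then analytic completion of the remaining genes."""
    posterior = sample_posterior(y, priors, signature, gene_ids, config)
    eap_full, gamma_sel, fit = infer_nonsignature(
        y,
        posterior.ratio_mean,
        priors,
        posterior.x_signature_eap,
        signature,
        gene_ids,
        gamma_grid,
    )
    types = posterior.cell_types
    P = np.column_stack([p.variance for p in priors])
    var_printed = gamma_sel * posterior.ratio_mean[None, :] ** 2 + P
    return DeconvolutionResult(
        cell_types=types,
        ratios=dict(zip(types, posterior.ratio_mean.tolist())),
        eap=pd.DataFrame(eap_full, index=list(gene_ids), columns=types),
        var_printed=pd.DataFrame(var_printed, index=list(gene_ids), columns=types),
        rhat_max=posterior.rhat_max,
        converged=posterior.converged,
        gamma_selected=gamma_sel,
        fit_rmse=fit,
        posterior=posterior,
    )


@dataclass(frozen=True)
class SignatureEvaluation:
    """Per-signature-size evidence for the three selection criteria."""

    n: int
    reconstitution_improved: bool
    converged: bool
    ratio_rmse: float
    reference_pearson: float


def choose_optimal_signature_n(evaluations: Sequence[SignatureEvaluation]) -> int:
    """Pick the signature-gene count: drop sizes that failed to improve
    reconstitution or to converge; among survivors take the lowest
    composition RMSE, ties broken by higher reference-composition
    Pearson."""
    survivors = [e for e in evaluations if e.reconstitution_improved and e.converged]
    if not survivors:
        failures = [
            (e.n, "no reconstitution improvement" if not e.reconstitution_improved else "not converged")
            for e in evaluations
        ]
        raise ValueError(f"all signature sizes filtered out: {failures}")
    best = min(survivors, key=lambda e: (e.ratio_rmse, -e.reference_pearson))
    return best.n
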