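"""Bayesian deconvolution: priors, posterior sampling, analytic completion."""

import numpy as np
import pytest

from cwfkit.cwf import CWFSet, estimate_cwfs
from cwfkit.data_model import CellAnnotation, CountMatrix, ReferenceRatios
from cwfkit.deconvolution import (
    DEFAULT_GAMMA_GRID,
    SamplerConfig,
    SignatureEvaluation,
    TypePrior,
    _analytic_update,
    build_type_priors,
    choose_optimal_signature_n,
    deconvolve,
    infer_nonsignature,
    rmse,
    sample_posterior,
)
from cwfkit.signatures import SignatureGeneSet
from cwfkit.simulate import SimulationConfig, simulate_dataset


def _signature(genes):
    n = len(genes)
    return SignatureGeneSet(
        tuple(genes), tuple(float(n - i) for i in range(n)), 1.0, 1, 1, True
    )


class TestBuildTypePriors:
    def test_single_subject_scalar_formula(self):
        sc = CountMatrix(("g1", "g2"), ("c1",), np.array([[10.0], [0.0]]))
        annotation = CellAnnotation({"c1": "alpha"})
        cwfs = CWFSet(
            samples={"c1": np.array([1.5, 2.5])},  # mean 2, variance 0.5
            cell_types={"c1": "alpha"},
        )
        # force the exact summary values of the worked example
        assert cwfs.mean("c1") == pytest.approx(2.0)
        cwfs.samples["c1"] = np.array([2.0 - 0.35355339, 2.0 + 0.35355339])
        assert cwfs.variance("c1") == pytest.approx(0.25)
        (prior,) = build_type_priors(sc, annotation, cwfs)
        assert np.allclose(prior.mean, [20.0, 0.0])
        assert np.allclose(prior.variance, [25.0, 0.0])

    def test_duplicated_subject_matches_single(self):
        values = np.array([[10.0], [3.0]])
        sc1 = CountMatrix(("g1", "g2"), ("c1",), values)
        sc2 = CountMatrix(("g1", "g2"), ("c1", "c2"), np.hstack([values, values]))
        samples = np.array([1.0, 2.0, 3.0])
        one = build_type_priors(
            sc1, CellAnnotation({"c1": "a"}),
            CWFSet({"c1": samples}, {"c1": "a"}),
        )[0]
        two = build_type_priors(
            sc2, CellAnnotation({"c1": "a", "c2": "a"}),
            CWFSet({"c1": samples, "c2": samples.copy()}, {"c1": "a", "c2": "a"}),
        )[0]
        assert np.allclose(one.mean, two.mean)
        assert np.allclose(one.variance, two.variance)

    def test_zero_cwf_variance_gives_zero_prior_variance(self):
        sc = CountMatrix(("g1",), ("c1",), np.array([[5.0]]))
        cwfs = CWFSet({"c1": np.array([2.0, 2.0, 2.0])}, {"c1": "a"})
        (prior,) = build_type_priors(sc, CellAnnotation({"c1": "a"}), cwfs)
        assert prior.variance[0] == 0.0

    def test_sem_convention_divides_by_n(self):
        sc = CountMatrix(("g1",), ("c1", "c2"), np.array([[5.0, 5.0]]))
        annotation = CellAnnotation({"c1": "a", "c2": "a"})
        cwfs = CWFSet(
            {"c1": np.array([1.0, 3.0]), "c2": np.array([1.0, 3.0])},
            {"c1": "a", "c2": "a"},
        )
        pooled = build_type_priors(sc, annotation, cwfs, "pooled")[0]
        sem = build_type_priors(sc, annotation, cwfs, "sem")[0]
        assert np.allclose(sem.variance * 2, pooled.variance)
        assert np.allclose(sem.mean, pooled.mean)

    def test_type_without_subjects_raises(self):
        sc = CountMatrix(("g1",), ("c1",), np.array([[5.0]]))
        annotation = CellAnnotation({"c1": "a"})
        cwfs = CWFSet({"c2": np.array([1.0])}, {"c2": "b"})
        with pytest.raises((ValueError, KeyError)):
            build_type_priors(sc, annotation, cwfs)


class TestAnalyticUpdate:
    def test_scalar_conditional_mean(self):
        """gamma=1, r=1, y=4, mu'=2, prior diagonal 1 -> (1+1)^-1 (4+2) = 3."""
        y = np.array([4.0])
        M = np.array([[2.0]])
        P = np.array([[1.0]])
        out = _analytic_update(y, M, P, np.array([1.0]), 1.0, M.copy())
        assert out[0, 0] == pytest.approx(3.0)

    def test_uninformative_prior_limit_returns_data(self):
        """With vanishing prior precision the update converges to y / r."""
        y = np.array([6.0])
        M = np.array([[2.0]])
        P = np.array([[1e-12]])
        r = np.array([0.5])
        out = _analytic_update(y, M, P, r, 1.0, M.copy())
        assert out[0, 0] == pytest.approx(12.0, rel=1e-6)

    def test_mixture_fixed_point(self):
        """If y is exactly the prior mixture, the prior means are a fixed point."""
        rng = np.random.default_rng(0)
        M = rng.uniform(1, 10, size=(4, 2))
        P = rng.uniform(0.5, 2, size=(4, 2))
        r = np.array([0.6, 0.4])
        y = M @ r
        for gamma in (1e-3, 1.0, 1e3):
            out = _analytic_update(y, M, P, r, gamma, M.copy())
            assert np.allclose(out, M, atol=1e-8)

    def test_monte_carlo_conditional_oracle(self):
        """The update equals the conditional mean of the Gaussian model,
        estimated by importance sampling from the prior."""
        rng = np.random.default_rng(1)
        y = np.array([5.0, 2.0])
        M = np.array([[3.0, 1.0], [1.0, 2.0]])
        P = np.array([[1.0, 0.5], [2.0, 0.25]])  # precision reading
        r = np.array([0.7, 0.3])
        gamma = 2.0
        x_other = np.array([1.2, 2.5])  # fixed profile of type 2
        x_prev = np.column_stack([M[:, 0], x_other])
        expected = _analytic_update(y, M, P, r, gamma, x_prev)[:, 0]

        n = 200_000
        draws = M[:, 0] + rng.standard_normal((n, 2)) / np.sqrt(P[:, 0])
        mean_pred = r[0] * draws + r[1] * x_other
        logw = -0.5 * gamma * ((y - mean_pred) ** 2).sum(axis=1)
        w = np.exp(logw - logw.max())
        w /= w.sum()
        mc_mean = (w[:, None] * draws).sum(axis=0)
        mc_var = (w[:, None] * (draws - mc_mean) ** 2).sum(axis=0)
        ess = 1.0 / np.sum(w**2)
        se = np.sqrt(mc_var / ess)
        assert np.all(np.abs(expected - mc_mean) < 3 * se)


class TestInferNonsignature:
    def test_single_gamma_forced(self):
        gene_ids = ["g0", "g1"]
        sig = _signature(["g1"])
        priors = [TypePrior("a", np.array([2.0, 7.0]), np.array([1.0, 1.0]), 1)]
        y = np.array([4.0, 7.0])
        eap, gamma_sel, fit = infer_nonsignature(
            y, np.array([1.0]), priors, np.array([[7.0]]), sig, gene_ids, [1.0]
        )
        assert gamma_sel == 1.0
        assert eap[0, 0] == pytest.approx(3.0)  # scalar conditional mean
        assert eap[1, 0] == pytest.approx(7.0)  # signature slot untouched

    def test_empty_grid_rejected(self):
        sig = _signature(["g1"])
        priors = [TypePrior("a", np.array([2.0, 7.0]), np.array([1.0, 1.0]), 1)]
        with pytest.raises(ValueError, match="empty"):
            infer_nonsignature(
                np.array([4.0, 7.0]), np.array([1.0]), priors,
                np.array([[7.0]]), sig, ["g0", "g1"], [],
            )

    def test_gamma_selected_from_default_grid(self, trio_dataset, trio_signature):
        sc, annotation, bulk, truth = trio_dataset
        types = truth.cell_types
        sizes = np.array([truth.sizes[t] for t in types])
        ratios = np.array([truth.ratios[t] for t in types])
        X = truth.profiles * sizes / (ratios * sizes).sum()
        priors = [
            TypePrior(t, X[:, k], (0.05 * X[:, k]) ** 2, 5)
            for k, t in enumerate(types)
        ]
        y = bulk.values.mean(axis=1)
        eap, gamma_sel, fit = infer_nonsignature(
            y, ratios, priors, np.clip(X[: len(trio_signature.genes)], 0, None),
            trio_signature,
            [g for g in truth.gene_ids],
        )
        assert gamma_sel in DEFAULT_GAMMA_GRID
        assert np.all(eap >= 0)


class TestRmse:
    def test_closed_forms(self):
        assert rmse(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0
        assert rmse(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == pytest.approx(
            np.sqrt(12.5)
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(size=10)
        perm = rng.permutation(10)
        assert rmse(a, b) == pytest.approx(rmse(a[perm], b[perm]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            rmse(np.zeros(3), np.zeros(4))


def _truth_priors(truth, r_true, rel_sd=0.05):
    types = truth.cell_types
    s = np.array([truth.sizes[t] for t in types])
    X = truth.profiles * s / (np.asarray(r_true) * s).sum()
    return (
        [TypePrior(t, X[:, k], (rel_sd * X[:, k]) ** 2, 10) for k, t in enumerate(types)],
        X,
    )


class TestSamplePosterior:
    def test_single_type_is_exact(self):
        prior = TypePrior("only", np.array([3.0, 4.0]), np.array([1.0, 1.0]), 2)
        post = sample_posterior(np.array([3.0, 4.0]), [prior])
        assert post.ratio_mean[0] == 1.0
        assert post.converged

    def test_ratio_recovery_with_correct_priors(self, trio_dataset, trio_signature):
        sc, annotation, bulk, truth = trio_dataset
        rng = np.random.default_rng(0)
        errors = []
        for trial in range(3):
            r_true = rng.dirichlet(np.ones(3))
            priors, X = _truth_priors(truth, r_true)
            y = X @ r_true
            post = sample_posterior(
                y, priors, trio_signature, truth.gene_ids,
                SamplerConfig(n_chains=2, n_warmup=300, n_samples=300, seed=trial),
            )
            assert post.rhat_max < 1.1
            errors.append(rmse(post.ratio_mean, r_true))
        assert np.mean(errors) < 0.05

    def test_posterior_ratios_on_simplex(self, trio_dataset, trio_signature):
        _, _, _, truth = trio_dataset
        priors, X = _truth_priors(truth, [0.3, 0.3, 0.4])
        y = X @ np.array([0.3, 0.3, 0.4])
        post = sample_posterior(
            y, priors, trio_signature, truth.gene_ids,
            SamplerConfig(n_chains=2, n_warmup=200, n_samples=200, seed=0),
        )
        assert np.all(post.ratio_draws >= 0)
        assert np.allclose(post.ratio_draws.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(post.x_signature_eap >= 0)

    def test_degradation_monotone_in_prior_misscaling(
        self, trio_dataset, trio_signature
    ):
        _, _, _, truth = trio_dataset
        r_true = np.array([0.5, 0.3, 0.2])
        errors = []
        for mis in (1.0, 2.0, 4.0):
            priors, X = _truth_priors(truth, r_true)
            y = X @ r_true
            skew = [
                TypePrior(p.cell_type, p.mean * (mis if k == 0 else 1.0),
                          p.variance, p.n_subjects)
                for k, p in enumerate(priors)
            ]
            post = sample_posterior(
                y, skew, trio_signature, truth.gene_ids,
                SamplerConfig(n_chains=2, n_warmup=300, n_samples=300, seed=1),
            )
            errors.append(rmse(post.ratio_mean, r_true))
        assert errors[0] < errors[1] < errors[2]


class TestDeconvolveEndToEnd:
    def test_pipeline_estimated_priors(self, trio_dataset, trio_signature):
        sc, annotation, bulk, truth = trio_dataset
        cwfs = estimate_cwfs(
            bulk, sc, annotation, ReferenceRatios(truth.ratios), trio_signature,
            m=30, min_samples=30, rng_seed=2,
        )
        priors = build_type_priors(sc, annotation, cwfs)
        result = deconvolve(
            bulk.values.mean(axis=1), bulk.gene_ids, priors, trio_signature,
            SamplerConfig(n_chains=2, n_warmup=300, n_samples=300, seed=2),
        )
        assert sum(result.ratios.values()) == pytest.approx(1.0)
        assert result.gamma_selected in DEFAULT_GAMMA_GRID
        assert (result.eap.to_numpy() >= 0).all()
        assert result.rhat_max > 0
        # recovered composition is in the right region of the simplex
        est = np.array([result.ratios[t] for t in result.cell_types])
        true = np.array([truth.ratios[t] for t in result.cell_types])
        assert rmse(est, true) < 0.15


class TestChooseOptimalSignatureN:
    def test_single_survivor_forced(self):
        evals = [
            SignatureEvaluation(100, True, True, 0.08, 0.9),
            SignatureEvaluation(300, False, True, 0.02, 0.99),
            SignatureEvaluation(500, True, False, 0.01, 0.99),
        ]
        assert choose_optimal_signature_n(evals) == 100

    def test_lowest_rmse_wins(self):
        evals = [
            SignatureEvaluation(100, True, True, 0.10, 0.9),
            SignatureEvaluation(300, True, True, 0.05, 0.9),
        ]
        assert choose_optimal_signature_n(evals) == 300

    def test_tie_broken_by_reference_pearson(self):
        evals = [
            SignatureEvaluation(100, True, True, 0.05, 0.92),
            SignatureEvaluation(300, True, True, 0.05, 0.97),
        ]
        assert choose_optimal_signature_n(evals) == 300

    def test_all_filtered_raises_with_reasons(self):
        evals = [SignatureEvaluation(100, False, True, 0.1, 0.9)]
        with pytest.raises(ValueError, match="no reconstitution improvement"):
            choose_optimal_signature_n(evals)
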