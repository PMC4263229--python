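import itertools

import numpy as np
import pytest
from scipy import stats

from cormotif import (
    MotifModel,
    PosteriorSummary,
    e_step,
    fit_motifs,
    joint_config_prob,
    log_likelihood,
    log_posterior,
    m_step,
)
from cormotif.emfit import gene_class_loglik

from conftest import make_tstat


# ---------------------------------------------------------------------------
# independent oracle: exhaustive enumeration of the joint latent space

def brute_force(matrix, model):
    """Enumerate all (class, configuration) pairs per gene and sum the joint
    density exactly; returns (class_post, diff_post, log_likelihood)."""
    g, d = matrix.t.shape
    k = model.n_classes
    f0 = stats.t.pdf(matrix.t, matrix.df)
    f1 = stats.t.pdf(matrix.t / matrix.scale_alt, matrix.df) / matrix.scale_alt
    class_post = np.zeros((g, k))
    diff_post = np.zeros((g, d))
    ll = 0.0
    for gi in range(g):
        total = 0.0
        by_class = np.zeros(k)
        by_study = np.zeros(d)
        for ki in range(k):
            for a in itertools.product((0, 1), repeat=d):
                p = model.pi[ki]
                for di in range(d):
                    if a[di]:
                        p *= model.q[ki, di] * f1[gi, di]
                    else:
                        p *= (1.0 - model.q[ki, di]) * f0[gi, di]
                total += p
                by_class[ki] += p
                for di in range(d):
                    if a[di]:
                        by_study[di] += p
        class_post[gi] = by_class / total
        diff_post[gi] = by_study / total
        ll += np.log(total)
    return class_post, diff_post, ll


def random_instance(rng, g, d, k):
    matrix = make_tstat(rng.normal(scale=3.0, size=(g, d)),
                        df=rng.uniform(4, 12), scale=rng.uniform(1.2, 5.0))
    pi = rng.dirichlet(np.ones(k))
    q = rng.uniform(0.05, 0.95, size=(k, d))
    return matrix, MotifModel(pi=pi, q=q)


@pytest.mark.parametrize("g,d,k", [(4, 2, 2), (6, 4, 3), (5, 3, 1), (3, 1, 2)])
def test_e_step_matches_exhaustive_enumeration(g, d, k, rng):
    matrix, model = random_instance(rng, g, d, k)
    post = e_step(matrix, model)
    ref_class, ref_diff, ref_ll = brute_force(matrix, model)
    np.testing.assert_allclose(post.class_post, ref_class, atol=1e-10)
    np.testing.assert_allclose(post.diff_post, ref_diff, atol=1e-10)
    assert log_likelihood(matrix, model) == pytest.approx(ref_ll, abs=1e-10)


def test_e_step_invariants(rng):
    matrix, model = random_instance(rng, 50, 3, 3)
    post = e_step(matrix, model)
    np.testing.assert_allclose(post.class_post.sum(axis=1), 1.0, atol=1e-10)
    assert np.all((post.within_class_diff >= 0) & (post.within_class_diff <= 1))
    # the decomposition Pr(a=1|T) = sum_k Pr(b=k|T) Pr(a=1|T,b=k) holds exactly
    np.testing.assert_allclose(
        post.diff_post,
        np.einsum("gk,gkd->gd", post.class_post, post.within_class_diff),
        atol=1e-12,
    )


def test_single_class_posteriors():
    matrix = make_tstat([[0.3, -4.0], [2.0, 1.0]], df=6, scale=2.0)
    model = MotifModel(pi=np.array([1.0]), q=np.array([[0.3, 0.7]]))
    post = e_step(matrix, model)
    np.testing.assert_allclose(post.class_post, 1.0)
    f0 = stats.t.pdf(matrix.t, 6.0)
    f1 = stats.t.pdf(matrix.t / 2.0, 6.0) / 2.0
    q = model.q[0]
    np.testing.assert_allclose(
        post.diff_post, q * f1 / (q * f1 + (1 - q) * f0), atol=1e-12
    )


def test_gene_class_loglik_scalar_case():
    t, df, c, q = 1.7, 6.0, 2.0, 0.3
    f0 = stats.t.pdf(t, df)
    f1 = stats.t.pdf(t / c, df) / c
    val = gene_class_loglik(np.array([t]), np.array([q]),
                            np.array([df]), np.array([c]))
    assert val == pytest.approx(np.log(q * f1 + (1 - q) * f0), abs=1e-12)


def test_gene_class_loglik_collapses_when_densities_equal():
    t = np.array([0.5, -1.0, 2.0])
    val = gene_class_loglik(t, np.full(3, 0.5), np.full(3, 6.0), np.ones(3))
    assert val == pytest.approx(stats.t.logpdf(t, 6.0).sum(), abs=1e-12)


class TestMStep:
    def test_saturated_counts_with_pseudocounts(self):
        g, d = 40, 2
        post = PosteriorSummary(
            class_post=np.ones((g, 1)),
            within_class_diff=np.ones((g, 1, d)),
        )
        model = m_step(post)
        np.testing.assert_allclose(model.q, (g + 1) / (g + 2))
        np.testing.assert_allclose(model.pi, 1.0)

    def test_empty_input_returns_prior_mode(self):
        post = PosteriorSummary(
            class_post=np.zeros((0, 3)),
            within_class_diff=np.zeros((0, 3, 2)),
        )
        model = m_step(post)
        np.testing.assert_allclose(model.pi, 1 / 3)
        np.testing.assert_allclose(model.q, 0.5)

    def test_em_step_never_decreases_map_objective(self, rng):
        for _ in range(20):
            matrix, model = random_instance(rng, 25, 2, 2)
            before = log_posterior(matrix, model)
            after = log_posterior(matrix, m_step(e_step(matrix, model)))
            assert after >= before - 1e-8


def test_label_permutation_invariance(rng):
    matrix, model = random_instance(rng, 20, 3, 3)
    perm = [2, 0, 1]
    permuted = MotifModel(pi=model.pi[perm], q=model.q[perm])
    assert log_likelihood(matrix, permuted) == pytest.approx(
        log_likelihood(matrix, model), abs=1e-10
    )
    assert log_posterior(matrix, permuted) == pytest.approx(
        log_posterior(matrix, model), abs=1e-10
    )


def test_fit_is_deterministic_under_seed(small_tstat):
    a = fit_motifs(small_tstat, 2, n_starts=3, seed=42)
    b = fit_motifs(small_tstat, 2, n_starts=3, seed=42)
    np.testing.assert_array_equal(a.model.pi, b.model.pi)
    np.testing.assert_array_equal(a.model.q, b.model.q)
    np.testing.assert_array_equal(a.trace, b.trace)
    assert a.log_posterior == b.log_posterior


def test_fit_trace_monotone(small_tstat):
    fit = fit_motifs(small_tstat, 3, n_starts=2, seed=0)
    assert np.all(np.diff(fit.trace) >= -1e-8)
    assert fit.log_posterior <= fit.log_likelihood  # prior terms are negative
    assert fit.converged


def test_fit_k_exceeding_genes_rejected(rng):
    matrix = make_tstat(rng.normal(size=(3, 2)))
    with pytest.raises(ValueError, match="exceeds"):
        fit_motifs(matrix, 4)


def _study_em_oracle(t_col, df, scale, tol=1e-12):
    """One-dimensional MAP-EM for a single study's null/alt mixture."""
    f0 = stats.t.pdf(t_col, df)
    f1 = stats.t.pdf(t_col / scale, df) / scale
    q = 0.3
    for _ in range(10_000):
        r = q * f1 / (q * f1 + (1 - q) * f0)
        q_new = (r.sum() + 1.0) / (len(t_col) + 2.0)
        if abs(q_new - q) < tol:
            break
        q = q_new
    return q, q * f1 / (q * f1 + (1 - q) * f0)


def test_k1_fit_decomposes_into_per_study_mixtures(small_tstat):
    fit = fit_motifs(small_tstat, 1, n_starts=2, seed=1, tol=1e-12)
    post = e_step(small_tstat, fit.model)
    for d in range(small_tstat.n_studies):
        q_ref, post_ref = _study_em_oracle(
            small_tstat.t[:, d], small_tstat.df[d], small_tstat.scale_alt[d]
        )
        assert fit.model.q[0, d] == pytest.approx(q_ref, abs=1e-6)
        np.testing.assert_allclose(post.diff_post[:, d], post_ref, atol=1e-5)


class TestJointConfigurationProbability:
    def test_k1_factorises_over_studies(self):
        model = MotifModel(pi=np.array([1.0]), q=np.array([[0.2, 0.6, 0.9]]))
        joint = joint_config_prob(model, [1, 1, 1])
        marginals = np.prod(model.q[0])
        assert joint == pytest.approx(marginals, abs=1e-15)

    def test_k2_differs_from_product_of_marginals(self):
        model = MotifModel(pi=np.array([0.5, 0.5]),
                           q=np.array([[0.9, 0.9], [0.1, 0.1]]))
        joint = joint_config_prob(model, [1, 1])
        marg = np.prod(model.pi @ model.q)
        # 0.5*0.81 + 0.5*0.01 = 0.41 vs 0.25: dependence induced by mixing
        assert joint == pytest.approx(0.41)
        assert abs(joint - marg) > 0.1
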