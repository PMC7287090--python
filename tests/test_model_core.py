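"""Four-hypothesis likelihoods, priors and posteriors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import duotada as dt
from duotada.model_core import trait_log_evidence


def poisson_pmf_oracle(k: int, lam: float) -> float:
    """Log-gamma-based Poisson pmf, independent of scipy."""
    if lam == 0:
        return 1.0 if k == 0 else 0.0
    return math.exp(k * math.log(lam) - lam - math.lgamma(k + 1))


def poisson_gamma_marginal_oracle(k: int, lam0: float, mean_rr: float, beta: float) -> float:
    """Arbitrary-precision integration of Poisson(k; lam0*g) over Gamma(g).

    Uses tanh-sinh quadrature (mpmath) after the substitution g = t^(1/a)
    for Gamma shapes a < 1, whose density is singular at zero and carries
    substantial mass at sub-double-precision g; split points cover both
    the Gamma scale and the Poisson-compatible scale k/lam0.
    """
    import mpmath as mp

    with mp.workdps(40):
        a = mp.mpf(mean_rr) * mp.mpf(beta)
        b = mp.mpf(beta)
        lam0_mp = mp.mpf(lam0)
        c = min(a, mp.mpf(1))

        def f(t):
            if t <= 0:
                return mp.mpf(0)
            g = t ** (1 / c)
            lam = lam0_mp * g
            pois = mp.exp(k * mp.log(lam) - lam - mp.loggamma(k + 1)) if k > 0 else mp.exp(-lam)
            dens = b**a / mp.gamma(a) * g ** (a - 1) * mp.exp(-b * g)
            return pois * dens * g / (c * t)

        g_scales = [a / b, (k + 1) / lam0_mp, 5 * (a / b + (k + 1) / lam0_mp), a / b / 10]
        pts = sorted({float(s**c) for s in g_scales if s > 0})
        return float(mp.quad(f, [0] + pts + [mp.inf]))


class TestNullLikelihood:
    def test_closed_form_values(self):
        assert dt.null_count_likelihood(0, 1e-5, 1000) == pytest.approx(math.exp(-0.02))
        assert dt.null_count_likelihood(1, 1e-5, 1000) == pytest.approx(0.02 * math.exp(-0.02))

    def test_matches_log_gamma_oracle(self):
        assert dt.null_count_likelihood(5, 1e-5, 1000) == pytest.approx(
            poisson_pmf_oracle(5, 0.02), rel=1e-12
        )

    def test_zero_rate_forces_zero_count(self):
        assert dt.null_count_likelihood(1, 0.0, 1000) == 0.0
        assert dt.null_count_likelihood(0, 0.0, 1000) == 1.0

    def test_rejects_invalid_counts(self):
        with pytest.raises(ValueError):
            dt.null_count_likelihood(-1, 1e-5, 1000)
        with pytest.raises(ValueError):
            dt.null_count_likelihood(1.5, 1e-5, 1000)


class TestAltLikelihood:
    @pytest.mark.parametrize(
        "count,two_n_mu,mean_rr,beta",
        [
            (2, 0.02, 20.0, 1.0),
            (0, 1e-4, 1.0, 0.05),
            (5, 0.5, 200.0, 10.0),
            (10, 1.0, 50.0, 0.2),
            (1, 1e-3, 105.0, 1.0),
            (8, 0.1, 29.0, 0.8),
        ],
    )
    def test_negative_binomial_matches_integration(self, count, two_n_mu, mean_rr, beta):
        """Closed form agrees with direct Poisson x Gamma quadrature to 1e-8."""
        n_trios = 1000
        mu = two_n_mu / (2 * n_trios)
        got = dt.alt_count_likelihood(count, mu, n_trios, mean_rr, beta)
        want = poisson_gamma_marginal_oracle(count, two_n_mu, mean_rr, beta)
        assert got == pytest.approx(want, abs=1e-8)

    def test_spec_point_value(self):
        assert dt.alt_count_likelihood(2, 1e-5, 1000, 20, 1) == pytest.approx(0.0543, abs=5e-5)

    def test_zero_rate_point_mass(self):
        assert dt.alt_count_likelihood(0, 0.0, 1000, 20, 1) == pytest.approx(1.0)

    def test_large_dispersion_converges_to_poisson(self):
        """Gamma concentrates at mean_rr, so the marginal approaches Poisson."""
        lam = 2 * 1000 * 1e-5 * 20
        for k in range(6):
            nb = dt.alt_count_likelihood(k, 1e-5, 1000, 20, 1e7)
            assert nb == pytest.approx(poisson_pmf_oracle(k, lam), rel=1e-3)

    def test_likelihood_ratio_monotone_in_count(self):
        """For mean_rr > 1 the alt/null ratio is non-decreasing in count."""
        counts = np.arange(0, 51)
        ln = dt.model_core.null_count_log_likelihood(counts, 1e-5, 5000)
        la = dt.model_core.alt_count_log_likelihood(counts, 1e-5, 5000, 29.0, 1.0)
        ratio = la - ln
        assert np.all(np.diff(ratio) >= -1e-12)

    def test_no_underflow_in_log_space(self):
        ll = dt.model_core.alt_count_log_likelihood(50, 5e-14, 1000, 20.0, 1.0)
        assert np.isfinite(ll)
        ll0 = dt.model_core.null_count_log_likelihood(50, 5e-14, 1000)
        assert np.isfinite(ll0)

    def test_rejects_bad_hyperparameters(self):
        with pytest.raises(ValueError):
            dt.alt_count_likelihood(1, 1e-5, 1000, np.inf, 1.0)
        with pytest.raises(ValueError):
            dt.alt_count_likelihood(1, 1e-5, 1000, 20.0, -1.0)


class TestEvidenceAndJointLikelihoods:
    def test_single_category_reduces_to_primitives(self):
        params = dt.TraitHyperParams(1000, (20.0,), (1.0,), 0.05)
        rec = dt.CategoryData(1e-5, 2)
        null, alt = dt.gene_trait_evidence([rec], params)
        assert null == pytest.approx(dt.null_count_likelihood(2, 1e-5, 1000))
        assert alt == pytest.approx(dt.alt_count_likelihood(2, 1e-5, 1000, 20, 1))

    def test_two_categories_multiply(self):
        params = dt.TraitHyperParams(1000, (20.0, 5.0), (1.0, 0.5), 0.05)
        cats = [dt.CategoryData(1e-5, 2), dt.CategoryData(2e-5, 1)]
        null, alt = dt.gene_trait_evidence(cats, params)
        n_exp = dt.null_count_likelihood(2, 1e-5, 1000) * dt.null_count_likelihood(1, 2e-5, 1000)
        a_exp = dt.alt_count_likelihood(2, 1e-5, 1000, 20, 1) * dt.alt_count_likelihood(1, 2e-5, 1000, 5, 0.5)
        assert null == pytest.approx(n_exp, rel=1e-12)
        assert alt == pytest.approx(a_exp, rel=1e-12)

    def test_all_zero_counts_near_one(self):
        params = dt.TraitHyperParams(1000, (20.0, 5.0), (1.0, 1.0), 0.05)
        cats = [dt.CategoryData(1e-8, 0), dt.CategoryData(1e-8, 0)]
        null, _ = dt.gene_trait_evidence(cats, params)
        assert null == pytest.approx(1.0, abs=1e-4)

    def test_category_mismatch_rejected(self):
        params = dt.TraitHyperParams(1000, (20.0,), (1.0,), 0.05)
        with pytest.raises(ValueError):
            trait_log_evidence(np.array([[1, 2]]), np.array([[1e-5, 1e-5]]), params)

    def test_joint_vector_ordering(self, params_pair):
        """Entries are (null1*null2, alt1*null2, null1*alt2, alt1*alt2)."""
        p1, p2 = params_pair
        rec = dt.GeneRecord(
            "g",
            (dt.CategoryData(1e-5, 4), dt.CategoryData(1e-5, 0)),
            (dt.CategoryData(1e-5, 0), dt.CategoryData(1e-5, 0)),
        )
        vec = dt.joint_model_likelihoods(rec, p1, p2)
        n1, a1 = dt.gene_trait_evidence(rec.trait1, p1)
        n2, a2 = dt.gene_trait_evidence(rec.trait2, p2)
        assert vec == pytest.approx([n1 * n2, a1 * n2, n1 * a2, a1 * a2], rel=1e-10)
        # a large trait-1 burden favors H1 over H0
        assert vec[1] > vec[0]

    def test_symmetric_inputs_give_symmetric_entries(self):
        p = dt.TraitHyperParams(1000, (20.0,), (1.0,), 0.05)
        rec = dt.GeneRecord("g", (dt.CategoryData(1e-5, 2),), (dt.CategoryData(1e-5, 2),))
        vec = dt.joint_model_likelihoods(rec, p, p)
        assert vec[1] == pytest.approx(vec[2], rel=1e-12)

    def test_zero_rate_gene_falls_back_to_prior(self, params_pair):
        p1, p2 = params_pair
        table = dt.GeneTable(["g"], [[0.0, 0.0]], [[0, 0]], [[1e-5, 1e-5]], [[0, 0]])
        L = dt.joint_model_log_likelihoods(table, p1, p2)
        # trait-1 evidence equal under null and alternative
        assert L[0, 0] == pytest.approx(L[0, 1], rel=1e-12)
        assert L[0, 2] == pytest.approx(L[0, 3], rel=1e-12)


class TestPriorsAndPosteriors:
    @pytest.mark.parametrize(
        "p1s,p2s,p3,expected",
        [
            (0.05, 0.03, 0.02, (0.94, 0.03, 0.01, 0.02)),
            (0.05, 0.03, 0.0, (0.92, 0.05, 0.03, 0.0)),
        ],
    )
    def test_derive_joint_priors(self, p1s, p2s, p3, expected):
        priors = dt.derive_joint_priors(p1s, p2s, p3)
        assert priors.as_array() == pytest.approx(expected, abs=1e-12)

    def test_pi3_exceeding_min_rejected(self):
        with pytest.raises(ValueError):
            dt.derive_joint_priors(0.05, 0.03, 0.04)

    def test_degenerate_prior_pins_posterior(self):
        priors = dt.JointPriors(1.0, 0.0, 0.0, 0.0)
        pp = dt.gene_posteriors([0.5, 0.9, 0.9, 0.9], priors).pp
        assert pp == pytest.approx([1, 0, 0, 0])

    def test_equal_likelihoods_return_prior(self):
        priors = dt.derive_joint_priors(0.05, 0.03, 0.01)
        pp = dt.gene_posteriors([0.3, 0.3, 0.3, 0.3], priors).pp
        assert pp == pytest.approx(priors.as_array(), rel=1e-12)

    def test_hand_normalization(self):
        gp = dt.gene_posteriors([1, 2, 3, 4], dt.JointPriors(0.25, 0.25, 0.25, 0.25))
        assert gp.pp == pytest.approx([0.1, 0.2, 0.3, 0.4])
        assert gp.pp_trait1 == pytest.approx(0.6)
        assert gp.pp_trait2 == pytest.approx(0.7)

    def test_all_zero_numerator_is_an_error(self):
        priors = dt.JointPriors(1.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="geneX"):
            dt.gene_posteriors([0.0, 1.0, 1.0, 1.0], priors, gene_id="geneX")

    @given(
        liks=st.lists(st.floats(1e-300, 1.0), min_size=4, max_size=4),
        weights=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
    )
    @settings(max_examples=200, deadline=None)
    def test_posterior_normalization_property(self, liks, weights):
        w = np.array(weights) / np.sum(weights)
        w[3] = 1.0 - w[:3].sum()  # exact sum for the invariant check
        priors = dt.JointPriors(*w)
        pp = dt.gene_posteriors(liks, priors).pp
        assert abs(pp.sum() - 1.0) < 1e-10
        assert np.all(pp >= 0) and np.all(pp <= 1)

    def test_posterior_table_matches_per_gene(self, tiny_table, params_pair):
        p1, p2 = params_pair
        priors = dt.derive_joint_priors(p1.pi_single, p2.pi_single, 0.01)
        L = dt.joint_model_log_likelihoods(tiny_table, p1, p2)
        pp = dt.posterior_table(L, priors)
        for i, rec in enumerate(tiny_table.records):
            single = dt.gene_posteriors(dt.joint_model_likelihoods(rec, p1, p2), priors, rec.gene_id)
            assert pp[i] == pytest.approx(single.pp, rel=1e-9)

    def test_zero_pi3_zeroes_pp3(self, tiny_table, params_pair):
        p1, p2 = params_pair
        priors = dt.derive_joint_priors(p1.pi_single, p2.pi_single, 0.0)
        pp = dt.posterior_table(dt.joint_model_log_likelihoods(tiny_table, p1, p2), priors)
        assert np.all(pp[:, 3] == 0.0)


class TestGeneticOverlap:
    def test_endpoints(self):
        assert dt.genetic_overlap(dt.derive_joint_priors(0.05, 0.03, 0.0)) == 0.0
        assert dt.genetic_overlap(dt.JointPriors(0.97, 0.0, 0.0, 0.03)) == 100.0

    def test_worked_value(self):
        go = dt.genetic_overlap(dt.derive_joint_priors(0.05, 0.03, 0.01))
        assert go == pytest.approx(100 * 0.01 / 0.07, rel=1e-12)

    def test_undefined_when_no_risk_component(self):
        with pytest.raises(ValueError):
            dt.genetic_overlap(dt.JointPriors(1.0, 0.0, 0.0, 0.0))
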