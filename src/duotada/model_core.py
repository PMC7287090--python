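"""Per-gene likelihoods for the four-hypothesis two-trait DNM model.

Under the null a gene's DNM count in a category is Poisson with mean
2*N*mu (N trios, mutation rate mu, factor 2 for the diploid genome). In a
risk gene the Poisson mean is multiplied by a relative risk gamma drawn
from Gamma(gamma_bar * beta, beta). Integrating gamma out gives a negative
binomial marginal with shape r = gamma_bar * beta and success probability
p = beta / (beta + 2*N*mu) — the closed form used throughout.

The four hypotheses combine the two traits' null/alternative states:
H0 neither, H1 trait 1 only, H2 trait 2 only, H3 both. All likelihood
arithmetic is carried out in log space; probabilities are exponentiated
only at posterior normalization.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .types import GenePosterior, GeneTable, JointPriors, TraitHyperParams

__all__ = [
    "null_count_likelihood",
    "alt_count_likelihood",
    "null_count_log_likelihood",
    "alt_count_log_likelihood",
    "gene_trait_evidence",
    "trait_log_evidence",
    "joint_model_likelihoods",
    "joint_model_log_likelihoods",
    "derive_joint_priors",
    "gene_posteriors",
    "posterior_table",
    "genetic_overlap",
    "single_trait_posterior",
]

logger = logging.getLogger(__name__)


def _check_counts(count) -> np.ndarray:
    arr = np.asarray(count)
    if np.any(arr < 0) or not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValueError(f"counts must be non-negative integers, got {count!r}")
    return arr.astype(int)


def null_count_log_likelihood(count, mu, n_trios: int) -> np.ndarray:
    """Log Poisson probability of `count` DNMs at null mean 2*n_trios*mu."""
    x = _check_counts(count)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("mu must be >= 0")
    if n_trios < 1:
        raise ValueError("n_trios must be >= 1")
    lam = 2.0 * n_trios * mu
    # scipy yields -inf for lam=0, count>0 and 0.0 for lam=0, count=0, as required
    return stats.poisson.logpmf(x, lam)


def null_count_likelihood(count, mu, n_trios: int):
    """Poisson probability mass of `count` under the no-risk hypothesis."""
    out = np.exp(null_count_log_likelihood(count, mu, n_trios))
    return float(out) if np.isscalar(count) else out


def alt_count_log_likelihood(count, mu, n_trios: int, mean_rr, dispersion) -> np.ndarray:
    """Log marginal probability of `count` in a risk gene.

    The Poisson-Gamma compound integrates to a negative binomial with
    shape ``mean_rr * dispersion`` and success probability
    ``dispersion / (dispersion + 2 * n_trios * mu)``.
    """
    x = _check_counts(count)
    mu = np.asarray(mu, dtype=float)
    mean_rr = np.asarray(mean_rr, dtype=float)
    dispersion = np.asarray(dispersion, dtype=float)
    if not (np.all(np.isfinite(mean_rr)) and np.all(np.isfinite(dispersion))):
        raise ValueError("mean_rr and dispersion must be finite")
    if np.any(mean_rr <= 0) or np.any(dispersion <= 0):
        raise ValueError("mean_rr and dispersion must be > 0")
    if n_trios < 1:
        raise ValueError("n_trios must be >= 1")
    lam0 = 2.0 * n_trios * mu
    r = mean_rr * dispersion
    p = dispersion / (dispersion + lam0)
    # mu = 0 degenerates to a point mass at zero (p = 1): logpmf handles it
    return stats.nbinom.logpmf(x, r, p)


def alt_count_likelihood(count, mu, n_trios: int, mean_rr, dispersion):
    """Marginal probability mass of `count` under the risk-gene hypothesis."""
    out = np.exp(alt_count_log_likelihood(count, mu, n_trios, mean_rr, dispersion))
    return float(out) if np.isscalar(count) else out


def trait_log_evidence(
    counts: np.ndarray, mus: np.ndarray, params: TraitHyperParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene log evidence for one trait: (log null, log alternative).

    ``counts`` and ``mus`` are (n_genes, n_categories); evidence is the
    product (log: sum) over the trait's variant categories.
    """
    counts = np.atleast_2d(np.asarray(counts))
    mus = np.atleast_2d(np.asarray(mus, dtype=float))
    if counts.shape != mus.shape:
        raise ValueError(f"count/rate shape mismatch: {counts.shape} vs {mus.shape}")
    if counts.shape[1] != params.n_categories:
        raise ValueError(
            f"table has {counts.shape[1]} categories, hyperparameters have {params.n_categories}"
        )
    log_null = null_count_log_likelihood(counts, mus, params.n_trios).sum(axis=1)
    log_alt = alt_count_log_likelihood(
        counts,
        mus,
        params.n_trios,
        np.asarray(params.mean_rr)[None, :],
        np.asarray(params.dispersion)[None, :],
    ).sum(axis=1)
    return log_null, log_alt


def gene_trait_evidence(record_trait, params: TraitHyperParams) -> tuple[float, float]:
    """Null and alternative evidence of a single gene for one trait."""
    counts = np.array([[c.count for c in record_trait]])
    mus = np.array([[c.mu for c in record_trait]])
    log_null, log_alt = trait_log_evidence(counts, mus, params)
    return float(np.exp(log_null[0])), float(np.exp(log_alt[0]))


def joint_model_log_likelihoods(
    table: GeneTable, params1: TraitHyperParams, params2: TraitHyperParams
) -> np.ndarray:
    """(n_genes, 4) log likelihoods under H0..H3.

    Genes whose mutation rate is zero in every category of a trait carry
    no information for that trait; their evidence for that trait is set to
    the (equal) null value under both states so posteriors fall back to the
    prior for that trait's component, with a logged warning.
    """
    l0_1, l1_1 = trait_log_evidence(table.x1, table.mu1, params1)
    l0_2, l1_2 = trait_log_evidence(table.x2, table.mu2, params2)

    for trait, mus, l0, l1 in ((1, table.mu1, l0_1, l1_1), (2, table.mu2, l0_2, l1_2)):
        dead = np.all(mus == 0, axis=1)
        if np.any(dead):
            logger.warning(
                "%d gene(s) have zero mutation rate in every trait-%d category; "
                "treated as uninformative for that trait",
                int(dead.sum()),
                trait,
            )
            l1[dead] = l0[dead]

    return np.stack([l0_1 + l0_2, l1_1 + l0_2, l0_1 + l1_2, l1_1 + l1_2], axis=1)


def joint_model_likelihoods(record, params1: TraitHyperParams, params2: TraitHyperParams) -> np.ndarray:
    """Likelihood 4-vector (H0..H3) of a single gene record."""
    table = GeneTable.from_records([record])
    return np.exp(joint_model_log_likelihoods(table, params1, params2)[0])


def derive_joint_priors(pi1_single: float, pi2_single: float, pi3: float) -> JointPriors:
    """Four-model mixture weights implied by single-trait proportions.

    pi1 = pi1^S - pi3, pi2 = pi2^S - pi3, pi0 = 1 - (pi1^S + pi2^S - pi3):
    the shared proportion pi3 is carved out of each trait's marginal
    risk-gene proportion.
    """
    if not (0 <= pi3 <= min(pi1_single, pi2_single) + 1e-15):
        raise ValueError(
            f"pi3 = {pi3} must lie in [0, min(pi1_single, pi2_single) = "
            f"{min(pi1_single, pi2_single)}]"
        )
    pi1 = pi1_single - pi3
    pi2 = pi2_single - pi3
    pi0 = 1.0 - (pi1_single + pi2_single - pi3)
    if pi0 < 0:
        raise ValueError(f"pi1_single + pi2_single - pi3 = {pi1_single + pi2_single - pi3} exceeds 1")
    return JointPriors(pi0, max(pi1, 0.0), max(pi2, 0.0), pi3)


def gene_posteriors(model_liks, priors: JointPriors, gene_id: str = "") -> GenePosterior:
    """Posterior 4-vector of one gene: normalize prior-weighted likelihoods."""
    liks = np.asarray(model_liks, dtype=float)
    num = priors.as_array() * liks
    total = num.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError(f"gene {gene_id or '<unnamed>'}: degenerate posterior (all weights zero)")
    return GenePosterior(gene_id=gene_id, pp=num / total)


def posterior_table(log_liks: np.ndarray, priors: JointPriors) -> np.ndarray:
    """(n_genes, 4) posterior probabilities from log likelihoods, in log space."""
    log_pi = np.full(4, -np.inf)
    pi = priors.as_array()
    pos = pi > 0
    log_pi[pos] = np.log(pi[pos])
    log_num = log_liks + log_pi[None, :]
    denom = logsumexp(log_num, axis=1, keepdims=True)
    if np.any(~np.isfinite(denom)):
        bad = int(np.sum(~np.isfinite(denom).ravel()))
        raise ValueError(f"{bad} gene(s) have all-zero posterior weight")
    pp = np.exp(log_num - denom)
    pp[:, ~pos] = 0.0  # exact zeros where the prior is zero
    return pp / pp.sum(axis=1, keepdims=True)


def genetic_overlap(priors: JointPriors) -> float:
    """Gene-level genetic overlap gO = 100 * pi3 / (pi1 + pi2 + pi3), in percent."""
    denom = priors.pi1 + priors.pi2 + priors.pi3
    if denom <= 0:
        raise ValueError("genetic overlap undefined: no risk genes under the prior")
    return 100.0 * priors.pi3 / denom


def single_trait_posterior(
    counts: np.ndarray, mus: np.ndarray, params: TraitHyperParams
) -> np.ndarray:
    """Per-gene risk probability under the two-component single-trait mixture.

    This is the single-trait baseline the joint model reduces to when the
    shared proportion is irrelevant: P(risk) = pi * alt / (pi*alt + (1-pi)*null).
    """
    log_null, log_alt = trait_log_evidence(counts, mus, params)
    a = np.log(params.pi_single) + log_alt
    b = np.log1p(-params.pi_single) + log_null
    return np.exp(a - np.logaddexp(a, b))
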