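"""Single-trait hyperparameter estimation (the upstream two-component model).

One trait's gene table is modeled as a mixture: with probability pi a
gene is a risk gene (Poisson-Gamma alternative per category), otherwise
null Poisson. The joint two-trait analysis consumes the fitted
(pi^S, gamma_bar_c, beta_c) as fixed hyperparameters and estimates only
the shared proportion on top of them.

Default estimator: bounded MAP via multi-start L-BFGS-B on
(logit pi, log gamma_bar, log beta), i.e. uniform prior on pi and
log-uniform priors on gamma_bar and beta within the bounds. An optional
random-walk Metropolis sampler provides posterior draws and credible
intervals when point estimates are not enough.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .model_core import alt_count_log_likelihood, null_count_log_likelihood
from .types import SamplerDiagnostics, SingleTraitFit

__all__ = ["FitConfig", "single_trait_loglik", "fit_single_trait"]

logger = logging.getLogger(__name__)

# Bounds of the hyperparameter search box.
PI_BOUNDS = (1e-5, 0.5)
RR_BOUNDS = (1.0, 1e4)
BETA_BOUNDS = (0.01, 100.0)

_FLAT_CURVATURE = 1e-3  # |d2 logL / d pi2| below this flags an unidentifiable mixture


@dataclass
class FitConfig:
    method: str = "map"  # "map" or "mcmc"
    n_starts: int = 8
    seed: int = 0
    fix_dispersion: tuple[float, ...] | None = None
    # MCMC settings (method="mcmc")
    n_chains: int = 2
    n_steps: int = 4000
    n_kept: int = 1000
    step_size: float = 0.25


def single_trait_loglik(
    counts: np.ndarray,
    mus: np.ndarray,
    pi: float,
    mean_rr,
    dispersion,
    n_trios: int,
) -> float:
    """Mixture log likelihood sum_i log[(1-pi) P0_i + pi P1_i].

    P0_i and P1_i are products of per-category null and alternative
    evidence for gene i.
    """
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"pi must lie in [0, 1], got {pi}")
    counts = np.atleast_2d(np.asarray(counts))
    mus = np.atleast_2d(np.asarray(mus, dtype=float))
    l0 = null_count_log_likelihood(counts, mus, n_trios).sum(axis=1)
    l1 = alt_count_log_likelihood(
        counts, mus, n_trios, np.asarray(mean_rr, dtype=float)[None, :],
        np.asarray(dispersion, dtype=float)[None, :],
    ).sum(axis=1)
    if pi == 0.0:
        return float(l0.sum())
    if pi == 1.0:
        return float(l1.sum())
    per_gene = np.logaddexp(np.log1p(-pi) + l0, np.log(pi) + l1)
    return float(per_gene.sum())


def _unpack(theta: np.ndarray, n_cat: int, fixed_beta):
    pi = float(expit(theta[0]))
    rr = tuple(np.exp(theta[1 : 1 + n_cat]))
    if fixed_beta is None:
        beta = tuple(np.exp(theta[1 + n_cat : 1 + 2 * n_cat]))
    else:
        beta = tuple(fixed_beta)
    return pi, rr, beta


def _theta_bounds(n_cat: int, fixed_beta):
    bounds = [(logit(PI_BOUNDS[0]), logit(PI_BOUNDS[1]))]
    bounds += [(np.log(RR_BOUNDS[0]), np.log(RR_BOUNDS[1]))] * n_cat
    if fixed_beta is None:
        bounds += [(np.log(BETA_BOUNDS[0]), np.log(BETA_BOUNDS[1]))] * n_cat
    return bounds


def _random_start(rng: np.random.Generator, n_cat: int, fixed_beta) -> np.ndarray:
    pi = 10 ** rng.uniform(-4, np.log10(0.3))
    rr = 10 ** rng.uniform(np.log10(2.0), np.log10(500.0), size=n_cat)
    theta = [logit(pi), *np.log(rr)]
    if fixed_beta is None:
        theta += list(np.log(10 ** rng.uniform(-1, 1, size=n_cat)))
    return np.asarray(theta)


def fit_single_trait(
    counts: np.ndarray,
    mus: np.ndarray,
    n_trios: int,
    config: FitConfig | None = None,
) -> SingleTraitFit:
    """Estimate (pi^S, gamma_bar, beta) for one trait from its gene table.

    Multi-start bounded optimization; the best log likelihood is monotone
    non-decreasing across restarts by construction. Degenerate fits are
    flagged rather than raised: ``pi_at_lower_bound`` when the data carry
    no burden signal, ``flat_likelihood`` when the mixture is
    unidentifiable (curvature in pi below threshold).
    """
    config = config or FitConfig()
    counts = np.atleast_2d(np.asarray(counts))
    mus = np.atleast_2d(np.asarray(mus, dtype=float))
    if counts.shape[0] == 0:
        raise ValueError("empty gene table")
    n_cat = counts.shape[1]
    fixed_beta = config.fix_dispersion
    if fixed_beta is not None and len(fixed_beta) != n_cat:
        raise ValueError("fix_dispersion length must equal the number of categories")

    def negloglik(theta: np.ndarray) -> float:
        pi, rr, beta = _unpack(theta, n_cat, fixed_beta)
        return -single_trait_loglik(counts, mus, pi, rr, beta, n_trios)

    rng = np.random.default_rng(config.seed)
    bounds = _theta_bounds(n_cat, fixed_beta)
    best = None
    traces = []
    for s in range(max(1, config.n_starts)):
        x0 = _random_start(rng, n_cat, fixed_beta)
        res = minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds)
        traces.append((s, float(res.fun), bool(res.success)))
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"single-trait fit failed to converge; restart trace: {traces}")

    pi, rr, beta = _unpack(best.x, n_cat, fixed_beta)
    flags: list[str] = []

    # curvature of the profile in pi at the optimum; ~0 => unidentifiable
    h = 1e-4
    pi_lo, pi_hi = max(pi - h, 0.0), min(pi + h, 1.0)
    ll = lambda p: single_trait_loglik(counts, mus, p, rr, beta, n_trios)
    curv = (ll(pi_hi) - 2.0 * ll(pi) + ll(pi_lo)) / h**2
    if abs(curv) < _FLAT_CURVATURE:
        flags.append("flat_likelihood")
        logger.warning("single-trait likelihood is flat in pi (curvature %.3g)", curv)
        # flat in pi: report the most parsimonious value the data allow
        if ll(PI_BOUNDS[0]) >= ll(pi) - 1e-6:
            pi = PI_BOUNDS[0]

    if pi <= PI_BOUNDS[0] * (1 + 1e-3):
        flags.append("pi_at_lower_bound")

    fit = SingleTraitFit(
        pi_single=float(np.clip(pi, PI_BOUNDS[0], PI_BOUNDS[1])),
        mean_rr=tuple(float(g) for g in rr),
        dispersion=tuple(float(b) for b in beta),
        n_trios=int(n_trios),
        log_likelihood=-float(best.fun),
        method="map",
        flags=flags,
    )
    if config.method == "mcmc":
        fit = _refine_with_metropolis(counts, mus, n_trios, fit, config)
    return fit


def _refine_with_metropolis(
    counts: np.ndarray, mus: np.ndarray, n_trios: int, fit: SingleTraitFit, config: FitConfig
) -> SingleTraitFit:
    """Random-walk Metropolis around the MAP; posterior-mean point estimates."""
    n_cat = counts.shape[1]
    fixed_beta = config.fix_dispersion
    theta0 = [logit(fit.pi_single), *np.log(fit.mean_rr)]
    if fixed_beta is None:
        theta0 += list(np.log(fit.dispersion))
    theta0 = np.asarray(theta0)
    bounds = np.asarray(_theta_bounds(n_cat, fixed_beta))

    def logpost(theta: np.ndarray) -> float:
        if np.any(theta < bounds[:, 0]) or np.any(theta > bounds[:, 1]):
            return -np.inf
        pi, rr, beta = _unpack(theta, n_cat, fixed_beta)
        return single_trait_loglik(counts, mus, pi, rr, beta, n_trios)

    rng = np.random.default_rng(config.seed)
    chains = []
    for _ in range(config.n_chains):
        theta = theta0 + rng.normal(0, 0.05, size=theta0.size)
        lp = logpost(theta)
        kept = []
        for _ in range(config.n_steps):
            prop = theta + rng.normal(0, config.step_size, size=theta.size)
            lp_prop = logpost(prop)
            if np.log(rng.uniform()) < lp_prop - lp:
                theta, lp = prop, lp_prop
            kept.append(theta.copy())
        kept = np.asarray(kept)
        idx = np.linspace(config.n_steps // 2, config.n_steps - 1, config.n_kept).astype(int)
        chains.append(kept[idx])
    draws = np.asarray(chains)  # (chains, kept, dim)

    names = ["pi"] + [f"mean_rr_{c}" for c in range(n_cat)]
    if fixed_beta is None:
        names += [f"dispersion_{c}" for c in range(n_cat)]
    rhat = {name: split_rhat(draws[:, :, d]) for d, name in enumerate(names)}
    diag = SamplerDiagnostics(
        rhat=rhat, n_chains=config.n_chains, n_steps=config.n_steps, n_kept=config.n_kept
    )
    if max(rhat.values()) > 1.1:
        diag.flags.append("rhat_above_1.1")
        logger.warning("Metropolis convergence suspect: max Rhat = %.3f", max(rhat.values()))

    flat = draws.reshape(-1, draws.shape[-1])
    pi = float(np.mean(expit(flat[:, 0])))
    rr = tuple(float(g) for g in np.exp(flat[:, 1 : 1 + n_cat]).mean(axis=0))
    beta = tuple(fixed_beta) if fixed_beta is not None else tuple(
        float(b) for b in np.exp(flat[:, 1 + n_cat :]).mean(axis=0)
    )
    ll = single_trait_loglik(counts, mus, pi, rr, beta, n_trios)
    return SingleTraitFit(
        pi_single=pi,
        mean_rr=rr,
        dispersion=beta,
        n_trios=int(n_trios),
        log_likelihood=float(ll),
        method="mcmc",
        diagnostics=diag,
        flags=list(fit.flags),
    )


def split_rhat(chain_draws: np.ndarray) -> float:
    """Split potential-scale-reduction statistic for one scalar parameter.

    ``chain_draws`` is (n_chains, n_draws); each chain is split in half so
    within-chain drift shows up as between-chain variance.
    """
    m, n = chain_draws.shape
    half = n // 2
    splits = chain_draws[:, : 2 * half].reshape(2 * m, half)
    means = splits.mean(axis=1)
    w = splits.var(axis=1, ddof=1).mean()
    b = half * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))
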