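"""Marginal likelihoods and Bayes factors.

Model-level comparison uses stepping-stone sampling: independent MCMC runs
at a ladder of likelihood powers beta in [0, 1] (prior at 0, posterior at
1), with the log marginal likelihood assembled from ratios between adjacent
stones.  Model fit is reported as 2 ln BF, twice the difference in log
marginal likelihoods; values >> 10 decisively reject the weaker model.

Route-level support uses the posterior/prior odds formulation

    BF_ij = [p / (1 - p)] / [q / (1 - q)],

where p is the posterior inclusion frequency of route i-j (the proportion
of retained MCMC samples with delta_ij = 1) and q its prior inclusion
probability.  Because a sparse route prior makes q small, the same
posterior frequency p yields a *larger* Bayes factor under a sparser
prior — the mechanism by which prior choice inflates apparent route
support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .mcmc import McmcSettings, Trace, run_mcmc
from .priors import PriorConfig, prior_route_inclusion_probability
from .ctmc import route_pairs

__all__ = [
    "PowerPosteriorResult",
    "run_power_posterior",
    "stepping_stone_log_marginal",
    "model_bayes_factor",
    "kass_raftery_category",
    "RouteSupport",
    "route_bayes_factors",
]


def beta_schedule(n_stones: int, shape: float = 0.3) -> np.ndarray:
    """Beta(shape, 1)-quantile ladder from 0 to 1 (dense near 0, where the
    integrand changes fastest)."""
    return (np.arange(n_stones) / (n_stones - 1)) ** (1.0 / shape)


@dataclass
class PowerPosteriorResult:
    betas: np.ndarray
    loglik_samples: list[np.ndarray]
    ess_warnings: list[int]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beta": self.betas,
            "mean_loglik": [s.mean() for s in self.loglik_samples],
            "se_loglik": [s.std(ddof=1) / math.sqrt(max(s.size, 2)) for s in self.loglik_samples],
            "n": [s.size for s in self.loglik_samples],
        })


def run_power_posterior(
    tree,
    data,
    prior: PriorConfig,
    settings: McmcSettings,
    n_stones: int = 32,
    schedule_shape: float = 0.3,
    root_freqs=None,
    init=None,
    min_ess: float = 50.0,
) -> PowerPosteriorResult:
    """Independent MCMC runs at each power; log-likelihood samples per stone."""
    if n_stones < 4:
        raise ValueError("need at least 4 stones")
    betas = beta_schedule(n_stones, schedule_shape)
    samples: list[np.ndarray] = []
    warn_stones: list[int] = []
    from .mcmc import effective_sample_size

    for s_idx, beta in enumerate(betas):
        st = dc_replace(settings, power=float(beta), seed=settings.seed + 1000 * s_idx)
        trace = run_mcmc(tree, data, prior, st, root_freqs=root_freqs, init=init)
        ll = trace.samples["log_likelihood"].to_numpy()
        samples.append(ll)
        if ll.size >= 100:
            try:
                if effective_sample_size(ll) < min_ess:
                    warn_stones.append(s_idx)
            except ValueError:
                pass
    return PowerPosteriorResult(betas=betas, loglik_samples=samples, ess_warnings=warn_stones)


def stepping_stone_log_marginal(
    stones: PowerPosteriorResult, n_batches: int = 10
) -> tuple[float, float]:
    """Stepping-stone estimate of log P(G) with a batch-means standard error.

    The ratio between adjacent powers beta_j < beta_{j+1} is estimated from
    the samples at beta_j:  r_j = E_{beta_j}[ L^(beta_{j+1} - beta_j) ],
    accumulated in log space.
    """
    betas = stones.betas
    if betas.size < 2:
        raise ValueError("need at least 2 stones")
    total = 0.0
    var = 0.0
    for j in range(betas.size - 1):
        d = betas[j + 1] - betas[j]
        ll = stones.loglik_samples[j]
        log_r = logsumexp(d * ll) - math.log(ll.size)
        total += log_r
        # batch means on the per-stone log-ratio
        nb = min(n_batches, max(2, ll.size // 10))
        batches = np.array_split(ll, nb)
        log_rb = np.array([logsumexp(d * b) - math.log(b.size) for b in batches])
        var += log_rb.var(ddof=1) / nb
    return total, math.sqrt(var)


def model_bayes_factor(log_ml_a: float, log_ml_b: float) -> float:
    """2 ln BF in favour of model a over model b."""
    return 2.0 * (log_ml_a - log_ml_b)


def kass_raftery_category(two_ln_bf: float) -> str:
    """Support category: positive (2, 6], strong (6, 10], decisive > 10."""
    if two_ln_bf > 10:
        return "decisive"
    if two_ln_bf > 6:
        return "strong"
    if two_ln_bf > 2:
        return "positive"
    return "none"


@dataclass
class RouteSupport:
    route: tuple[int, int]
    prior_inclusion: float
    posterior_inclusion: float
    bf: float
    two_ln_bf: float
    category: str
    bounded: bool = False  # posterior frequency hit 0 or 1: one-sided bound


def route_bayes_factors(trace: Trace, prior: PriorConfig) -> list[RouteSupport]:
    """Per-route inclusion Bayes factors from a posterior trace.

    Posterior inclusion frequencies of exactly 0 or 1 are replaced by the
    1/(N+1) resolution bound of the chain and flagged.
    """
    q = prior_route_inclusion_probability(prior)
    prior_odds = q / (1.0 - q)
    pairs = route_pairs(prior.k, prior.symmetric)
    n = len(trace.samples)
    out: list[RouteSupport] = []
    for (i, j), col in zip(pairs, trace.delta_columns):
        p_hat = float(trace.samples[col].mean())
        bounded = p_hat in (0.0, 1.0)
        p_adj = min(max(p_hat, 1.0 / (n + 1)), n / (n + 1))
        bf = (p_adj / (1.0 - p_adj)) / prior_odds
        two = 2.0 * math.log(bf)
        out.append(RouteSupport(
            route=(i, j),
            prior_inclusion=q,
            posterior_inclusion=p_hat,
            bf=bf,
            two_ln_bf=two,
            category=kass_raftery_category(two),
            bounded=bounded,
        ))
    out.sort(key=lambda rs: rs.two_ln_bf, reverse=True)
    return out


def route_support_frame(supports: list[RouteSupport], areas=None) -> pd.DataFrame:
    rows = []
    for rs in supports:
        i, j = rs.route
        rows.append({
            "from": areas[i] if areas else i,
            "to": areas[j] if areas else j,
            "prior_p": rs.prior_inclusion,
            "post_p": rs.posterior_inclusion,
            "BF": rs.bf,
            "twolnBF": rs.two_ln_bf,
            "category": rs.category,
            "bounded": rs.bounded,
        })
    return pd.DataFrame(rows)
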