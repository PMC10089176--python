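"""Prior models for the discrete-geographic CTMC.

Two components of the model carry scientifically consequential priors:

**Number of dispersal routes (Delta).**  The *default* construction places
an offset Poisson prior on Delta for the symmetric model — zero mass below
the minimum Delta = k - 1 needed for an irreducible model, and a Poisson
with rate ``lambda = ln 2`` on the excess — and declares all irreducible
route configurations with the same Delta equiprobable.  For the asymmetric
model the default is a plain Poisson with mean k - 1 and no irreducibility
constraint.  The *alternative* construction centres Delta on half the
maximum number of routes instead, which keeps the implied per-route
inclusion probability roughly flat as k grows.

**Average dispersal rate (mu).**  The *default* is Gamma(shape 0.5,
rate T) where T is the tree length; since the expected number of dispersal
events is mu * T, this fixes the prior expected event count at 0.5 whatever
the duration of the history — the pathology the alternative addresses.  The
*alternative* is an exponential prior on mu whose mean ``m`` is itself a
latent variable with a Gamma(0.5, 0.5) hyperprior (marginally mu follows a
K-distribution); the implied event-count prior then scales with T.

The prior on Delta is expressed here as a *normalized* distribution: a
(truncated, renormalized) pmf on Delta divided by the number of admissible
configurations in that Delta class.  Some samplers instead weight each
configuration by the unnormalized Poisson factor; both styles are exposed
via ``delta_prior_style`` ("per-delta-count", the normalized default, or
"per-configuration").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .ctmc import GeoModelParams, n_routes, route_pairs

__all__ = [
    "PriorConfig",
    "resolve_prior_config",
    "count_configurations",
    "is_irreducible",
    "delta_count_pmf",
    "log_prior_delta",
    "prior_route_inclusion_probability",
    "log_prior_mu",
    "log_prior_relative_rates",
    "log_prior_params",
    "prior_event_count_distribution",
    "EventCountPrior",
    "sample_from_prior",
]

NEG_INF = float("-inf")
LAMBDA_FLOOR = math.log(2.0)


@dataclass(frozen=True)
class PriorConfig:
    """Resolved prior specification for one analysis.

    ``lam``/``offset`` parameterize the (offset) Poisson on the number of
    routes; ``rate_shape``/``rate_rate`` the default Gamma prior on mu;
    ``hyper_shape``/``hyper_rate`` the Gamma hyperprior on the exponential
    mean under the alternative rate prior; ``rr_rate`` the i.i.d.
    exponential prior rate on the relative dispersal rates.
    """

    routes_prior: str
    rate_prior: str
    symmetric: bool
    k: int
    T: float
    lam: float
    offset: int
    rate_shape: float = 0.5
    rate_rate: float = 1.0
    hyper_shape: float = 0.5
    hyper_rate: float = 0.5
    rr_rate: float = 1.0
    delta_prior_style: str = "per-delta-count"

    @property
    def K(self) -> int:
        return n_routes(self.k, self.symmetric)


def resolve_prior_config(
    *,
    routes_prior: str = "default",
    rate_prior: str = "default",
    k: int,
    T: float,
    symmetric: bool = True,
    delta_prior_style: str = "per-delta-count",
) -> PriorConfig:
    """Fill in the route/rate prior hyperparameters for a given k and T."""
    if k < 2:
        raise ValueError("need k >= 2 areas")
    if T <= 0:
        raise ValueError("tree length T must be positive")
    if routes_prior not in ("default", "alternative"):
        raise ValueError(f"unknown routes_prior {routes_prior!r}")
    if rate_prior not in ("default", "alternative"):
        raise ValueError(f"unknown rate_prior {rate_prior!r}")
    K = n_routes(k, symmetric)
    if symmetric:
        offset = k - 1
        if routes_prior == "default":
            lam = math.log(2.0)
        else:
            # centre Delta on K/2; floor keeps the prior proper for tiny k
            lam = max(K / 2.0 - (k - 1), LAMBDA_FLOOR)
    else:
        offset = 0
        lam = float(k - 1) if routes_prior == "default" else K / 2.0
    return PriorConfig(
        routes_prior=routes_prior,
        rate_prior=rate_prior,
        symmetric=symmetric,
        k=k,
        T=float(T),
        lam=lam,
        offset=offset,
        rate_rate=float(T),
        delta_prior_style=delta_prior_style,
    )


# ----------------------------------------------------------------------
# route-configuration counting


def is_irreducible(delta: np.ndarray, k: int, symmetric: bool = True) -> bool:
    """Can every area be reached from every other, directly or indirectly?

    Symmetric: connectivity of the undirected route graph (union-find).
    Asymmetric: strong connectivity of the directed route graph.
    """
    pairs = route_pairs(k, symmetric)
    if symmetric:
        parent = list(range(k))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        n_comp = k
        for idx, (i, j) in enumerate(pairs):
            if delta[idx]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
                    n_comp -= 1
        return n_comp == 1
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(k))
    g.add_edges_from((i, j) for idx, (i, j) in enumerate(pairs) if delta[idx])
    return nx.is_strongly_connected(g)


@lru_cache(maxsize=None)
def _connected_graph_count(n: int, m: int) -> int:
    """Number of connected labeled graphs on n vertices with exactly m edges.

    Standard recurrence: subtract, from all graphs, those whose component
    containing vertex 1 is a proper subset.  Exact integer arithmetic.
    """
    total_edges = n * (n - 1) // 2
    if m < n - 1 or m > total_edges:
        return 0
    if n == 1:
        return 1 if m == 0 else 0
    total = math.comb(total_edges, m)
    for j in range(1, n):
        rest_edges = (n - j) * (n - j - 1) // 2
        for m1 in range(min(m, j * (j - 1) // 2) + 1):
            c = _connected_graph_count(j, m1)
            if c:
                total -= math.comb(n - 1, j - 1) * c * math.comb(rest_edges, m - m1)
    return total


def _enumerate_connected_count(k: int, delta_total: int) -> int:
    pairs = route_pairs(k, True)
    K = len(pairs)
    count = 0
    delta = np.zeros(K, dtype=np.int64)
    for chosen in combinations(range(K), delta_total):
        delta[:] = 0
        delta[list(chosen)] = 1
        if is_irreducible(delta, k, True):
            count += 1
    return count


def count_configurations(
    k: int, delta_total: int, symmetric: bool = True, require_irreducible: bool = True
) -> int:
    """Number of route-indicator vectors with ``sum(delta) = delta_total``
    that are (if required) irreducible."""
    K = n_routes(k, symmetric)
    if not 0 <= delta_total <= K:
        raise ValueError(f"Delta={delta_total} outside [0, {K}]")
    if not require_irreducible:
        return math.comb(K, delta_total)
    if symmetric:
        if K <= 15:  # exhaustive check is cheap here; recurrence covers the rest
            return _enumerate_connected_count(k, delta_total)
        return _connected_graph_count(k, delta_total)
    # strong connectivity has no simple closed recurrence; enumerate
    if K > 20:
        raise NotImplementedError("irreducible counting for large asymmetric models")
    pairs = route_pairs(k, symmetric)
    delta = np.zeros(K, dtype=np.int64)
    count = 0
    for chosen in combinations(range(K), delta_total):
        delta[:] = 0
        delta[list(chosen)] = 1
        if is_irreducible(delta, k, symmetric):
            count += 1
    return count


# ----------------------------------------------------------------------
# prior on delta


def _delta_support(config: PriorConfig) -> np.ndarray:
    lo = config.offset if config.symmetric else 0
    return np.arange(lo, config.K + 1)


@lru_cache(maxsize=256)
def _config_counts_cached(k: int, symmetric: bool, lo: int, hi: int) -> tuple:
    require = symmetric  # irreducibility only enforced for symmetric Q
    return tuple(
        count_configurations(k, d, symmetric, require) for d in range(lo, hi + 1)
    )


def _config_counts(config: PriorConfig) -> np.ndarray:
    """Admissible configurations per Delta value on the support."""
    lo = config.offset if config.symmetric else 0
    return np.array(
        _config_counts_cached(config.k, config.symmetric, lo, config.K),
        dtype=np.float64,
    )


@lru_cache(maxsize=256)
def _delta_count_pmf_cached(config: PriorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Marginal pmf of Delta implied by the configured prior style.

    Returns ``(support, pmf)``.  Under "per-delta-count" this is the offset
    Poisson truncated and renormalized over attainable Delta; under
    "per-configuration" each configuration carries the raw Poisson weight,
    so the Delta marginal is reweighted by the configuration counts.
    """
    support = _delta_support(config)
    counts = _config_counts(config)
    logpois = stats.poisson.logpmf(support - config.offset, config.lam)
    if config.delta_prior_style == "per-delta-count":
        logw = np.where(counts > 0, logpois, NEG_INF)
    elif config.delta_prior_style == "per-configuration":
        with np.errstate(divide="ignore"):
            logw = logpois + np.log(counts)
    else:
        raise ValueError(f"unknown delta_prior_style {config.delta_prior_style!r}")
    pmf = np.exp(logw - logsumexp(logw))
    return support, pmf


def delta_count_pmf(config: PriorConfig) -> tuple[np.ndarray, np.ndarray]:
    support, pmf = _delta_count_pmf_cached(config)
    return support.copy(), pmf.copy()


def log_prior_delta(delta: np.ndarray, config: PriorConfig) -> float:
    """Log prior probability of one route-indicator configuration."""
    delta = np.asarray(delta)
    if delta.size != config.K:
        raise ValueError(f"expected {config.K} indicators, got {delta.size}")
    d = int(delta.sum())
    if config.symmetric:
        if d < config.k - 1 or not is_irreducible(delta, config.k, True):
            return NEG_INF
    support, pmf = delta_count_pmf(config)
    idx = d - int(support[0])
    if idx < 0 or idx >= support.size or pmf[idx] == 0.0:
        return NEG_INF
    count = count_configurations(config.k, d, config.symmetric, config.symmetric)
    return float(np.log(pmf[idx]) - np.log(count))


def prior_route_inclusion_probability(config: PriorConfig) -> float:
    """P(delta_ij = 1) for an arbitrary route.

    By exchangeability of routes (the admissible configuration set is
    invariant under area relabeling) this is sum_Delta p(Delta) * Delta / K.
    """
    support, pmf = delta_count_pmf(config)
    return float(np.sum(pmf * support) / config.K)


# ----------------------------------------------------------------------
# prior on mu (and the hyper-mean m)


def log_prior_mu(mu: float, m: float | None, config: PriorConfig) -> float:
    """Log prior density of the average dispersal rate.

    Default: Gamma(rate_shape, rate_rate = T) at mu.  Alternative: joint
    density of (mu, m) — exponential with mean m at mu, times the
    Gamma(hyper_shape, hyper_rate) hyperprior at m.
    """
    if mu <= 0:
        return NEG_INF
    if config.rate_prior == "default":
        return float(
            stats.gamma.logpdf(mu, a=config.rate_shape, scale=1.0 / config.rate_rate)
        )
    if m is None:
        raise ValueError("alternative rate prior requires the hyper-mean m")
    if m <= 0:
        return NEG_INF
    log_exp = -math.log(m) - mu / m
    log_hyper = stats.gamma.logpdf(m, a=config.hyper_shape, scale=1.0 / config.hyper_rate)
    return float(log_exp + log_hyper)


def log_prior_relative_rates(r: np.ndarray, config: PriorConfig) -> float:
    """i.i.d. exponential prior on the relative dispersal rates."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r <= 0):
        return NEG_INF
    lam = config.rr_rate
    return float(r.size * math.log(lam) - lam * r.sum())


def log_prior_params(params: GeoModelParams, config: PriorConfig) -> float:
    """Joint log prior of (mu, r, delta [, m])."""
    lp = log_prior_delta(params.delta, config)
    if lp == NEG_INF:
        return NEG_INF
    lp += log_prior_mu(params.mu, params.m, config)
    lp += log_prior_relative_rates(params.r, config)
    return lp


# ----------------------------------------------------------------------
# implied prior on the number of dispersal events


@dataclass
class EventCountPrior:
    """Marginal prior pmf of the number of dispersal events N on {0..n_max}.

    ``mc_se`` is the per-entry Monte Carlo standard error (zeros for the
    closed-form default prior).
    """

    n: np.ndarray
    pmf: np.ndarray
    mc_se: np.ndarray

    @property
    def mean(self) -> float:
        # include the (tiny) truncated tail via its conditional mass at n_max
        return float(np.sum(self.n * self.pmf) / np.sum(self.pmf))

    def quantile(self, q: float) -> int:
        cdf = np.cumsum(self.pmf)
        idx = np.searchsorted(cdf, q)
        return int(self.n[min(idx, self.n.size - 1)])


def prior_event_count_distribution(
    config: PriorConfig,
    T: float | None = None,
    n_max: int = 200,
    n_mc: int = 200_000,
    seed: int = 0,
) -> EventCountPrior:
    """Marginal pmf of N where N | mu ~ Poisson(mu * T).

    Default rate prior: mu ~ Gamma(a, T) mixed with Poisson(mu T) is
    negative binomial with size a and success probability 1/2 — independent
    of T.  Alternative: averaged over the (m, mu) hierarchy by Monte Carlo
    on m using the analytic geometric mixture given m.
    """
    if T is None:
        T = config.T
    n = np.arange(n_max + 1)
    if config.rate_prior == "default":
        # beta = T cancels T exactly: p = beta/(beta+T) = 1/2
        a = config.rate_shape
        p = config.rate_rate / (config.rate_rate + T)
        pmf = stats.nbinom.pmf(n, a, p)
        return EventCountPrior(n=n, pmf=pmf, mc_se=np.zeros_like(pmf))
    rng = np.random.default_rng(seed)
    m = rng.gamma(shape=config.hyper_shape, scale=1.0 / config.hyper_rate, size=n_mc)
    # mu | m ~ Exp(mean m)  =>  N | m ~ NB(1, 1/(1 + mT)) (geometric)
    p_m = 1.0 / (1.0 + m * T)
    logpmf_given_m = np.log(p_m)[:, None] + n[None, :] * np.log1p(-p_m)[:, None]
    pmf_given_m = np.exp(logpmf_given_m)
    pmf = pmf_given_m.mean(axis=0)
    se = pmf_given_m.std(axis=0, ddof=1) / math.sqrt(n_mc)
    return EventCountPrior(n=n, pmf=pmf, mc_se=se)


# ----------------------------------------------------------------------
# prior sampling (initialization, prior-predictive work)


def sample_from_prior(config: PriorConfig, rng: np.random.Generator) -> GeoModelParams:
    """Draw (mu, r, delta [, m]) from the configured joint prior."""
    support, pmf = delta_count_pmf(config)
    d = int(rng.choice(support, p=pmf))
    K = config.K
    # uniform admissible configuration with Delta = d by rejection
    delta = np.zeros(K, dtype=np.int64)
    while True:
        delta[:] = 0
        delta[rng.choice(K, size=d, replace=False)] = 1
        if not config.symmetric or is_irreducible(delta, config.k, True):
            break
    r = rng.exponential(scale=1.0 / config.rr_rate, size=K)
    if config.rate_prior == "default":
        mu = rng.gamma(shape=config.rate_shape, scale=1.0 / config.rate_rate)
        m = None
    else:
        m = rng.gamma(shape=config.hyper_shape, scale=1.0 / config.hyper_rate)
        mu = rng.exponential(scale=m)
    return GeoModelParams(
        symmetric=config.symmetric, r=r, delta=delta, mu=float(max(mu, 1e-300)), m=m
    )
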