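"""Metropolis-Hastings sampler for the dispersal model.

Samples (mu, r, delta [, m]) from ``prior x likelihood^beta``; ``beta = 1``
is the posterior, ``beta = 0`` the prior, intermediate powers are the
stones of the stepping-stone marginal-likelihood ladder.

Move set (standard for indicator-based variable selection):

* multiplier (log-scale random walk) on mu, window auto-tuned in burn-in;
* multiplier on a single randomly chosen relative rate;
* single-indicator flip on delta (proposals that break irreducibility are
  rejected through the -inf prior);
* paired flip that turns one route on and another off, preserving Delta;
* multiplier on the hyper-mean m (alternative rate prior only).

Tuning windows are frozen after burn-in so retained samples come from a
fixed Markov kernel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctmc import GeoModelParams, LikelihoodEvaluator, build_rate_matrix, route_pairs
from .priors import (
    NEG_INF,
    PriorConfig,
    count_configurations,
    delta_count_pmf,
    is_irreducible,
    log_prior_mu,
    log_prior_relative_rates,
)

__all__ = ["McmcSettings", "Trace", "run_mcmc", "effective_sample_size"]


@dataclass
class McmcSettings:
    chain_length: int = 50_000
    burnin_fraction: float = 0.25
    thin: int = 10
    seed: int = 1
    power: float = 1.0
    move_weights: dict[str, float] = field(default_factory=dict)
    tune_interval: int = 50
    target_acceptance: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.power <= 1.0:
            raise ValueError("power must lie in [0, 1]")
        if not 0.0 <= self.burnin_fraction < 1.0:
            raise ValueError("burnin_fraction must lie in [0, 1)")
        if self.chain_length <= self.burnin:
            raise ValueError("chain length must exceed burn-in")

    @property
    def burnin(self) -> int:
        return int(self.chain_length * self.burnin_fraction)


@dataclass
class Trace:
    """Retained MCMC samples plus the settings that produced them."""

    samples: pd.DataFrame
    settings: McmcSettings
    prior: PriorConfig
    acceptance: dict[str, tuple[int, int]]

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def delta_columns(self) -> list[str]:
        return [c for c in self.samples.columns if c.startswith("d_")]

    @property
    def r_columns(self) -> list[str]:
        return [c for c in self.samples.columns if c.startswith("r_")]

    def params_at(self, row: int) -> GeoModelParams:
        s = self.samples.iloc[row]
        return GeoModelParams(
            symmetric=self.prior.symmetric,
            r=s[self.r_columns].to_numpy(dtype=float),
            delta=s[self.delta_columns].to_numpy(dtype=float).astype(int),
            mu=float(s["mu"]),
            m=float(s["m"]) if "m" in s.index else None,
        )

    def write_log(self, path) -> None:
        """BEAST-log-like TSV with a '#' settings header."""
        with open(path, "w") as fh:
            fh.write(f"# phylodisp trace; seed={self.settings.seed} "
                     f"chain_length={self.settings.chain_length} "
                     f"burnin={self.settings.burnin} thin={self.settings.thin} "
                     f"power={self.settings.power}\n")
            fh.write(f"# prior: routes={self.prior.routes_prior} "
                     f"rate={self.prior.rate_prior} symmetric={self.prior.symmetric} "
                     f"k={self.prior.k} T={self.prior.T:.6g} lam={self.prior.lam:.6g}\n")
            self.samples.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_log(cls, path, settings=None, prior=None) -> "Trace":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(samples=df, settings=settings, prior=prior, acceptance={})


class _DeltaPriorTable:
    """Log prior of a delta configuration as a fast table lookup by Delta."""

    def __init__(self, config: PriorConfig):
        self.config = config
        support, pmf = delta_count_pmf(config)
        self.lo = int(support[0])
        with np.errstate(divide="ignore"):
            logpmf = np.log(pmf)
        counts = np.array(
            [count_configurations(config.k, int(d), config.symmetric, config.symmetric)
             for d in support], dtype=float)
        with np.errstate(divide="ignore"):
            self.table = logpmf - np.log(counts)

    def __call__(self, delta: np.ndarray) -> float:
        d = int(delta.sum())
        idx = d - self.lo
        if idx < 0 or idx >= self.table.size:
            return NEG_INF
        if self.config.symmetric and not is_irreducible(delta, self.config.k, True):
            return NEG_INF
        return float(self.table[idx])


def _init_params(config: PriorConfig, rng: np.random.Generator) -> GeoModelParams:
    K = config.K
    mu = float(rng.gamma(shape=0.5, scale=1.0 / config.rate_rate)) or 1e-6
    m = 1.0 if config.rate_prior == "alternative" else None
    return GeoModelParams(
        symmetric=config.symmetric,
        r=np.ones(K),
        delta=np.ones(K, dtype=np.int64),  # all routes on: always irreducible
        mu=max(mu, 1e-12),
        m=m,
    )


def run_mcmc(
    tree,
    data,
    prior: PriorConfig,
    settings: McmcSettings,
    root_freqs: np.ndarray | None = None,
    init: GeoModelParams | None = None,
) -> Trace:
    """Run the sampler; deterministic given the seed.

    ``data`` may be None for prior-only runs (power = 0), in which case the
    likelihood column is NaN.
    """
    rng = np.random.default_rng(settings.seed)
    beta = settings.power
    evaluator = None
    if data is not None:
        evaluator = LikelihoodEvaluator(tree, data, root_freqs)
    elif beta > 0:
        raise ValueError("power > 0 requires data")

    delta_prior = _DeltaPriorTable(prior)
    params = init.copy() if init is not None else _init_params(prior, rng)
    K = prior.K

    def loglik(p: GeoModelParams) -> float:
        if evaluator is None:
            return float("nan")
        return evaluator.log_likelihood(build_rate_matrix(p, prior.k))

    def logprior(p: GeoModelParams) -> float:
        lp = delta_prior(p.delta)
        if lp == NEG_INF:
            return NEG_INF
        return lp + log_prior_mu(p.mu, p.m, prior) + log_prior_relative_rates(p.r, prior)

    cur_prior = logprior(params)
    cur_lik = loglik(params) if beta > 0 else float("nan")
    if not np.isfinite(cur_prior) or (beta > 0 and not np.isfinite(cur_lik)):
        raise RuntimeError("non-finite density at the initial state")

    weights = {"mu": 1.0, "r": 2.0, "delta_flip": 2.0, "delta_swap": 1.0}
    if prior.symmetric and K == prior.k - 1:
        # every route is required for irreducibility: no indicator moves
        weights["delta_flip"] = 0.0
        weights["delta_swap"] = 0.0
    if prior.rate_prior == "alternative":
        weights["m"] = 1.0
    weights.update(settings.move_weights)
    moves = [mv for mv, w in weights.items() if w > 0]
    probs = np.array([weights[mv] for mv in moves])
    probs = probs / probs.sum()

    windows = {"mu": 1.0, "r": 1.0, "m": 1.0}
    accepted = {mv: 0 for mv in moves}
    proposed = {mv: 0 for mv in moves}
    win_acc = {mv: 0 for mv in moves}
    win_prop = {mv: 0 for mv in moves}

    pairs = route_pairs(prior.k, prior.symmetric)
    colnames = (["state", "mu"]
                + (["m"] if prior.rate_prior == "alternative" else [])
                + [f"r_{i}_{j}" for i, j in pairs]
                + [f"d_{i}_{j}" for i, j in pairs]
                + ["Delta", "log_prior", "log_likelihood", "log_posterior"])
    records: list[list[float]] = []

    def record(it: int) -> None:
        lik = cur_lik if beta > 0 else loglik(params)
        row = [float(it), params.mu]
        if prior.rate_prior == "alternative":
            row.append(params.m)
        row.extend(params.r.tolist())
        row.extend(params.delta.tolist())
        row.extend([
            float(params.n_active), cur_prior, lik,
            cur_prior + (beta * lik if beta > 0 and np.isfinite(lik) else 0.0),
        ])
        records.append(row)

    move_idx = rng.choice(len(moves), size=settings.chain_length, p=probs)
    for it in range(settings.chain_length):
        mv = moves[move_idx[it]]
        proposed[mv] += 1
        win_prop[mv] += 1
        log_hastings = 0.0
        prop = params
        new_lik_needed = True

        if mv == "mu":
            w = windows["mu"]
            fac = math.exp(w * (rng.random() - 0.5))
            prop = params.copy()
            prop.mu = params.mu * fac
            log_hastings = math.log(fac)
        elif mv == "m":
            w = windows["m"]
            fac = math.exp(w * (rng.random() - 0.5))
            prop = params.copy()
            prop.m = params.m * fac
            log_hastings = math.log(fac)
            new_lik_needed = False  # m does not enter the likelihood
        elif mv == "r":
            idx = int(rng.integers(K))
            w = windows["r"]
            fac = math.exp(w * (rng.random() - 0.5))
            prop = params.copy()
            prop.r[idx] *= fac
            log_hastings = math.log(fac)
            new_lik_needed = bool(params.delta[idx])
        elif mv == "delta_flip":
            idx = int(rng.integers(K))
            prop = params.copy()
            prop.delta[idx] = 1 - prop.delta[idx]
        else:  # delta_swap
            on = np.flatnonzero(params.delta == 1)
            off = np.flatnonzero(params.delta == 0)
            if on.size == 0 or off.size == 0:
                prop = None  # nothing to swap: counts as a rejected proposal
            else:
                prop = params.copy()
                prop.delta[on[rng.integers(on.size)]] = 0
                prop.delta[off[rng.integers(off.size)]] = 1

        new_prior = logprior(prop) if prop is not None else NEG_INF
        if new_prior == NEG_INF:
            accept = False
            new_lik = cur_lik
        else:
            if beta > 0 and new_lik_needed:
                new_lik = loglik(prop)
            else:
                new_lik = cur_lik
            log_ratio = new_prior - cur_prior + log_hastings
            if beta > 0:
                if new_lik == NEG_INF:
                    log_ratio = NEG_INF
                else:
                    log_ratio += beta * (new_lik - cur_lik)
            accept = log_ratio >= 0 or rng.random() < math.exp(max(log_ratio, -745.0))
        if accept:
            params = prop
            cur_prior = new_prior
            cur_lik = new_lik
            accepted[mv] += 1
            win_acc[mv] += 1

        # window tuning during burn-in only
        if it < settings.burnin and (it + 1) % settings.tune_interval == 0:
            for name in windows:
                if win_prop.get(name, 0) >= 10:
                    rate = win_acc[name] / win_prop[name]
                    windows[name] *= math.exp(0.5 * (rate - settings.target_acceptance))
                    windows[name] = min(max(windows[name], 1e-3), 20.0)
                    win_acc[name] = 0
                    win_prop[name] = 0

        if it >= settings.burnin and (it - settings.burnin) % settings.thin == 0:
            record(it)

    for mv in moves:
        if proposed[mv] > 0 and accepted[mv] == 0:
            warnings.warn(f"move {mv!r} never accepted", RuntimeWarning)

    df = pd.DataFrame(records, columns=colnames)
    return Trace(
        samples=df,
        settings=settings,
        prior=prior,
        acceptance={mv: (accepted[mv], proposed[mv]) for mv in moves},
    )


def effective_sample_size(x: np.ndarray | pd.Series) -> float:
    """Autocorrelation-time effective sample size of one trace column."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 100:
        raise ValueError("need at least 100 retained samples for ESS")
    if np.allclose(x, x[0]):
        warnings.warn("constant trace column; ESS set to the sample count",
                      RuntimeWarning)
        return float(x.size)
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(x[None, :]))
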