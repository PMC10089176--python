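"""Model and results objects for discrete-geographic inference.

`DiscreteGeographyModel` binds the fixed inputs — a time tree, the tip
areas, the Q-matrix symmetry and the prior model (default or alternative,
per component) — the way a statsmodels model binds endog/exog.  `fit()`
runs the MCMC sampler and returns a :class:`DispersalResults` carrying the
trace; everything downstream (route Bayes factors, marginal likelihoods,
ancestral areas, event counts, adequacy checks, summaries) hangs off the
results object.
"""

from __future__ import annotations

import math
from dataclasses import replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import evidence, histories as hist_mod, ppcheck
from .ctmc import GeoModelParams, LikelihoodEvaluator, build_rate_matrix, route_pairs
from .geodata import GeographicData, read_tip_areas
from .mcmc import McmcSettings, Trace, effective_sample_size, run_mcmc
from .priors import PriorConfig, log_prior_params, resolve_prior_config
from .tree import Tree, read_newick_tree, write_newick

__all__ = ["DiscreteGeographyModel", "DispersalResults"]


class DiscreteGeographyModel:
    """Bayesian CTMC dispersal model on a fixed time tree.

    Parameters
    ----------
    tree : Tree
        Rooted time-calibrated phylogeny; never re-estimated.
    data : GeographicData
        Observed area of every tip.
    symmetric : bool
        Whether dispersal rates are constrained to q_ij = q_ji.
    routes_prior, rate_prior : {"default", "alternative"}
        Prior model per component (see :mod:`phylodisp.priors`).
    """

    def __init__(
        self,
        tree: Tree,
        data: GeographicData,
        *,
        symmetric: bool = True,
        routes_prior: str = "default",
        rate_prior: str = "default",
        root_freqs: np.ndarray | None = None,
        delta_prior_style: str = "per-delta-count",
    ):
        tree.validate_for_inference()
        self.tree = tree
        self.data = data
        self.root_freqs = (
            np.full(data.k, 1.0 / data.k) if root_freqs is None else np.asarray(root_freqs)
        )
        self.prior = resolve_prior_config(
            routes_prior=routes_prior,
            rate_prior=rate_prior,
            k=data.k,
            T=tree.tree_length,
            symmetric=symmetric,
            delta_prior_style=delta_prior_style,
        )
        self._evaluator = LikelihoodEvaluator(tree, data, self.root_freqs)

    @classmethod
    def from_files(cls, tree_path, tips_path, *, areas=None, **kwargs):
        tree = read_newick_tree(Path(tree_path).read_text())
        data = read_tip_areas(Path(tips_path).read_text(), tree, areas=areas)
        return cls(tree, data, **kwargs)

    # ------------------------------------------------------------------
    def loglike(self, params: GeoModelParams) -> float:
        return self._evaluator.log_likelihood(build_rate_matrix(params, self.data.k))

    def logprior(self, params: GeoModelParams) -> float:
        return log_prior_params(params, self.prior)

    def fit(
        self,
        chain_length: int = 50_000,
        burnin_fraction: float = 0.25,
        thin: int = 10,
        seed: int = 1,
        **mcmc_kwargs,
    ) -> "DispersalResults":
        settings = McmcSettings(
            chain_length=chain_length,
            burnin_fraction=burnin_fraction,
            thin=thin,
            seed=seed,
            **mcmc_kwargs,
        )
        trace = run_mcmc(self.tree, self.data, self.prior, settings, self.root_freqs)
        return DispersalResults(self, trace)

    def log_marginal_likelihood(
        self,
        n_stones: int = 32,
        chain_length: int = 8_000,
        seed: int = 1,
        n_replicates: int = 1,
        **mcmc_kwargs,
    ) -> tuple[float, float]:
        """Stepping-stone log marginal likelihood (mean, uncertainty).

        With one replicate the uncertainty is the batch-means SE; with
        several it is the SD across independent replicate estimates.
        """
        estimates, ses = [], []
        for rep in range(n_replicates):
            settings = McmcSettings(
                chain_length=chain_length, seed=seed + 7919 * rep, **mcmc_kwargs
            )
            stones = evidence.run_power_posterior(
                self.tree, self.data, self.prior, settings,
                n_stones=n_stones, root_freqs=self.root_freqs,
            )
            est, se = evidence.stepping_stone_log_marginal(stones)
            estimates.append(est)
            ses.append(se)
        if n_replicates == 1:
            return estimates[0], ses[0]
        return float(np.mean(estimates)), float(np.std(estimates, ddof=1))


class DispersalResults:
    """Posterior sample and derived summaries for one fitted model."""

    def __init__(self, model: DiscreteGeographyModel, trace: Trace):
        self.model = model
        self.trace = trace
        self.prior = model.prior

    # -- parameter summaries -------------------------------------------
    @property
    def samples(self) -> pd.DataFrame:
        return self.trace.samples

    def posterior_mean(self, column: str) -> float:
        return float(self.samples[column].mean())

    def credible_interval(self, column: str, level: float = 0.95) -> tuple[float, float]:
        lo, hi = (1 - level) / 2, (1 + level) / 2
        q = self.samples[column].quantile([lo, hi])
        return float(q.iloc[0]), float(q.iloc[1])

    def posterior_mean_rate_matrix(self) -> np.ndarray:
        """Posterior mean of Q entry-wise (the quantity heatmapped in
        prior-sensitivity comparisons)."""
        k = self.model.data.k
        acc = np.zeros((k, k))
        for row in range(len(self.trace)):
            acc += build_rate_matrix(self.trace.params_at(row), k).Q
        return acc / len(self.trace)

    def ess(self) -> dict[str, float]:
        out = {}
        for col in ("mu", "Delta", "log_likelihood"):
            if col in self.samples and self.samples[col].notna().all():
                out[col] = effective_sample_size(self.samples[col].to_numpy())
        return out

    # -- route support -------------------------------------------------
    def route_support(self) -> pd.DataFrame:
        supports = evidence.route_bayes_factors(self.trace, self.prior)
        return evidence.route_support_frame(supports, areas=self.model.data.areas)

    # -- conditional histories -----------------------------------------
    def sample_histories(self, seed: int = 1, max_histories: int | None = None):
        """One conditional history per retained posterior sample (thinned
        uniformly to ``max_histories`` if given), marginalizing over Q."""
        rng = np.random.default_rng(seed)
        n = len(self.trace)
        rows = np.arange(n)
        if max_histories is not None and max_histories < n:
            rows = np.linspace(0, n - 1, max_histories).astype(int)
        out = []
        for row in rows:
            Q = build_rate_matrix(self.trace.params_at(int(row)), self.model.data.k)
            out.append(hist_mod.sample_conditional_history(
                self.model.tree, self.model.data, Q,
                self.model.root_freqs, rng, evaluator=self.model._evaluator,
            ))
        return out

    def ancestral_areas(self, histories=None, **kw) -> pd.DataFrame:
        if histories is None:
            histories = self.sample_histories(**kw)
        return hist_mod.ancestral_area_probabilities(histories)

    def event_counts(self, histories=None, **kw) -> dict:
        if histories is None:
            histories = self.sample_histories(**kw)
        return hist_mod.count_dispersal_events(histories)

    def annotated_newick(self, histories=None, **kw) -> str:
        """Newick with per-node [&area_probs={...},MAP_area=...] comments."""
        table = self.ancestral_areas(histories, **kw)
        areas = self.model.data.areas
        comments = {}
        for node in self.model.tree.internal_nodes:
            probs = ",".join(
                f"{table.loc[node, f'p_{a}']:.4f}" for a in range(len(areas))
            )
            map_area = areas[int(table.loc[node, "map_area"])]
            comments[node] = f"[&area_probs={{{probs}}},MAP_area={map_area}]"
        return write_newick(self.model.tree, comments)

    # -- adequacy ------------------------------------------------------
    def posterior_predictive_check(
        self, n_draws: int = 200, seed: int = 1, statistics: dict | None = None
    ) -> list[ppcheck.AdequacyReport]:
        """Simulate predictive datasets from posterior draws and score the
        observed data against them."""
        if statistics is None:
            statistics = {
                "parsimony": lambda d: ppcheck.parsimony_statistic(self.model.tree, d),
                "multinomial": lambda d: ppcheck.tipwise_multinomial_statistic(d),
            }
        rng = np.random.default_rng(seed)
        n = len(self.trace)
        rows = np.linspace(0, n - 1, min(n_draws, n)).astype(int)
        preds = {name: [] for name in statistics}
        for row in rows:
            draw = self.trace.params_at(int(row))
            rep = ppcheck.simulate_predictive_dataset(
                self.model.tree, draw, self.model.root_freqs, rng,
                areas=self.model.data.areas,
            )
            for name, fn in statistics.items():
                preds[name].append(fn(rep))
        reports = []
        for name, fn in statistics.items():
            obs = fn(self.model.data)
            reports.append(ppcheck.posterior_predictive_pvalue(
                obs, np.array(preds[name], dtype=float), statistic=name))
        return reports

    # -- plotting ------------------------------------------------------
    def plot_trace(self, columns=("mu", "Delta", "log_likelihood"), axes=None):
        """Sampled-value and histogram panels per trace column."""
        import matplotlib.pyplot as plt

        columns = [c for c in columns if c in self.samples]
        if axes is None:
            _, axes = plt.subplots(len(columns), 2,
                                   figsize=(8, 2.2 * len(columns)), squeeze=False)
        for ax_row, col in zip(axes, columns):
            vals = self.samples[col]
            ax_row[0].plot(self.samples["state"], vals, lw=0.5)
            ax_row[0].set_ylabel(col)
            ax_row[1].hist(vals.dropna(), bins=40, density=True)
        axes[-1][0].set_xlabel("iteration")
        return axes

    def plot_route_support(self, ax=None, min_two_ln_bf: float = 2.0):
        """Bar plot of 2lnBF per dispersal route, shaded by support level."""
        import matplotlib.pyplot as plt

        df = self.route_support()
        df = df[df["twolnBF"] > min_two_ln_bf]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.4 * max(len(df), 4) + 1))
        labels = [f"{r['from']}–{r['to']}" for _, r in df.iterrows()]
        ax.barh(labels[::-1], df["twolnBF"].to_numpy()[::-1])
        for threshold in (2, 6, 10):
            ax.axvline(threshold, color="0.6", lw=0.8, ls="--")
        ax.set_xlabel("2 ln BF")
        return ax

    # -- presentation --------------------------------------------------
    def summary(self) -> str:
        lines = []
        pr = self.prior
        lines.append("Discrete-geographic dispersal model")
        lines.append("=" * 64)
        lines.append(f"areas (k):        {self.model.data.k}"
                     f"    tips: {self.model.tree.n_tips}"
                     f"    tree length T: {self.model.tree.tree_length:.4g}")
        lines.append(f"Q symmetry:       {'symmetric' if pr.symmetric else 'asymmetric'}")
        lines.append(f"routes prior:     {pr.routes_prior} "
                     f"(Poisson lam={pr.lam:.4g}, offset={pr.offset})")
        lines.append(f"rate prior:       {pr.rate_prior}")
        lines.append(f"retained samples: {len(self.trace)}")
        lines.append("-" * 64)
        header = f"{'parameter':<14}{'mean':>12}{'2.5%':>12}{'97.5%':>12}{'ESS':>10}"
        lines.append(header)
        ess = self.ess()
        for col in ["mu"] + (["m"] if "m" in self.samples else []) + ["Delta"]:
            lo, hi = self.credible_interval(col)
            e = ess.get(col, float("nan"))
            lines.append(f"{col:<14}{self.posterior_mean(col):>12.4g}"
                         f"{lo:>12.4g}{hi:>12.4g}{e:>10.0f}")
        lines.append("-" * 64)
        top = self.route_support().head(5)
        lines.append("top routes by 2lnBF:")
        for _, r in top.iterrows():
            lines.append(f"  {r['from']} - {r['to']}: post_p={r['post_p']:.3f} "
                         f"2lnBF={r['twolnBF']:+.2f} ({r['category']})")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<DispersalResults: k={self.model.data.k}, "
                f"{len(self.trace)} samples, "
                f"mean mu={self.posterior_mean('mu'):.4g}>")
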