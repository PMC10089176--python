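"""Posterior-predictive adequacy checks.

If a fitted dispersal model describes the process that generated the tip
areas, replicate datasets simulated from its posterior should resemble the
observed data.  Replicates are simulated forward along the fixed tree from
posterior draws of (r, delta, mu); the resemblance is scored by summary
statistics of the tip-area pattern:

* the Fitch parsimony score — the minimum number of dispersal events any
  history needs to explain the tips (sensitive to phylogenetic clustering
  of areas), and
* a tipwise multinomial statistic, sum_a n_a ln(n_a / n) over area counts
  (sensitive to the evenness of the area frequencies).

Both statistics are conventional discrete-character adequacy summaries;
the statistic set is pluggable.  A two-sided posterior-predictive p-value
(doubled minimum tail) below the threshold flags inadequacy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ctmc import GeoModelParams, RateMatrix, build_rate_matrix
from .geodata import GeographicData
from .tree import Tree

__all__ = [
    "simulate_predictive_dataset",
    "parsimony_statistic",
    "tipwise_multinomial_statistic",
    "posterior_predictive_pvalue",
    "AdequacyReport",
]


def _forward_states(tree: Tree, Q: np.ndarray, root_state: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Forward CTMC simulation of node states down every branch (no event
    times retained)."""
    k = Q.shape[0]
    states = np.full(tree.n_nodes, -1, dtype=np.int64)
    states[tree.root] = root_state
    for node in tree.preorder:
        if node == tree.root:
            continue
        state = states[tree.parent[node]]
        t = tree.branch_length[node]
        now = 0.0
        while True:
            rate = -Q[state, state]
            if rate <= 0:
                break
            now += rng.exponential(1.0 / rate)
            if now >= t:
                break
            probs = Q[state].copy()
            probs[state] = 0.0
            state = int(rng.choice(k, p=probs / probs.sum()))
        states[node] = state
    return states


def simulate_predictive_dataset(
    tree: Tree,
    draw: GeoModelParams,
    root_freqs: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    areas: tuple[str, ...] | None = None,
) -> GeographicData:
    """Simulate one replicate tip-area dataset from a posterior draw."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    k = draw.k_for()
    if root_freqs is None:
        root_freqs = np.full(k, 1.0 / k)
    Q = build_rate_matrix(draw, k)
    root_state = int(rng.choice(k, p=np.asarray(root_freqs)))
    states = _forward_states(tree, Q.Q, root_state, rng)
    if areas is None:
        areas = tuple(f"area{i}" for i in range(k))
    return GeographicData(
        areas=areas,
        tip_area={label: int(states[node]) for node, label in tree.tip_labels.items()},
    )


def parsimony_statistic(tree: Tree, data: GeographicData) -> int:
    """Minimum number of dispersal events explaining the tip areas.

    Unit-cost Sankoff dynamic programme (equals the Fitch count on binary
    trees, exact for any arity).
    """
    tip_state = data.tip_state_vector(tree)
    k = data.k
    INF = 10 ** 9
    cost = np.zeros((tree.n_nodes, k), dtype=np.int64)
    for node in tree.postorder:
        ch = tree.children(node)
        if not ch:
            cost[node] = INF
            cost[node, tip_state[node]] = 0
            continue
        total = np.zeros(k, dtype=np.int64)
        for c in ch:
            child = cost[c]
            total += np.minimum(child, child.min() + 1)
        cost[node] = total
    return int(cost[tree.root].min())


def tipwise_multinomial_statistic(data: GeographicData) -> float:
    """sum_a n_a ln(n_a / n) over observed areas (0 ln 0 := 0)."""
    counts = data.area_counts()
    n = counts.sum()
    val = 0.0
    for c in counts:
        if c > 0:
            val += c * math.log(c / n)
    return val


@dataclass
class AdequacyReport:
    statistic: str
    observed: float
    predictive: np.ndarray
    lower_tail: float
    upper_tail: float
    p_value: float
    inadequate: bool

    def __repr__(self) -> str:  # compact, table-friendly
        return (f"AdequacyReport({self.statistic}: obs={self.observed:.4g}, "
                f"p={self.p_value:.4g}{', INADEQUATE' if self.inadequate else ''})")


def posterior_predictive_pvalue(
    observed: float,
    predictive: np.ndarray,
    statistic: str = "statistic",
    alpha: float = 0.05,
) -> AdequacyReport:
    """Two-sided posterior-predictive p-value (doubled minimum tail)."""
    predictive = np.asarray(predictive, dtype=np.float64)
    if predictive.size < 100:
        raise ValueError("need at least 100 predictive draws")
    lower = float(np.mean(predictive <= observed))
    upper = float(np.mean(predictive >= observed))
    p = min(2.0 * min(lower, upper), 1.0)
    if p == 0.0:
        p = 2.0 / (predictive.size + 1)
    return AdequacyReport(
        statistic=statistic,
        observed=float(observed),
        predictive=predictive,
        lower_tail=lower,
        upper_tail=upper,
        p_value=p,
        inadequate=p < alpha,
    )
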