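"""Endpoint-conditioned dispersal histories (stochastic mapping).

A *conditional history* is a realized, timed sequence of dispersal events
over the whole tree that is consistent with the observed tip areas — a
draw from the distribution of geographic histories given (Q, tree, data).
Histories are sampled in two stages:

1. node states: a pruning down-pass computes partial likelihoods, then a
   preorder up-pass draws every node's area from its joint conditional
   distribution;
2. branch interiors: each branch is filled in by endpoint-conditioned CTMC
   sampling via uniformization — jumps of a dominating Poisson process are
   thinned through the discrete kernel R = I + Q/omega, with the number of
   jumps drawn from its exact conditional distribution given the branch
   endpoints.

Summaries over a collection of histories give ancestral-area probability
tables (the proportion of histories placing a node in each area) and
dispersal-event count matrices with per-source percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctmc import LikelihoodEvaluator, RateMatrix, transition_probabilities

__all__ = [
    "DispersalHistory",
    "sample_conditional_history",
    "sample_branch_path_uniformization",
    "sample_branch_path_rejection",
    "ancestral_area_probabilities",
    "count_dispersal_events",
]


@dataclass
class DispersalHistory:
    """One realized dispersal history over a fixed tree.

    ``events[node]`` lists (time_from_branch_start, from_area, to_area) for
    the branch subtending ``node``; ``node_state[i]`` is the realized area
    at node ``i``.
    """

    node_state: np.ndarray
    events: dict[int, list[tuple[float, int, int]]]
    tree: object = field(repr=False, default=None)
    k: int = 0

    @property
    def n_events(self) -> int:
        return sum(len(ev) for ev in self.events.values())

    def event_count_matrix(self) -> np.ndarray:
        counts = np.zeros((self.k, self.k), dtype=np.int64)
        for ev in self.events.values():
            for _, a, b in ev:
                counts[a, b] += 1
        return counts

    def validate(self) -> None:
        """Chain consistency: events on each branch link parent to child."""
        for node, ev in self.events.items():
            state = self.node_state[self.tree.parent[node]]
            t_prev = 0.0
            for t, a, b in ev:
                if a != state or t < t_prev or a == b:
                    raise AssertionError("inconsistent event chain")
                state, t_prev = b, t
            if state != self.node_state[node]:
                raise AssertionError("branch endpoint does not match node state")


# ----------------------------------------------------------------------
# branch-level endpoint-conditioned sampling


def _uniformization_kernel(Q: np.ndarray) -> tuple[float, np.ndarray]:
    omega = float(np.max(-np.diag(Q)))
    if omega <= 0.0:
        return 0.0, np.eye(Q.shape[0])
    R = np.eye(Q.shape[0]) + Q / omega
    return omega, R


def sample_branch_path_uniformization(
    Q: np.ndarray,
    t: float,
    a: int,
    b: int,
    rng: np.random.Generator,
    rel_tol: float = 1e-10,
) -> list[tuple[float, int, int]]:
    """Sample a CTMC path on [0, t] conditioned on X(0)=a, X(t)=b.

    Exact in distribution: the number of uniformized jumps n is drawn from
    P(n | a, b, t) ∝ Pois(n; omega t) * (R^n)[a, b], with the series
    truncated once the accumulated mass reaches 1 - rel_tol of P_t[a, b];
    jump states then follow the discrete bridge through powers of R, and
    virtual (self) jumps are discarded.
    """
    omega, R = _uniformization_kernel(Q)
    if omega * t == 0.0:
        if a != b:
            raise ValueError("zero-rate or zero-duration branch with unequal endpoints")
        return []
    # powers of R up to truncation
    pois = math.exp(-omega * t)
    Rn = [np.eye(Q.shape[0])]
    weights = [pois * Rn[0][a, b]]
    total_target = transition_probabilities(Q, t)[a, b]
    if total_target <= 0:
        raise ValueError("endpoint pair has zero probability")
    n = 0
    acc = weights[0]
    while acc < (1.0 - rel_tol) * total_target and n < 10_000:
        n += 1
        pois *= omega * t / n
        Rn.append(Rn[-1] @ R)
        weights.append(pois * Rn[n][a, b])
        acc += weights[-1]
    w = np.asarray(weights)
    w = np.maximum(w, 0.0)
    n_jumps = int(rng.choice(w.size, p=w / w.sum()))
    if n_jumps == 0:
        return []
    # bridge through the discrete chain
    states = [a]
    for i in range(1, n_jumps + 1):
        prev = states[-1]
        back = Rn[n_jumps - i][:, b]
        probs = R[prev] * back
        probs = np.maximum(probs, 0.0)
        states.append(int(rng.choice(probs.size, p=probs / probs.sum())))
    times = np.sort(rng.uniform(0.0, t, size=n_jumps))
    path = []
    cur = a
    for tt, s in zip(times, states[1:]):
        if s != cur:  # drop virtual jumps
            path.append((float(tt), cur, int(s)))
            cur = int(s)
    return path


def sample_branch_path_rejection(
    Q: np.ndarray,
    t: float,
    a: int,
    b: int,
    rng: np.random.Generator,
    max_tries: int = 1_000_000,
) -> list[tuple[float, int, int]]:
    """Forward-simulate-and-reject sampler; test oracle for uniformization."""
    k = Q.shape[0]
    for _ in range(max_tries):
        path: list[tuple[float, int, int]] = []
        state, now = a, 0.0
        while True:
            rate = -Q[state, state]
            if rate <= 0:
                break
            now += rng.exponential(1.0 / rate)
            if now >= t:
                break
            probs = Q[state].copy()
            probs[state] = 0.0
            nxt = int(rng.choice(k, p=probs / probs.sum()))
            path.append((float(now), state, nxt))
            state = nxt
        if state == b:
            return path
    raise RuntimeError("rejection sampler failed to hit the endpoint")


# ----------------------------------------------------------------------
# whole-tree conditional histories


def sample_conditional_history(
    tree,
    data,
    Q: RateMatrix,
    root_freqs: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    evaluator: LikelihoodEvaluator | None = None,
) -> DispersalHistory:
    """Draw one dispersal history from P(history | G, Q, tree)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if evaluator is None:
        evaluator = LikelihoodEvaluator(tree, data, root_freqs)
    k = evaluator.k
    L, logscale = evaluator.partials(Q)
    if logscale == float("-inf"):
        raise ValueError("zero-likelihood input: no history is consistent")
    from .ctmc import _branch_transition_stack

    if Q.degenerate:
        P = np.broadcast_to(np.eye(k), (tree.n_nodes, k, k)).copy()
    else:
        P = _branch_transition_stack(Q.Q, tree.branch_length)

    node_state = np.full(tree.n_nodes, -1, dtype=np.int64)
    root = tree.root
    probs = evaluator.root_freqs * L[root]
    s = probs.sum()
    if s <= 0:
        raise ValueError("zero-likelihood input at the root")
    node_state[root] = int(rng.choice(k, p=probs / s))
    for node in tree.preorder:
        if node == root:
            continue
        par = node_state[tree.parent[node]]
        probs = P[node][par] * L[node]
        probs = np.maximum(probs, 0.0)
        node_state[node] = int(rng.choice(k, p=probs / probs.sum()))

    events: dict[int, list[tuple[float, int, int]]] = {}
    for node in range(tree.n_nodes):
        if node == root:
            continue
        a, b = int(node_state[tree.parent[node]]), int(node_state[node])
        t = float(tree.branch_length[node])
        if t == 0.0:
            events[node] = []
            continue
        events[node] = sample_branch_path_uniformization(Q.Q, t, a, b, rng)
    return DispersalHistory(node_state=node_state, events=events, tree=tree, k=k)


# ----------------------------------------------------------------------
# summaries


def ancestral_area_probabilities(histories: list[DispersalHistory]) -> pd.DataFrame:
    """Per-node area frequencies across histories, with the MAP area.

    One row per node; columns ``p_<area index>``, ``map_area``, ``map_prob``.
    When each history is drawn under a different posterior sample of Q, the
    table marginalizes over the posterior of Q.
    """
    if not histories:
        raise ValueError("need at least one history")
    tree = histories[0].tree
    if any(h.tree is not tree for h in histories):
        raise ValueError("histories must share a tree")
    k = histories[0].k
    states = np.stack([h.node_state for h in histories])  # (H, nodes)
    n = len(histories)
    rows = []
    for node in range(tree.n_nodes):
        freqs = np.bincount(states[:, node], minlength=k) / n
        rows.append(list(freqs) + [int(freqs.argmax()), float(freqs.max())])
    cols = [f"p_{a}" for a in range(k)] + ["map_area", "map_prob"]
    df = pd.DataFrame(rows, columns=cols)
    df.index.name = "node"
    return df


def count_dispersal_events(
    histories: list[DispersalHistory], ci: float = 0.95
) -> dict:
    """Mean event-count matrix and per-source percentages across histories.

    Returns mean and credible-interval count matrices plus, per source
    area, the percentage of all events originating there (mean and CI over
    the across-history distribution) — the "which area seeds the outbreak"
    summary.
    """
    if not histories:
        raise ValueError("need at least one history")
    k = histories[0].k
    counts = np.stack([h.event_count_matrix() for h in histories]).astype(float)
    lo, hi = (1 - ci) / 2 * 100, (1 + ci) / 2 * 100
    totals = counts.sum(axis=(1, 2))
    source = counts.sum(axis=2)  # (H, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals[:, None] > 0, 100.0 * source / totals[:, None], np.nan)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # event-free history sets
        src_df = pd.DataFrame({
            "source": np.arange(k),
            "pct_mean": np.nanmean(pct, axis=0),
            "pct_lo": np.nanpercentile(pct, lo, axis=0),
            "pct_hi": np.nanpercentile(pct, hi, axis=0),
            "count_mean": source.mean(axis=0),
        })
    return {
        "mean": counts.mean(axis=0),
        "lo": np.percentile(counts, lo, axis=0),
        "hi": np.percentile(counts, hi, axis=0),
        "total_mean": float(totals.mean()),
        "per_source": src_df,
    }
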