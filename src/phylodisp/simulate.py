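"""Synthetic dispersal datasets with known ground truth.

Every stage of the inference pipeline is validated against data generated
here: a random time tree (Yule or Kingman coalescent), a true rate matrix
built from chosen (r, delta, mu), and tip areas produced by exact forward
(Gillespie) simulation of the dispersal process from root to tips.  The
full event history is kept, not just the tips, so inferred ancestral areas
and event counts can be checked against the truth that generated the data.

Scenario defaults are sized like small published discrete-phylogeography
datasets (tens of tips, a handful of areas) while staying cheap enough for
routine test runs; `make_benchmark_suite` writes a deterministic fixture
directory spanning sparse/dense route sets and low/high dispersal rates so
that default-versus-alternative prior contrasts are informative by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ctmc import GeoModelParams, RateMatrix, build_rate_matrix, n_routes, route_pairs
from .geodata import GeographicData
from .histories import DispersalHistory
from .priors import is_irreducible
from .tree import Tree, write_newick

__all__ = [
    "SimulationScenario",
    "simulate_tree",
    "simulate_history_and_tips",
    "make_benchmark_suite",
]


@dataclass
class SimulationScenario:
    """One synthetic study condition.

    ``tree_model`` is "yule" (rate ``birth_rate``) or "coalescent"
    (population size ``pop_size``); the true route set ``delta`` must be
    irreducible when a symmetric model is to be fit to the result.
    """

    n_tips: int = 50
    k: int = 5
    tree_model: str = "yule"
    birth_rate: float = 1.0
    pop_size: float = 1.0
    symmetric: bool = True
    r: np.ndarray | None = None
    delta: np.ndarray | None = None
    mu: float = 1.0
    root_area: int | None = None
    seed: int = 1
    n_replicates: int = 1
    name: str = "scenario"

    def resolve_params(self, rng: np.random.Generator | None = None) -> GeoModelParams:
        K = n_routes(self.k, self.symmetric)
        r = np.ones(K) if self.r is None else np.asarray(self.r, dtype=float)
        delta = np.ones(K, dtype=np.int64) if self.delta is None else np.asarray(self.delta, dtype=np.int64)
        if self.symmetric and delta.sum() and not is_irreducible(delta, self.k, True):
            raise ValueError("true delta must be irreducible for a symmetric fit")
        return GeoModelParams(symmetric=self.symmetric, r=r, delta=delta, mu=self.mu)


def _yule_tree(n_tips: int, birth_rate: float, rng: np.random.Generator) -> Tree:
    """Forward pure-birth simulation until n_tips lineages, then cut."""
    # the root splits at time 0 (no stem branch: the crown tree is what the
    # dispersal process runs over); at j lineages the next split is
    # Exp(j * birth_rate) away
    split_times = [0.0]
    t = 0.0
    for j in range(2, n_tips):
        t += rng.exponential(1.0 / (j * birth_rate))
        split_times.append(t)
    end = t + rng.exponential(1.0 / (n_tips * birth_rate))
    # assemble topology: each split picks a uniform live lineage to divide
    parent: list[int] = [-1]
    blen: list[float] = [0.0]
    birth: list[float] = [0.0]
    live = [0]
    for st in split_times:
        pick = int(rng.integers(len(live)))
        node = live[pick]
        for _ in range(2):
            parent.append(node)
            birth.append(st)
            blen.append(0.0)
        left, right = len(parent) - 2, len(parent) - 1
        live[pick] = left
        live.append(right)
        blen[node] = st - birth[node]
    for node in live:
        blen[node] = end - birth[node]
    tips = {node: f"t{idx}" for idx, node in enumerate(sorted(live))}
    return Tree(parent=np.array(parent), branch_length=np.array(blen), tip_labels=tips)


def _kingman_tree(n_tips: int, pop_size: float, rng: np.random.Generator) -> Tree:
    """Kingman coalescent: pairwise merging backwards in time."""
    nodes_parent: dict[int, int] = {}
    node_time: dict[int, float] = {i: 0.0 for i in range(n_tips)}
    live = list(range(n_tips))
    next_id = n_tips
    t = 0.0
    while len(live) > 1:
        j = len(live)
        t += rng.exponential(pop_size / (j * (j - 1) / 2))
        a, b = rng.choice(j, size=2, replace=False)
        na, nb = live[int(a)], live[int(b)]
        node_time[next_id] = t
        nodes_parent[na] = next_id
        nodes_parent[nb] = next_id
        live = [x for x in live if x not in (na, nb)] + [next_id]
        next_id += 1
    total = next_id
    parent = np.full(total, -1, dtype=np.int64)
    blen = np.zeros(total)
    for child, par in nodes_parent.items():
        parent[child] = par
        blen[child] = node_time[par] - node_time[child]
    tips = {i: f"t{i}" for i in range(n_tips)}
    return Tree(parent=parent, branch_length=blen, tip_labels=tips)


def simulate_tree(scenario: SimulationScenario, rng: np.random.Generator | None = None) -> Tree:
    """Random time tree under the scenario's tree model; deterministic by seed."""
    if scenario.n_tips < 2:
        raise ValueError("need at least 2 tips")
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    if scenario.tree_model == "yule":
        return _yule_tree(scenario.n_tips, scenario.birth_rate, rng)
    if scenario.tree_model == "coalescent":
        return _kingman_tree(scenario.n_tips, scenario.pop_size, rng)
    raise ValueError(f"unknown tree model {scenario.tree_model!r}")


def simulate_history_and_tips(
    tree: Tree,
    Q: RateMatrix | np.ndarray,
    root_area: int | None = None,
    root_freqs: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    areas: tuple[str, ...] | None = None,
) -> tuple[DispersalHistory, GeographicData]:
    """Exact Gillespie forward simulation of dispersal from root to tips.

    Returns the full timed event history (ground truth for stochastic-
    mapping validation) and the induced tip-area data.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    Qm = Q.Q if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)
    k = Qm.shape[0]
    if root_area is None:
        if root_freqs is None:
            root_freqs = np.full(k, 1.0 / k)
        root_area = int(rng.choice(k, p=np.asarray(root_freqs)))
    node_state = np.full(tree.n_nodes, -1, dtype=np.int64)
    node_state[tree.root] = root_area
    events: dict[int, list[tuple[float, int, int]]] = {}
    for node in tree.preorder:
        if node == tree.root:
            continue
        state = int(node_state[tree.parent[node]])
        t_end = float(tree.branch_length[node])
        now = 0.0
        ev: list[tuple[float, int, int]] = []
        while True:
            rate = -Qm[state, state]
            if rate <= 0:
                break
            now += rng.exponential(1.0 / rate)
            if now >= t_end:
                break
            probs = Qm[state].copy()
            probs[state] = 0.0
            nxt = int(rng.choice(k, p=probs / probs.sum()))
            ev.append((float(now), state, nxt))
            state = nxt
        events[node] = ev
        node_state[node] = state
    if areas is None:
        areas = tuple(f"area{i}" for i in range(k))
    data = GeographicData(
        areas=areas,
        tip_area={label: int(node_state[node]) for node, label in tree.tip_labels.items()},
    )
    history = DispersalHistory(node_state=node_state, events=events, tree=tree, k=k)
    return history, data


def _sparse_delta(k: int, rng: np.random.Generator) -> np.ndarray:
    """A uniform random spanning tree's edge set: Delta = k - 1 (minimal)."""
    pairs = route_pairs(k, True)
    idx = {p: i for i, p in enumerate(pairs)}
    delta = np.zeros(len(pairs), dtype=np.int64)
    joined = [0]
    rest = list(range(1, k))
    rng.shuffle(rest)
    for v in rest:
        u = int(rng.choice(joined))
        delta[idx[(min(u, v), max(u, v))]] = 1
        joined.append(v)
    return delta


def make_benchmark_suite(out_dir, master_seed: int = 2023) -> list[dict]:
    """Write a deterministic fixture directory of simulation scenarios.

    Scenarios cross k in {3, 5, 8} with sparse (Delta = k-1) versus dense
    (all routes) true route sets and low (0.5 events over the tree) versus
    high (3 events per unit tree length... concretely mu chosen so the
    expected event count is well above k) dispersal rates, at 20 or 50
    tips.  Layout: ``<name>/tree.nwk``, ``tips.csv``, ``truth.json`` and a
    top-level ``manifest.json`` with all seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    combos = [
        (3, 20, "sparse", "low"), (3, 20, "dense", "high"),
        (5, 50, "sparse", "low"), (5, 50, "dense", "high"),
        (8, 50, "dense", "high"),
    ]
    for idx, (k, n, routes, rate) in enumerate(combos):
        seed = master_seed + idx
        rng = np.random.default_rng(seed)
        name = f"scenario_k{k}_n{n}_{routes}_{rate}"
        scen = SimulationScenario(n_tips=n, k=k, seed=seed, name=name)
        tree = simulate_tree(scen, rng)
        T = tree.tree_length
        delta = _sparse_delta(k, rng) if routes == "sparse" else np.ones(n_routes(k, True), dtype=np.int64)
        mu = (0.5 / T) if rate == "low" else (3.0 * k / T)
        params = GeoModelParams(symmetric=True, r=np.ones(delta.size), delta=delta, mu=mu)
        Q = build_rate_matrix(params, k)
        history, data = simulate_history_and_tips(tree, Q, root_area=0, rng=rng)
        d = out / name
        d.mkdir(exist_ok=True)
        (d / "tree.nwk").write_text(write_newick(tree) + "\n")
        data.to_frame().to_csv(d / "tips.csv", index=False)
        truth = {
            "k": k, "n_tips": n, "symmetric": True,
            "mu": mu, "T": T,
            "delta": delta.tolist(),
            "r": [1.0] * int(delta.size),
            "Delta": int(delta.sum()),
            "root_area": 0,
            "n_events_true": history.n_events,
            "seed": seed,
        }
        (d / "truth.json").write_text(json.dumps(truth, indent=1))
        manifest.append({"name": name, "seed": seed, "k": k, "n_tips": n,
                         "routes": routes, "rate": rate})
    (out / "manifest.json").write_text(json.dumps(
        {"master_seed": master_seed, "scenarios": manifest}, indent=1))
    return manifest
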