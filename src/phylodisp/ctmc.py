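"""CTMC dispersal process among k discrete areas.

The geographic model is a continuous-time Markov chain on area labels with
instantaneous-rate matrix Q built from three ingredients:

* relative rates ``r`` (one per possible dispersal route),
* binary route indicators ``delta`` that switch entries of Q on and off
  (the variable-selection device: delta_ij = 0 removes route i->j), and
* an average dispersal rate ``mu`` (expected dispersal events per unit
  time) that sets the overall scale.

Unscaled entries are ``q'_ij = r_ij * delta_ij`` (mirrored when symmetric);
Q is then rescaled so that the mean off-diagonal flow under *uniform* area
weights equals mu: ``(1/k) * sum_{i != j} q_ij = mu``.  Uniform weights are
used rather than the stationary distribution of Q because reducible
configurations (allowed under the asymmetric prior) have no unique
stationary distribution; the convention is held fixed across the package.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "GeoModelParams",
    "RateMatrix",
    "route_pairs",
    "n_routes",
    "build_rate_matrix",
    "transition_probabilities",
    "pruning_log_likelihood",
    "LikelihoodEvaluator",
]

NEG_INF = float("-inf")


def n_routes(k: int, symmetric: bool) -> int:
    """Number K of possible dispersal routes: k(k-1)/2 symmetric, k(k-1) not."""
    return k * (k - 1) // 2 if symmetric else k * (k - 1)


def route_pairs(k: int, symmetric: bool) -> list[tuple[int, int]]:
    """Canonical route ordering: unordered pairs (i<j) lexicographic if
    symmetric, else all ordered pairs (i, j), i != j, row-major."""
    if symmetric:
        return list(itertools.combinations(range(k), 2))
    return [(i, j) for i in range(k) for j in range(k) if i != j]


@dataclass
class GeoModelParams:
    """Parameters (r, delta, mu[, m]) that determine Q for a given k.

    ``m`` is the latent hyper-mean of the dispersal rate, present only under
    the alternative (hierarchical exponential) rate prior.
    """

    symmetric: bool
    r: np.ndarray
    delta: np.ndarray
    mu: float
    m: float | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        self.delta = np.asarray(self.delta, dtype=np.int64)
        if self.r.shape != self.delta.shape:
            raise ValueError("r and delta must have equal length")
        if np.any(self.r <= 0):
            raise ValueError("relative rates must be positive")
        if not np.all((self.delta == 0) | (self.delta == 1)):
            raise ValueError("delta entries must be 0 or 1")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.m is not None and self.m <= 0:
            raise ValueError("hyper-mean m must be positive")

    @property
    def n_active(self) -> int:
        """Delta: the number of dispersal routes in the configuration."""
        return int(self.delta.sum())

    def k_for(self) -> int:
        K = self.r.size
        if self.symmetric:
            k = int(round((1 + np.sqrt(1 + 8 * K)) / 2))
            if k * (k - 1) // 2 != K:
                raise ValueError(f"length {K} is not k(k-1)/2 for any k")
        else:
            k = int(round((1 + np.sqrt(1 + 4 * K)) / 2))
            if k * (k - 1) != K:
                raise ValueError(f"length {K} is not k(k-1) for any k")
        return k

    def copy(self) -> "GeoModelParams":
        return GeoModelParams(
            symmetric=self.symmetric,
            r=self.r.copy(),
            delta=self.delta.copy(),
            mu=self.mu,
            m=self.m,
        )


@dataclass
class RateMatrix:
    """A k x k instantaneous-rate matrix with the uniform-weight rescaling.

    ``degenerate`` flags the Delta = 0 configuration, where Q = 0 and no
    dispersal is possible.
    """

    Q: np.ndarray
    degenerate: bool = False
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=np.float64)
        k = self.Q.shape[0]
        if self.Q.shape != (k, k):
            raise ValueError("Q must be square")
        if self.weights is None:
            self.weights = np.full(k, 1.0 / k)
        off = self.Q - np.diag(np.diag(self.Q))
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal rates must be nonnegative")
        if np.max(np.abs(self.Q.sum(axis=1))) > 1e-9 * max(1.0, np.abs(self.Q).max()):
            raise ValueError("rows of Q must sum to zero")

    @property
    def k(self) -> int:
        return self.Q.shape[0]

    @property
    def is_symmetric(self) -> bool:
        return bool(np.allclose(self.Q, self.Q.T))


def build_rate_matrix(params: GeoModelParams, k: int | None = None) -> RateMatrix:
    """Assemble and rescale Q from (r, delta, mu)."""
    if k is None:
        k = params.k_for()
    K = n_routes(k, params.symmetric)
    if params.r.size != K:
        raise ValueError(f"expected {K} routes for k={k}, got {params.r.size}")
    q = np.zeros((k, k))
    for idx, (i, j) in enumerate(route_pairs(k, params.symmetric)):
        val = params.r[idx] * params.delta[idx]
        q[i, j] = val
        if params.symmetric:
            q[j, i] = val
    total = q.sum()
    if total == 0.0 or params.mu == 0.0:
        return RateMatrix(Q=np.zeros((k, k)), degenerate=total == 0.0)
    # (1/k) * sum_{i!=j} q_ij = mu  =>  scale by mu * k / sum(q')
    q *= params.mu * k / total
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return RateMatrix(Q=q)


# ----------------------------------------------------------------------
# transition probabilities


def _branch_transition_stack(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """exp(Q t) for every t in ``ts``, shape (len(ts), k, k).

    Symmetric Q goes through a single eigendecomposition; general Q through
    scipy's eigendecomposition with a Pade ``expm`` fallback when the
    eigenvector basis is ill-conditioned (defective or near-defective Q).
    """
    ts = np.asarray(ts, dtype=np.float64)
    k = Q.shape[0]
    if np.allclose(Q, Q.T, atol=1e-13):
        lam, V = np.linalg.eigh(Q)
        E = np.exp(np.outer(ts, lam))  # (B, k)
        P = np.einsum("ij,bj,kj->bik", V, E, V)
    else:
        lam, V = np.linalg.eig(Q)
        cond_ok = True
        try:
            Vinv = np.linalg.inv(V)
            cond_ok = np.linalg.cond(V) < 1e8
        except np.linalg.LinAlgError:
            cond_ok = False
        if cond_ok:
            E = np.exp(np.outer(ts, lam))
            P = np.einsum("ij,bj,jk->bik", V, E, Vinv).real
        else:
            P = np.stack([expm(Q * t) for t in ts])
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P


def transition_probabilities(Q: RateMatrix | np.ndarray, t: float) -> np.ndarray:
    """Stochastic matrix exp(Qt); rows sum to 1, entries >= 0."""
    if t < 0:
        raise ValueError("negative duration")
    mat = Q.Q if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=np.float64)
    if t == 0.0:
        return np.eye(mat.shape[0])
    return _branch_transition_stack(mat, np.array([t]))[0]


# ----------------------------------------------------------------------
# pruning likelihood


class LikelihoodEvaluator:
    """Felsenstein pruning bound to a fixed (tree, data) pair.

    Precomputes the postorder traversal, per-node children and observed tip
    states once; each call computes all branch transition matrices in one
    eigendecomposition pass and then runs the post-order recursion with
    per-node underflow rescaling.
    """

    def __init__(self, tree, data, root_freqs: np.ndarray | None = None):
        self.tree = tree
        self.k = data.k
        self.tip_state = data.tip_state_vector(tree)
        if root_freqs is None:
            root_freqs = np.full(self.k, 1.0 / self.k)
        root_freqs = np.asarray(root_freqs, dtype=np.float64)
        if root_freqs.size != self.k or abs(root_freqs.sum() - 1.0) > 1e-8:
            raise ValueError("root_freqs must be a length-k probability vector")
        self.root_freqs = root_freqs
        self.postorder = tree.postorder
        self.children = [tree.children(i) for i in range(tree.n_nodes)]
        self.blen = tree.branch_length

    def partials(self, Q: RateMatrix) -> tuple[np.ndarray, float]:
        """Per-node partial likelihood vectors and the accumulated log-scaler."""
        if Q.k != self.k:
            raise ValueError(f"Q is {Q.k}x{Q.k} but data has k={self.k} areas")
        n = self.tree.n_nodes
        k = self.k
        if Q.degenerate:
            P = np.broadcast_to(np.eye(k), (n, k, k)).copy()
        else:
            P = _branch_transition_stack(Q.Q, self.blen)
        L = np.zeros((n, k))
        logscale = 0.0
        for node in self.postorder:
            ch = self.children[node]
            if not ch:
                L[node, self.tip_state[node]] = 1.0
                continue
            vec = np.ones(k)
            for c in ch:
                vec *= P[c] @ L[c]
            mx = vec.max()
            if mx <= 0.0:
                return L, NEG_INF
            vec /= mx
            logscale += np.log(mx)
            L[node] = vec
        return L, logscale

    def log_likelihood(self, Q: RateMatrix) -> float:
        L, logscale = self.partials(Q)
        if logscale == NEG_INF:
            return NEG_INF
        root_val = float(self.root_freqs @ L[self.tree.root])
        if root_val <= 0.0:
            return NEG_INF
        return np.log(root_val) + logscale


def pruning_log_likelihood(tree, data, Q: RateMatrix, root_freqs=None) -> float:
    """log P(G | Q, tree) by pruning; -inf when the tip pattern has
    probability zero (e.g. a reducible Q that cannot realize it)."""
    return LikelihoodEvaluator(tree, data, root_freqs).log_likelihood(Q)
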