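"""Diffusion state distance (DSD) on a single PPI network.

The diffusion state of node u after t steps is the vector
He_t(u) = (expected visits to v_1, ..., expected visits to v_n) of a
degree-normalized simple random walk of length t started at u, counting the
start as one visit (so He_0 = I and each row of He_t sums to t + 1).  DSD is
the L1 distance between diffusion states; it is a graph metric and its
pairwise differences converge as t → ∞, which lets the converged variant be
computed by a single linear solve against the walk's fundamental matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .netio import MundoError, PPINetwork

#: Sentinel value of ``t`` marking the t → ∞ diffusion state.
CONVERGED = "converged"


@dataclass(frozen=True)
class DiffusionState:
    """Per-node expected-visit vectors, rows aligned to ``nodes``."""

    he: np.ndarray
    nodes: tuple[str, ...]
    t: int | str

    def __post_init__(self) -> None:
        if self.he.shape != (len(self.nodes), len(self.nodes)):
            raise MundoError("he shape does not match node count")


@dataclass(frozen=True)
class DSDMatrix:
    """Symmetric matrix of pairwise DSD values, aligned to ``nodes``."""

    dist: np.ndarray
    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.dist.shape != (len(self.nodes), len(self.nodes)):
            raise MundoError("dist shape does not match node count")

    def index(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise MundoError(f"node {node!r} not in DSD matrix") from None

    def neighbor_order(self, i: int) -> np.ndarray:
        """Indices of all nodes by distance from node i ascending, ties
        lexicographic by node id (memoized; independent of labels)."""
        cache = self.__dict__.setdefault("_order_cache", {})
        if i not in cache:
            names = self.__dict__.setdefault("_names_arr", np.asarray(self.nodes))
            cache[i] = np.lexsort((names, self.dist[i]))
        return cache[i]


def transition_matrix(net: PPINetwork, lazy: bool = False) -> np.ndarray:
    """Row-stochastic transition matrix of the degree-normalized walk.

    ``lazy=True`` mixes in a 1/2 self-transition (useful on bipartite-ish
    graphs where the plain walk does not converge).
    """
    deg = net.degrees()
    if np.any(deg == 0):
        bad = net.nodes[int(np.argmin(deg))]
        raise MundoError(
            f"node {bad!r} is isolated; run largest_connected_component first"
        )
    p = net.adjacency / deg[:, None]
    if lazy:
        p = 0.5 * (np.eye(net.n_nodes) + p)
    return p


def _require_connected(net: PPINetwork) -> None:
    if not net.is_connected():
        raise MundoError(
            "network is not connected; run largest_connected_component first"
        )


def diffusion_state(net: PPINetwork, t: int, lazy: bool = False) -> DiffusionState:
    """Expected-visit matrix He_t = sum_{k=0..t} P^k of the t-step walk."""
    if t < 0:
        raise MundoError("t must be >= 0")
    _require_connected(net)
    p = transition_matrix(net, lazy=lazy)
    he = np.eye(net.n_nodes)
    power = np.eye(net.n_nodes)
    for _ in range(t):
        power = power @ p
        he += power
    return DiffusionState(he=he, nodes=net.nodes, t=t)


def stationary_distribution(net: PPINetwork) -> np.ndarray:
    deg = net.degrees()
    return deg / deg.sum()


def converged_diffusion_state(net: PPINetwork, lazy: bool = False) -> DiffusionState:
    """The t → ∞ diffusion state, up to a row-constant offset.

    He_t itself grows without bound (visits accumulate along the stationary
    distribution), but the *differences* between rows converge, which is all
    DSD and the co-embedding kernels consume.  The limit is computed
    spectrally: with S = D^{-1/2} A D^{-1/2} = U diag(lambda) Uᵀ the
    symmetrized walk operator, sum_{k<=t} lambda^k tends to 1/(1−lambda) for
    |lambda| < 1; the lambda = 1 (stationary) component is row-constant and
    set to zero; on bipartite graphs the lambda = −1 component oscillates
    with period 2 and is assigned its even-t subsequence limit (1), matching
    a long even-step iteration.
    """
    _require_connected(net)
    deg = net.degrees()
    if np.any(deg == 0):
        raise MundoError("isolated node; run largest_connected_component first")
    d_isqrt = 1.0 / np.sqrt(deg)
    s = net.adjacency * d_isqrt[:, None] * d_isqrt[None, :]
    if lazy:
        s = 0.5 * (np.eye(net.n_nodes) + s)
    lam, u = np.linalg.eigh(s)
    g = np.empty_like(lam)
    for i, lv in enumerate(lam):
        if lv > 1 - 1e-9:
            g[i] = 0.0
        elif lv < -1 + 1e-9:
            g[i] = 1.0  # even-t limit of the period-2 component
        else:
            g[i] = 1.0 / (1.0 - lv)
    core = (u * g[None, :]) @ u.T
    z = (d_isqrt[:, None] * core) * (1.0 / d_isqrt)[None, :]
    return DiffusionState(he=z, nodes=net.nodes, t=CONVERGED)


def dsd_matrix(ds: DiffusionState) -> DSDMatrix:
    """Pairwise L1 distances between diffusion-state vectors."""
    dist = squareform(pdist(ds.he, metric="cityblock"))
    return DSDMatrix(dist=dist, nodes=ds.nodes)


def converged_dsd(
    net: PPINetwork,
    tol: float = 1e-8,
    step_cap: int = 1_000_000,
    method: str = "solve",
    lazy: bool = False,
) -> DSDMatrix:
    """The t → ∞ DSD matrix.

    ``method="solve"`` (default) uses the spectral closed form;
    ``method="iterate"`` grows He_t two steps at a time (the walk may have
    period 2 on bipartite graphs) until the maximum entrywise change of the
    DSD matrix drops below ``tol`` — the independent check the closed form
    is validated against — raising after ``step_cap`` steps.
    """
    if method == "solve":
        return dsd_matrix(converged_diffusion_state(net, lazy=lazy))
    if method != "iterate":
        raise MundoError(f"unknown method {method!r}")
    _require_connected(net)
    p = transition_matrix(net, lazy=lazy)
    n = net.n_nodes
    he = np.eye(n)
    power = np.eye(n)
    prev = squareform(pdist(he, metric="cityblock"))
    for _ in range(0, step_cap, 2):
        power = power @ p
        he += power
        power = power @ p
        he += power
        cur = squareform(pdist(he, metric="cityblock"))
        delta = float(np.max(np.abs(cur - prev)))
        if delta < tol:
            return DSDMatrix(dist=cur, nodes=net.nodes)
        prev = cur
    raise MundoError(
        f"converged_dsd did not stabilize within {step_cap} steps (last delta {delta:.3e})"
    )
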