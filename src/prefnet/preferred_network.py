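"""Preferred-degree network ensemble (no disease).

Every node steers its number of contacts toward a preferred degree kappa:
when selected, it attempts to *add* a link with the Fermi probability
``w+(k) = 1 / (1 + exp(beta (k - kappa)))`` and to *cut* one otherwise
(``w- = 1 - w+``).  The partner is drawn uniformly from the eligible pool
(all non-neighbors for an addition, all current neighbors for a cut) and
has no veto.  ``beta`` is the inflexibility of the population:
``beta = inf`` means a node always adds below kappa and always cuts above
it, which is why kappa is conventionally stored as integer + 0.5 so the
marginal case k == kappa never occurs.

The stationary degree distribution of this ensemble is not Gaussian: at
``beta = inf`` it is a Laplace (double-exponential) distribution centred on
kappa, and at finite beta the peak is rounded over a width ~ 1/beta before
crossing over to the same exponential tails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import _kernels as K


@dataclass
class FlexibilityProfile:
    """Preferred degree kappa and inflexibility beta of a homogeneous population.

    kappa is conventionally an integer plus a small offset (default 0.5) so
    that at beta = inf the add/cut decision is never ambiguous.
    """

    kappa: float = 20.5
    beta: float = math.inf

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative (may be inf)")


class NetworkState:
    """Undirected simple graph over n nodes with mutable edges and cached degrees.

    Backed by a fixed-capacity adjacency-list matrix shared with the
    simulation kernels; intended for populations up to a few thousand nodes.
    """

    def __init__(self, n_nodes: int):
        if n_nodes < 1:
            raise ValueError("need at least one node")
        self.n_nodes = int(n_nodes)
        cap = max(1, self.n_nodes - 1)
        self._nbr = np.zeros((self.n_nodes, cap), dtype=np.int32)
        self._deg = np.zeros(self.n_nodes, dtype=np.int64)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_edges(cls, n_nodes: int, edges: Iterable[tuple[int, int]]) -> "NetworkState":
        net = cls(n_nodes)
        for i, j in edges:
            net.add_edge(int(i), int(j))
        return net

    @classmethod
    def read_edge_list(cls, path: str | Path, n_nodes: int | None = None) -> "NetworkState":
        """Read a two-column whitespace-separated 0-based edge list."""
        pairs = []
        top = -1
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split()[:2]
            i, j = int(a), int(b)
            pairs.append((i, j))
            top = max(top, i, j)
        if n_nodes is None:
            n_nodes = top + 1
        return cls.from_edges(n_nodes, pairs)

    # -- basic queries ------------------------------------------------------

    @property
    def degree(self) -> np.ndarray:
        return self._deg.copy()

    @property
    def n_edges(self) -> int:
        return int(self._deg.sum()) // 2

    def neighbors(self, i: int) -> np.ndarray:
        return np.sort(self._nbr[i, : self._deg[i]].copy())

    def has_edge(self, i: int, j: int) -> bool:
        return bool(K._is_neighbor(self._nbr, self._deg, i, j))

    def edges(self) -> set[tuple[int, int]]:
        out = set()
        for i in range(self.n_nodes):
            for j in self._nbr[i, : self._deg[i]]:
                a, b = (i, int(j)) if i < j else (int(j), i)
                out.add((a, b))
        return out

    # -- mutation -----------------------------------------------------------

    def add_edge(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("self-loops are not allowed")
        if self.has_edge(i, j):
            raise ValueError(f"duplicate edge ({i}, {j})")
        K._add_edge(self._nbr, self._deg, i, j)

    def cut_edge(self, i: int, j: int) -> None:
        if not self.has_edge(i, j):
            raise ValueError(f"edge ({i}, {j}) not present")
        K._cut_edge(self._nbr, self._deg, i, j)

    # -- consistency --------------------------------------------------------

    def validate(self) -> None:
        """Assert simplicity and degree-cache consistency (debug aid)."""
        for i in range(self.n_nodes):
            row = self._nbr[i, : self._deg[i]]
            if len(set(row.tolist())) != len(row):
                raise AssertionError(f"duplicate neighbor entries at node {i}")
            if i in row:
                raise AssertionError(f"self-loop at node {i}")
            for j in row:
                if not K._is_neighbor(self._nbr, self._deg, int(j), i):
                    raise AssertionError(f"asymmetric edge ({i}, {j})")
        if not (0 <= self._deg.min() and self._deg.max() <= self.n_nodes - 1):
            raise AssertionError("degree out of range")

    # -- interoperability ---------------------------------------------------

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges())
        return g

    def write_edge_list(self, path: str | Path) -> None:
        lines = [f"{i} {j}" for i, j in sorted(self.edges())]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))

    def write_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), str(path))


@dataclass
class DegreeHistogram:
    """Normalized degree histogram rho(k) with support in [0, N-1]."""

    counts: np.ndarray
    label: str = "all"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probability(self) -> np.ndarray:
        tot = self.counts.sum()
        if tot == 0:
            raise ValueError(f"empty degree histogram ({self.label!r})")
        return self.counts / tot

    @property
    def support(self) -> np.ndarray:
        return np.arange(len(self.counts))

    def mean(self) -> float:
        return float(self.support @ self.probability)

    def moment(self, order: int) -> float:
        return float((self.support.astype(float) ** order) @ self.probability)

    def to_frame(self):
        import pandas as pd

        p = self.probability
        return pd.DataFrame(
            {"k": self.support, "count": self.counts, "probability": p, "state": self.label}
        )


def add_probability(k: int, profile: FlexibilityProfile) -> float:
    """Fermi add-probability w+(k); the cut probability is 1 - w+(k)."""
    if k < 0:
        raise ValueError("degree must be nonnegative")
    return float(K._wplus(float(k), profile.kappa, profile.beta))


def link_update_attempt(net: NetworkState, node: int, profile: FlexibilityProfile, rng) -> NetworkState:
    """One add-or-cut attempt by ``node``; exactly zero or one edge changes.

    Degenerate attempts (add when connected to everyone, cut at degree 0)
    are silent no-ops counted in the rng's diagnostics.  ``rng`` is a
    :class:`prefnet.sis_dynamics.KernelRng`.
    """
    if not (0 <= node < net.n_nodes):
        raise ValueError(f"invalid node id {node}")
    sig = np.zeros(net.n_nodes, dtype=np.int8)
    _single_attempt(net, node, sig, 0, profile.kappa, profile.beta, False, 0.0, rng)
    return net


def _single_attempt(net, node, sig, n_inf, kappa, beta, selective, bias, rng):
    """Run _link_attempt's body for a *chosen* node (kernel picks randomly,
    so we temporarily splice the choice by drawing the attempt inline)."""
    # the kernel draws the node itself; emulate by retrying a 1-node-id table
    # is wasteful, so this re-implements the decision using kernel pieces.
    nbr, deg = net._nbr, net._deg
    k = int(deg[node])
    n = net.n_nodes
    if rng.random() < K._wplus(float(k), kappa, beta):
        if k >= n - 1:
            rng.diag[K.DIAG_NOOP_FULL] += 1
            return
        if selective and sig[node] == 0 and n_inf > 0:
            k_i = int(K._count_inf_neighbors(nbr, deg, sig, node))
            k_s = k - k_i
            pool_s = (n - n_inf) - 1 - k_s
            pool_i = n_inf - k_i
            if pool_s == 0 and pool_i == 0:
                rng.diag[K.DIAG_NOOP_FULL] += 1
                return
            p_ss = (1.0 + bias) * pool_s / ((1.0 + bias) * pool_s + pool_i)
            target, pool = (0, pool_s) if rng.random() < p_ss else (1, pool_i)
            if pool == 0:
                rng.diag[K.DIAG_FALLBACK] += 1
                target, pool = (1, pool_i) if target == 0 else (0, pool_s)
            j = int(K._sample_partner(nbr, deg, sig, rng.state, node, target, pool))
        else:
            j = int(K._sample_partner(nbr, deg, sig, rng.state, node, -1, n - 1 - k))
        K._add_edge(nbr, deg, node, j)
        rng.diag[K.DIAG_ADDS] += 1
    else:
        if k == 0:
            rng.diag[K.DIAG_NOOP_EMPTY] += 1
            return
        if selective and sig[node] == 0:
            k_i = int(K._count_inf_neighbors(nbr, deg, sig, node))
            k_s = k - k_i
            p_ci = (1.0 + bias) * k_i / ((1.0 + bias) * k_i + k_s) if k > 0 else 0.0
            target, cnt = (1, k_i) if rng.random() < p_ci else (0, k_s)
            if cnt == 0:
                rng.diag[K.DIAG_FALLBACK] += 1
                target, cnt = (0, k_s) if target == 1 else (1, k_i)
            idx = int(rng.integers(cnt))
            c = 0
            j = -1
            for a in range(k):
                if sig[nbr[node, a]] == target:
                    if c == idx:
                        j = int(nbr[node, a])
                        break
                    c += 1
        else:
            j = int(nbr[node, int(rng.integers(k))])
        K._cut_edge(nbr, deg, node, j)
        rng.diag[K.DIAG_CUTS] += 1


def network_mcs(net: NetworkState, profile: FlexibilityProfile, rng, n_mcs: int = 1) -> NetworkState:
    """n_mcs Monte Carlo steps: N link attempts each, on uniform random nodes."""
    sig = np.zeros(net.n_nodes, dtype=np.int8)
    for _ in range(int(n_mcs)):
        K._network_mcs(
            net._nbr, net._deg, sig, 0, rng.state, profile.kappa, profile.beta, False, 0.0, rng.diag
        )
    return net


def grow_network(
    n_nodes: int, profile: FlexibilityProfile, rng, burn_in_mcs: int = 10_000
) -> NetworkState:
    """Grow a stationary preferred-degree network from the empty graph.

    The default burn-in of 10^4 MCS comfortably relaxes the degree
    distribution at kappa << N; the mean degree itself reaches kappa within
    ~kappa/2 MCS.
    """
    net = NetworkState(n_nodes)
    K._grow_network(net._nbr, net._deg, rng.state, profile.kappa, profile.beta, int(burn_in_mcs), rng.diag)
    return net


def degree_distribution(
    nets: NetworkState | Sequence[NetworkState],
    epi=None,
) -> DegreeHistogram | dict[str, DegreeHistogram]:
    """Normalized degree histogram of one network or an ensemble.

    With an epidemic state supplied, returns histograms split by node class
    {'S', 'I', 'all'} (callers are responsible for having reached steady
    state; see `grow_network` for burn-in guidance).
    """
    if isinstance(nets, NetworkState):
        nets = [nets]
    nets = list(nets)
    if not nets:
        raise ValueError("empty ensemble")
    n_max = max(net.n_nodes for net in nets)
    if epi is None:
        counts = np.zeros(n_max, dtype=np.int64)
        for net in nets:
            counts += np.bincount(net._deg, minlength=n_max)
        return DegreeHistogram(counts)
    hist = {
        "all": np.zeros(n_max, dtype=np.int64),
        "S": np.zeros(n_max, dtype=np.int64),
        "I": np.zeros(n_max, dtype=np.int64),
    }
    for net in nets:
        deg = net._deg
        hist["all"] += np.bincount(deg, minlength=n_max)
        mask = np.asarray(epi.state, dtype=bool)
        hist["I"] += np.bincount(deg[mask], minlength=n_max)
        hist["S"] += np.bincount(deg[~mask], minlength=n_max)
    return {lab: DegreeHistogram(c, label=lab) for lab, c in hist.items()}


def laplace_tail_fit(
    hist: DegreeHistogram, kappa: float, min_offset: int = 2, min_count: int = 5
):
    """Weighted least-squares line on log rho(k) vs |k - kappa| in the tails.

    Bins are weighted by sqrt(count) (the Poisson-appropriate weight for a
    log-linear fit) and bins with fewer than ``min_count`` samples are
    excluded, since their log values are dominated by shot noise.  Returns
    (slope, intercept, r_squared); for the beta=inf ensemble the tails are
    exponential, so r_squared should be close to 1.
    """
    p = hist.probability
    k = hist.support
    mask = (np.abs(k - kappa) >= min_offset) & (hist.counts >= max(1, min_count))
    xv = np.abs(k[mask] - kappa).astype(float)
    yv = np.log(p[mask])
    if xv.size < 3:
        raise ValueError("not enough populated tail bins for a fit")
    wts = hist.counts[mask].astype(float)
    slope, intercept = np.polyfit(xv, yv, 1, w=np.sqrt(wts))
    resid = yv - (slope * xv + intercept)
    ybar = float(np.average(yv, weights=wts))
    ss_tot = float((wts * (yv - ybar) ** 2).sum())
    r2 = 1.0 - float((wts * resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2
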