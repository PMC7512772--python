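"""Comparison models: Barabási–Albert growth and the uncorrelated
(expected-degree / Chung–Lu) ensemble with structural cutoff.

The BA model is projective but not exchangeable — a node's expected degree
``m (t/t_i)^(1/2)`` depends on its arrival time.  The uncorrelated ensemble
is exchangeable but, in the sparse regime, not projective: keeping the
pairwise marginals fixed while enlarging the node set forces the expected
degrees to grow linearly with N, i.e. a dense network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import networkx as nx

__all__ = [
    "BAConfig",
    "ba_grow",
    "ba_expected_degree",
    "ba_connection_prob",
    "UncorrelatedConfig",
    "uncorrelated_sample",
    "projective_rescale",
]


@dataclass(frozen=True)
class BAConfig:
    """Preferential-attachment growth: each newcomer adds m distinct links."""

    n_nodes: int
    m: int = 2
    n0: int | None = None  # initial clique size; defaults to m

    def __post_init__(self) -> None:
        n0 = self.m if self.n0 is None else self.n0
        object.__setattr__(self, "n0", n0)
        if not (1 <= self.m <= n0 < self.n_nodes):
            raise ValueError("need 1 <= m <= n0 < n_nodes")


def ba_grow(cfg: BAConfig, rng) -> nx.Graph:
    """Grow a Barabási–Albert network, recording arrival times.

    Seeded with an n0-clique (arrival times 1..n0); each new node draws m
    *distinct* targets with probability proportional to current degree
    (uniform sampling from the edge-endpoint list, rejecting repeats).
    Returns a simple graph with a node attribute ``arrival``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n, m, n0 = cfg.n_nodes, cfg.m, cfg.n0
    graph = nx.complete_graph(range(1, n0 + 1))
    if n0 == 1:  # degenerate seed (m=1): no endpoints yet, attach uniformly
        endpoints = [1]
    else:
        endpoints = [v for e in graph.edges for v in e]
    for t in range(n0 + 1, n + 1):
        targets: set[int] = set()
        while len(targets) < m:
            cand = endpoints[rng.integers(len(endpoints))]
            targets.add(int(cand))
        for j in targets:
            graph.add_edge(t, j)
            endpoints.extend((t, j))
    nx.set_node_attributes(graph, {v: v for v in graph}, "arrival")
    return graph


def ba_expected_degree(t: float, t_i: float, m: int) -> float:
    """Mean-field BA degree ``m (t / t_i)**0.5`` of a node arrived at t_i."""
    if not (t >= t_i >= 1):
        raise ValueError("need t >= t_i >= 1")
    return m * (t / t_i) ** 0.5


def ba_connection_prob(t_i: float, t_j: float, m: int, t: float | None = None,
                       form: str = "times") -> float:
    """Mean-field BA connection probability.

    ``times`` form: ``p_ij = (m/2) / sqrt(t_i t_j)``.  ``degrees`` form:
    ``p_ij = kbar_i kbar_j / sum_r kbar_r`` evaluated at time ``t`` — the two
    coincide because the expected degrees sum to 2mt.  Values above 1 (very
    early pairs, where the asymptotic form breaks down) are clipped with a
    warning.
    """
    if form == "times":
        p = (m / 2.0) / np.sqrt(t_i * t_j)
    elif form == "degrees":
        if t is None:
            raise ValueError("degrees form needs the evaluation time t")
        ki = ba_expected_degree(t, t_i, m)
        kj = ba_expected_degree(t, t_j, m)
        p = ki * kj / (2.0 * m * t)
    else:
        raise ValueError(f"unknown form {form!r}")
    if p > 1.0:
        warnings.warn("mean-field connection probability > 1, clipped", RuntimeWarning)
        p = 1.0
    return float(p)


@dataclass(frozen=True)
class UncorrelatedConfig:
    """Expected-degree (Chung–Lu) ensemble: p_ij = theta_i theta_j / (<theta> N)."""

    expected_degrees: tuple

    def __post_init__(self) -> None:
        theta = np.asarray(self.expected_degrees, dtype=float)
        if np.any(theta < 0):
            raise ValueError("expected degrees must be >= 0")
        object.__setattr__(self, "expected_degrees", tuple(theta))

    @property
    def n_nodes(self) -> int:
        return len(self.expected_degrees)

    @property
    def theta(self) -> np.ndarray:
        return np.asarray(self.expected_degrees, dtype=float)

    def check_cutoff(self) -> None:
        theta = self.theta
        cutoff = np.sqrt(theta.mean() * self.n_nodes)
        bad = np.nonzero(theta > cutoff)[0]
        if bad.size:
            raise ValueError(
                f"structural cutoff sqrt(<theta> N) = {cutoff:.4g} violated by "
                f"nodes {list(bad + 1)}"
            )


def uncorrelated_sample(cfg: UncorrelatedConfig, rng) -> nx.Graph:
    """Sample a simple graph with independent edges p_ij = theta_i theta_j / (<theta> N).

    The structural cutoff theta_i <= sqrt(<theta> N) must hold so all p_ij
    are valid probabilities and expected degrees equal theta exactly.
    Sampling delegates to networkx's efficient expected-degree sampler.
    """
    cfg.check_cutoff()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    theta = cfg.theta
    if theta.sum() == 0:
        g = nx.empty_graph(cfg.n_nodes)
    else:
        # networkx uses p_ij = w_i w_j / sum(w) == theta_i theta_j / (<theta> N)
        seed = int(rng.integers(2**31))
        g = nx.expected_degree_graph(theta.tolist(), seed=seed, selfloops=False)
    return nx.relabel_nodes(g, {v: v + 1 for v in range(cfg.n_nodes)})


def projective_rescale(cfg: UncorrelatedConfig, z: int) -> UncorrelatedConfig:
    """Enlarge the ensemble by an integer factor z keeping original marginals.

    The N' = zN node ensemble replicates the theta list z times and scales
    every entry by z; then for the original pairs
    ``p'_ij = (z theta_i)(z theta_j) / (z <theta> z N) = p_ij`` exactly.
    The price of this projectivity is density: expected link count grows as
    ``z^2``, i.e. L = O(N^2).
    """
    if not (isinstance(z, (int, np.integer)) and z >= 1):
        raise ValueError("z must be an integer >= 1")
    if z == 1:
        return cfg
    theta = cfg.theta
    enlarged = np.tile(theta, z) * z
    return replace(cfg, expected_degrees=tuple(enlarged))
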