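"""Synthetic network fixtures with ground-truth metadata.

Stand-ins for large public power-law datasets: every fixture is generated
from a known process with recorded parameters, so downstream analyses can do
parameter recovery instead of eyeballing.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .growth import HiddenVariableSpec, grow, simple_projection
from .reference import UncorrelatedConfig, uncorrelated_sample

__all__ = ["make_fixture"]


def make_fixture(kind: str, params: dict | None = None, seed=0):
    """Generate a synthetic graph plus the metadata of its generator.

    Kinds
    -----
    ``powerlaw_process``
        a growth-process network (params: gamma, n, theta_min, theta_max;
        theta_max defaults to sqrt(n), keeping the run sparse).
    ``regular``
        a random k-regular graph (params: k, n).
    ``disassortative``
        a forest of stars with geometrically spread hub sizes (params:
        sizes or n_stars/max_size): hubs only touch leaves, so knn falls
        steeply with k.
    ``uncorrelated``
        an expected-degree (Chung-Lu) graph with power-law expected degrees
        under the structural cutoff (params: gamma, n, theta_min, theta_max).

    Returns ``(graph, meta)`` where ``meta`` records kind, params and seed.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    meta = {"kind": kind, "seed": seed}

    if kind == "powerlaw_process":
        n = int(params.pop("n", 10_000))
        gamma = float(params.pop("gamma", 2.5))
        theta_min = float(params.pop("theta_min", 1.0))
        theta_max = float(params.pop("theta_max", np.sqrt(n)))
        spec = HiddenVariableSpec(gamma=gamma, theta_min=theta_min,
                                  theta_max=theta_max)
        g = grow(spec, n, rng)
        graph = simple_projection(g)
        meta.update(n=n, gamma=gamma, theta_min=theta_min, theta_max=theta_max,
                    theta=g.theta)
    elif kind == "regular":
        n = int(params.pop("n", 100))
        k = int(params.pop("k", 4))
        graph = nx.random_regular_graph(k, n, seed=int(rng.integers(2**31)))
        graph = nx.relabel_nodes(graph, {v: v + 1 for v in range(n)})
        meta.update(n=n, k=k)
    elif kind == "disassortative":
        if "sizes" in params:
            sizes = list(params.pop("sizes"))
        else:
            n_stars = int(params.pop("n_stars", 200))
            max_size = int(params.pop("max_size", 256))
            sizes = np.unique(np.geomspace(2, max_size, n_stars).astype(int)).tolist()
            sizes = (sizes * (n_stars // len(sizes) + 1))[:n_stars]
        graph = nx.Graph()
        label = 1
        for size in sizes:
            hub = label
            graph.add_node(hub)
            for leaf in range(label + 1, label + 1 + size):
                graph.add_edge(hub, leaf)
            label += size + 1
        meta.update(sizes=sizes, n=graph.number_of_nodes())
    elif kind == "uncorrelated":
        n = int(params.pop("n", 10_000))
        gamma = float(params.pop("gamma", 2.5))
        theta_min = float(params.pop("theta_min", 2.0))
        theta_max = float(params.pop("theta_max", None) or np.sqrt(2 * n))
        spec = HiddenVariableSpec(gamma=gamma, theta_min=theta_min,
                                  theta_max=theta_max)
        from .growth import sample_theta

        theta = sample_theta(spec, n, rng)
        cutoff = np.sqrt(theta.mean() * n)
        theta = np.minimum(theta, cutoff)  # enforce the structural cutoff
        graph = uncorrelated_sample(UncorrelatedConfig(tuple(theta)), rng)
        meta.update(n=n, gamma=gamma, theta_min=theta_min, theta_max=theta_max,
                    theta=theta)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if params:
        raise ValueError(f"unused fixture params: {sorted(params)}")
    return graph, meta
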