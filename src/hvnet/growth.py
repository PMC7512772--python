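"""Hidden-variable growing-network process.

The process builds a weighted multigraph by sequential node addition.  Every
node ``i`` carries a latent fitness ("hidden variable") ``theta_i`` drawn from
a distribution ``rho(theta)``.  Starting from a single isolated node at time
``t = 1``, at each time ``t > 1`` a new node enters, draws

    kappa_t ~ Poisson(theta_t)

link endpoints, and attaches each endpoint independently to an existing node
``j < t`` with probability ``theta_j / sum_{r < t} theta_r``.  A repeat hit on
an already linked pair increments the edge weight by one, so the network is a
weighted multigraph.  The strength ``s_i`` (sum of incident weights) of a node
therefore grows logarithmically in time at rate ``theta_i``, and for a
power-law ``rho(theta)`` the strength and degree distributions inherit the
same power-law exponent.

The attachment kernel uses only the static hidden variables, never the
dynamically acquired degree: this is *not* preferential attachment, and it is
exactly what makes the process projective (adding nodes never rewires the
existing subgraph).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "HiddenVariableSpec",
    "GrowthRealization",
    "sample_theta",
    "sample_initial_links",
    "choose_attachment_target",
    "grow",
    "simple_projection",
    "write_realization",
    "read_realization",
]


@dataclass(frozen=True)
class HiddenVariableSpec:
    """Specification of the hidden-variable distribution ``rho(theta)``.

    Two families are supported:

    ``bounded_power_law``
        density proportional to ``theta**(-gamma)`` on
        ``[theta_min, theta_max]``, zero outside.  ``gamma > 1`` so the
        density is normalisable on the bounded interval.
    ``explicit``
        an explicit per-node list of non-negative ``theta`` values.
    """

    family: str = "bounded_power_law"
    gamma: float = 2.5
    theta_min: float = 1.0
    theta_max: float = 100.0
    values: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("bounded_power_law", "explicit"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "bounded_power_law":
            if not self.gamma > 1:
                raise ValueError("gamma must be > 1 for a bounded power law")
            if not (self.theta_min > 0 and self.theta_max >= self.theta_min):
                raise ValueError("need 0 < theta_min <= theta_max")
        else:
            if self.values is None:
                raise ValueError("explicit spec requires values")
            if np.any(np.asarray(self.values, dtype=float) < 0):
                raise ValueError("explicit theta values must be >= 0")

    # normalisation constant C of the truncated power law
    @property
    def norm_constant(self) -> float:
        if self.family != "bounded_power_law":
            raise ValueError("norm_constant defined only for bounded_power_law")
        a, b, g = self.theta_min, self.theta_max, self.gamma
        if a == b:
            return np.inf
        return (g - 1.0) / (a ** (1.0 - g) - b ** (1.0 - g))

    def pdf(self, theta):
        """Density of the bounded power law, zero outside the support."""
        theta = np.asarray(theta, dtype=float)
        if self.family != "bounded_power_law":
            raise ValueError("pdf defined only for bounded_power_law")
        out = np.where(
            (theta >= self.theta_min) & (theta <= self.theta_max),
            self.norm_constant * theta ** (-self.gamma),
            0.0,
        )
        return out

    def cdf(self, theta):
        """CDF of the truncated power law."""
        theta = np.clip(np.asarray(theta, dtype=float), self.theta_min, self.theta_max)
        a, b, g = self.theta_min, self.theta_max, self.gamma
        if a == b:
            return np.where(np.asarray(theta) >= a, 1.0, 0.0)
        return (theta ** (1.0 - g) - a ** (1.0 - g)) / (b ** (1.0 - g) - a ** (1.0 - g))

    def mean(self) -> float:
        """Analytic mean of the distribution."""
        if self.family == "explicit":
            return float(np.mean(self.values))
        a, b, g = self.theta_min, self.theta_max, self.gamma
        if a == b:
            return a
        C = self.norm_constant
        if g == 2.0:
            return C * np.log(b / a)
        return C * (b ** (2.0 - g) - a ** (2.0 - g)) / (2.0 - g)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_theta(spec: HiddenVariableSpec, n: int, rng) -> np.ndarray:
    """Draw ``n`` hidden variables from ``spec``.

    Bounded power-law values are drawn by inverse-CDF sampling of the
    truncated Pareto law.  An explicit spec must carry exactly ``n`` values.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(rng)
    if spec.family == "explicit":
        vals = np.asarray(spec.values, dtype=float)
        if len(vals) != n:
            raise ValueError(f"explicit spec has {len(vals)} values, expected {n}")
        return vals.copy()
    a, b, g = spec.theta_min, spec.theta_max, spec.gamma
    if a == b:
        return np.full(n, a)
    u = rng.random(n)
    # inverse of F(x) = (x^(1-g) - a^(1-g)) / (b^(1-g) - a^(1-g))
    return (a ** (1.0 - g) + u * (b ** (1.0 - g) - a ** (1.0 - g))) ** (1.0 / (1.0 - g))


def sample_initial_links(theta: float, rng) -> int:
    """Number of link endpoints a newborn node draws: Poisson(theta)."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    return int(_as_rng(rng).poisson(theta))


def choose_attachment_target(theta_existing: Sequence[float], rng) -> int:
    """Pick an existing node with probability proportional to its theta.

    Returns a 1-based node index.  Raises ``ValueError`` when the total mass
    is zero (the kernel is undefined there; callers decide what to do).
    """
    theta_existing = np.asarray(theta_existing, dtype=float)
    if theta_existing.size == 0:
        raise ValueError("need at least one existing node")
    total = theta_existing.sum()
    if total <= 0:
        raise ValueError("zero total attachment mass")
    cum = np.cumsum(theta_existing)
    u = _as_rng(rng).random() * total
    return int(np.searchsorted(cum, u, side="right")) + 1


@dataclass
class GrowthRealization:
    """One sampled trajectory of the growth process.

    Nodes are labelled 1..N in arrival order, so node ``i`` arrived at time
    ``t_i = i``.  ``weights`` maps unordered pairs ``(i, j)`` with ``i < j``
    to multiedge counts.  ``kappa[0]`` (node 1) is defined as 0: the seed
    node has no possible targets, so no initial draw is made for it.
    """

    n_nodes: int
    theta: np.ndarray
    kappa: np.ndarray
    weights: dict[tuple[int, int], int]
    placed_links: int
    dropped_endpoints: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def arrival_time(self) -> np.ndarray:
        return np.arange(1, self.n_nodes + 1)

    def strengths(self) -> np.ndarray:
        """Per-node strength s_i = sum of incident multiedge weights."""
        s = np.zeros(self.n_nodes)
        for (i, j), w in self.weights.items():
            s[i - 1] += w
            s[j - 1] += w
        return s

    def degrees(self) -> np.ndarray:
        """Per-node simple degree k_i = number of distinct neighbours."""
        k = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.weights:
            k[i - 1] += 1
            k[j - 1] += 1
        return k

    def check_invariants(self) -> None:
        s = self.strengths()
        if not np.isclose(s.sum(), 2 * self.placed_links):
            raise AssertionError("handshake identity violated")
        if any(i == j for i, j in self.weights):
            raise AssertionError("self-loop present")
        if np.any(self.degrees() > s + 1e-9):
            raise AssertionError("degree exceeds strength")


def grow(spec_or_thetas, n: int, rng) -> GrowthRealization:
    """Sample one realization of the hidden-variable growth process.

    Parameters
    ----------
    spec_or_thetas
        Either a :class:`HiddenVariableSpec` (thetas are drawn from it) or an
        explicit sequence of per-node theta values in arrival order.
    n
        Final network size N >= 1.
    rng
        Seed or ``numpy.random.Generator``.  A single stream drives all
        draws, in fixed order: theta sampling (if a spec is given), then for
        each arriving node its Poisson draw followed by its target draws.

    Notes
    -----
    If a newborn draws ``kappa > 0`` endpoints while all predecessors have
    ``theta = 0``, the attachment kernel has no mass and those endpoints are
    dropped (counted in ``dropped_endpoints`` and logged): zero-fitness nodes
    must never receive links.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(rng)
    if isinstance(spec_or_thetas, HiddenVariableSpec):
        theta = sample_theta(spec_or_thetas, n, rng)
    else:
        theta = np.asarray(spec_or_thetas, dtype=float)
        if len(theta) != n:
            raise ValueError("theta list length must equal n")
        if np.any(theta < 0):
            raise ValueError("theta values must be >= 0")

    cum = np.cumsum(theta)
    weights: dict[tuple[int, int], int] = {}
    kappa = np.zeros(n, dtype=np.int64)
    dropped = 0
    for t in range(2, n + 1):
        k = int(rng.poisson(theta[t - 1]))
        kappa[t - 1] = k
        if k == 0:
            continue
        total = cum[t - 2]
        if total <= 0:
            dropped += k
            logger.debug("node %d: %d endpoints dropped (zero mass)", t, k)
            continue
        u = rng.random(k) * total
        targets = np.searchsorted(cum[: t - 1], u, side="right") + 1
        for j in targets:
            pair = (int(j), t)
            weights[pair] = weights.get(pair, 0) + 1

    placed = int(kappa.sum()) - dropped
    return GrowthRealization(
        n_nodes=n,
        theta=theta,
        kappa=kappa,
        weights=weights,
        placed_links=placed,
        dropped_endpoints=dropped,
    )


def simple_projection(g: GrowthRealization) -> nx.Graph:
    """Unweighted simple graph: one edge per pair with weight >= 1.

    In the sparse regime almost no pair carries more than one multiedge, so
    the projection's degrees track the strengths (k_i ~ s_i).
    """
    graph = nx.Graph()
    graph.add_nodes_from(range(1, g.n_nodes + 1))
    graph.add_edges_from(g.weights.keys())
    return graph


def write_realization(g: GrowthRealization, edge_path, node_path=None) -> None:
    """Serialize a realization as a weighted edge list ("i j w") plus an
    optional node table ("i t_i theta_i kappa_i s_i k_i")."""
    meta = g.meta
    with open(edge_path, "w") as fh:
        fh.write(f"# hvnet growth realization N={g.n_nodes}")
        for key in ("seed", "gamma", "theta_min", "theta_max"):
            if key in meta:
                fh.write(f" {key}={meta[key]}")
        fh.write("\n# i j w\n")
        for (i, j), w in sorted(g.weights.items()):
            fh.write(f"{i} {j} {w}\n")
    if node_path is not None:
        s, k = g.strengths(), g.degrees()
        with open(node_path, "w") as fh:
            fh.write("# i t_i theta_i kappa_i s_i k_i\n")
            for i in range(g.n_nodes):
                fh.write(
                    f"{i + 1} {i + 1} {theta_fmt(g.theta[i])} "
                    f"{g.kappa[i]} {theta_fmt(s[i])} {k[i]}\n"
                )


def theta_fmt(x: float) -> str:
    return format(float(x), ".12g")


def read_realization(edge_path) -> dict[tuple[int, int], int]:
    """Read back a weighted edge list written by :func:`write_realization`."""
    weights: dict[tuple[int, int], int] = {}
    with open(edge_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i, j, w = line.split()
            weights[(int(i), int(j))] = int(w)
    return weights
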