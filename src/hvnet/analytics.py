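"""Closed-form analytics of the hidden-variable growth process.

Implements the mean-field strength dynamics, the master-equation strength
distribution and its closed-form solution, pairwise connection probabilities,
the per-node Poisson degree law, the ensemble degree distribution, and the
arrival-time-averaged ("permutation") connection marginal that links the
growth process to an exchangeable uncorrelated ensemble.

Conventions
-----------
* ``<theta>`` always denotes the *empirical* mean of the realized theta list
  (not the distribution mean), which keeps the finite-N formulas
  self-consistent on any sample.
* Node ``j`` in a pair is the later arrival; arrival times are 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .fitting import fit_powerlaw_tail
from .growth import HiddenVariableSpec, grow, simple_projection

__all__ = [
    "mean_strength",
    "mean_strength_over_arrivals",
    "master_equation_iterate",
    "strength_pmf_conditional",
    "strength_pmf_conditional_vector",
    "strength_pmf_marginal",
    "tail_exponent_check",
    "StrengthDistribution",
    "ConnectionModel",
    "connection_probability",
    "expected_degree",
    "degree_pmf_node",
    "DegreeCurve",
    "degree_distribution_ensemble",
    "permutation_marginal",
    "log_bin",
]


# ---------------------------------------------------------------------------
# strength dynamics
# ---------------------------------------------------------------------------

def mean_strength(theta: float, t_i: float, t: float, kappa: float = 0.0) -> float:
    """Mean-field strength of a node at time t.

    A node that arrived at ``t_i`` with hidden variable ``theta`` and initial
    draw ``kappa`` gains strength at rate ``theta / t`` (every time step adds
    ``<theta>`` endpoints, a fraction ``theta / (<theta> t)`` of which land on
    the node), so ``s(t) = theta * ln(t / t_i) + kappa``.
    """
    if t_i < 1 or t < t_i:
        raise ValueError("need t >= t_i >= 1")
    if theta < 0 or kappa < 0:
        raise ValueError("theta and kappa must be >= 0")
    return theta * np.log(t / t_i) + kappa


def mean_strength_over_arrivals(theta: float, t: float) -> float:
    """Strength averaged over a uniform random arrival time in [1, t].

    Exact closed form ``theta * (1 - (1 + ln t)/t) + theta`` (the second
    ``theta`` is the mean initial Poisson draw); converges to ``2*theta`` as
    ``t -> infinity``.  This is the key identity behind using ``theta = k/2``
    when fitting hidden variables from observed degrees.
    """
    if t <= 1:
        raise ValueError("need t > 1")
    return theta * (1.0 - (1.0 + np.log(t)) / t) + theta


# ---------------------------------------------------------------------------
# strength distribution: master equation and closed form
# ---------------------------------------------------------------------------

def master_equation_iterate(
    theta_grid,
    masses,
    t_max: int,
    s_max: int,
):
    """Forward-iterate the strength rate equation on a discrete theta grid.

    ``N_theta(s)`` counts the expected number of nodes with hidden variable
    ``theta`` and strength ``s``.  Each time step a newborn contributes its
    Poisson initial-strength pmf, and existing nodes with variable ``theta``
    are hit at rate ``theta / t``, moving mass from strength ``s`` to
    ``s + 1``.  Returns the array ``N_theta(s) / t_max`` of shape
    ``(len(theta_grid), s_max + 1)``, which converges to the per-node joint
    law of (theta, strength).

    This iteration is deliberately independent of the closed-form solution in
    :func:`strength_pmf_conditional` and serves as its brute-force oracle.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    if not np.isclose(masses.sum(), 1.0):
        raise ValueError("grid masses must sum to 1")

    s = np.arange(s_max + 1)
    # Poisson initial-strength pmf per grid point, weighted by the grid mass
    birth = masses[:, None] * stats.poisson.pmf(s[None, :], theta_grid[:, None])

    N = np.zeros((len(theta_grid), s_max + 1))
    N[:, 0] = masses  # the seed node: strength 0
    for t in range(1, t_max):
        rate = theta_grid / t
        shifted = np.zeros_like(N)
        shifted[:, 1:] = N[:, :-1]
        N = N + rate[:, None] * (shifted - N) + birth
    out = N / t_max
    if out.sum() < 1.0 - 1e-3:
        warnings.warn(
            f"s_max={s_max} truncates {1.0 - out.sum():.2e} of the strength mass",
            RuntimeWarning,
        )
    return out


def strength_pmf_conditional(theta: float, s: int) -> float:
    """P(strength = s | theta): Poisson initial draw convolved with a
    geometric number of later reinforcements.

    ``P(s|theta) = sum_{kappa=0}^{s} Pois(kappa; theta) *
    (1/(1+theta)) * (theta/(1+theta))**(s-kappa)``.
    """
    if theta < 0 or s < 0:
        raise ValueError("need theta >= 0 and s >= 0")
    if theta == 0:
        return 1.0 if s == 0 else 0.0
    kappa = np.arange(s + 1)
    pois = stats.poisson.pmf(kappa, theta)
    geom = (1.0 / (1.0 + theta)) * (theta / (1.0 + theta)) ** (s - kappa)
    return float(np.sum(pois * geom))


def strength_pmf_conditional_vector(theta: float, s_max: int) -> np.ndarray:
    """P(strength = s | theta) for all s = 0..s_max at once.

    Uses the stationarity recurrence ``(1+theta) P(s) = theta P(s-1) +
    Pois(s; theta)`` with ``P(0) = exp(-theta)/(1+theta)``, which is O(s_max)
    instead of O(s_max^2).
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    s = np.arange(s_max + 1)
    if theta == 0:
        out = np.zeros(s_max + 1)
        out[0] = 1.0
        return out
    pois = stats.poisson.pmf(s, theta)
    out = np.empty(s_max + 1)
    out[0] = pois[0] / (1.0 + theta)
    for i in range(1, s_max + 1):
        out[i] = (theta * out[i - 1] + pois[i]) / (1.0 + theta)
    return out


def _theta_quadrature(spec: HiddenVariableSpec, n_panels: int = 48, order: int = 12):
    """Gauss-Legendre nodes/weights for integrals against rho(theta).

    Panels are laid out in log-theta so heavy-tailed densities are resolved.
    Returns ``(theta_nodes, weights)`` with ``weights`` already carrying the
    density and the log-jacobian; ``sum(weights) ~ 1``.
    """
    a, b = spec.theta_min, spec.theta_max
    if a == b:
        return np.array([a]), np.array([1.0])
    edges = np.exp(np.linspace(np.log(a), np.log(b), n_panels + 1))
    x, w = np.polynomial.legendre.leggauss(order)
    nodes, wts = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        llo, lhi = np.log(lo), np.log(hi)
        mid, half = 0.5 * (llo + lhi), 0.5 * (lhi - llo)
        u = mid + half * x
        th = np.exp(u)
        nodes.append(th)
        wts.append(half * w * spec.pdf(th) * th)
    return np.concatenate(nodes), np.concatenate(wts)


@dataclass
class StrengthDistribution:
    """Strength law of the process under a given hidden-variable spec."""

    s_max: int
    theta_nodes: np.ndarray
    theta_weights: np.ndarray
    conditional: np.ndarray  # shape (n_theta, s_max+1)
    marginal: np.ndarray     # shape (s_max+1,)

    def pmf(self, s: int) -> float:
        return float(self.marginal[s])


def strength_pmf_marginal(spec: HiddenVariableSpec, s_max: int) -> StrengthDistribution:
    """Marginal strength pmf P(s) by numeric quadrature over rho(theta).

    For a bounded power-law spec the tail of P(s) is a power law with the
    same exponent gamma as rho.
    """
    if spec.family == "bounded_power_law" and spec.gamma <= 1:
        raise ValueError("gamma must be > 1")
    if spec.family == "explicit":
        vals = np.asarray(spec.values, dtype=float)
        nodes, weights = np.unique(vals, return_counts=True)
        weights = weights / weights.sum()
    else:
        nodes, weights = _theta_quadrature(spec)
    cond = np.vstack([strength_pmf_conditional_vector(th, s_max) for th in nodes])
    marginal = weights @ cond
    return StrengthDistribution(
        s_max=s_max, theta_nodes=nodes, theta_weights=weights,
        conditional=cond, marginal=marginal,
    )


def tail_exponent_check(spec: HiddenVariableSpec, s_min: int = 10,
                        s_max: int | None = None) -> float:
    """Fitted power-law exponent of the analytic strength marginal.

    The pmf is computed on ``[0, s_max]`` (default: ``2 * theta_max`` rounded
    up) and the exponent fitted by discrete MLE on ``[s_min, s_max]``.
    """
    if s_max is None:
        s_max = int(2 * spec.theta_max)
    dist = strength_pmf_marginal(spec, s_max)
    return fit_powerlaw_tail(pmf=dist.marginal, x_min=s_min, x_max=s_max)


# ---------------------------------------------------------------------------
# connection probabilities and degrees
# ---------------------------------------------------------------------------

@dataclass
class ConnectionModel:
    """Pairwise connection-probability evaluator for a fixed trajectory.

    ``theta`` is listed in arrival order; node ``i`` (1-based) arrived at
    time ``t_i = i``.  The probability that the later arrival ``j`` ever
    links to ``i`` is ``1 - exp(-theta_i theta_j / D)`` where ``D`` is either
    the realized mass ``sum_{r < t_j} theta_r`` (``exact_sum``) or its
    mean-field value ``<theta> * t_j`` (``asymptotic``).
    """

    theta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.n_nodes = len(self.theta)
        self.mean_theta = float(self.theta.mean())
        self._cum = np.cumsum(self.theta)

    def _denominator(self, t_j: int, mode: str) -> float:
        if mode == "exact_sum":
            return float(self._cum[t_j - 2])  # mass of nodes 1..t_j-1
        if mode == "asymptotic":
            return self.mean_theta * t_j
        raise ValueError(f"unknown mode {mode!r}")


def connection_probability(i: int, j: int, model: ConnectionModel,
                           mode: str = "exact_sum") -> float:
    """P(a_ij = 1) for a node pair of a fixed trajectory.

    Averaging over the later node's Poisson initial draw gives
    ``1 - exp(-theta_i theta_j / D)`` with D as in :class:`ConnectionModel`.
    """
    if i == j:
        raise ValueError("self-pairs have no connection probability")
    early, late = (i, j) if i < j else (j, i)
    th = model.theta
    denom = model._denominator(late, mode)
    if denom <= 0:
        return 0.0
    return float(1.0 - np.exp(-th[early - 1] * th[late - 1] / denom))


def expected_degree(i: int, model: ConnectionModel, mode: str = "exact_sum") -> float:
    """Expected simple degree: the sum of pairwise connection probabilities."""
    th = model.theta
    n = model.n_nodes
    t = np.arange(1, n + 1)
    if mode == "exact_sum":
        denom = np.concatenate([[np.inf], model._cum[:-1]])  # D(t_j) for j=1..n
    else:
        denom = model.mean_theta * t.astype(float)
        denom[0] = np.inf
    denom = np.where(denom <= 0, np.inf, denom)
    # pairs where i is the earlier node
    later = t > i
    p_later = 1.0 - np.exp(-th[i - 1] * th[later] / denom[later])
    # pairs where i is the later node
    earlier = t < i
    p_earlier = 1.0 - np.exp(-th[i - 1] * th[earlier] / denom[i - 1])
    return float(p_later.sum() + p_earlier.sum())


def degree_pmf_node(kbar: float, k) -> np.ndarray | float:
    """Poisson degree law of a single node with expected degree kbar.

    In the sparse regime the indicator edges of a node are nearly independent
    with small probabilities, so its simple degree is Poisson(kbar).
    """
    if kbar < 0:
        raise ValueError("kbar must be >= 0")
    return stats.poisson.pmf(k, kbar)


# ---------------------------------------------------------------------------
# ensemble degree distribution
# ---------------------------------------------------------------------------

@dataclass
class DegreeCurve:
    """Degree distribution of the ensemble, raw and log-binned."""

    k: np.ndarray
    pk: np.ndarray
    logbin_centers: np.ndarray
    logbin_density: np.ndarray


def log_bin(values: np.ndarray, probs: np.ndarray, base: float = 2.0):
    """Log-binned probability density over positive integer support."""
    pos = values >= 1
    values, probs = values[pos], probs[pos]
    if len(values) == 0:
        return np.array([]), np.array([])
    n_bins = int(np.ceil(np.log(values.max() + 1) / np.log(base))) + 1
    edges = base ** np.arange(n_bins + 1)
    idx = np.digitize(values, edges) - 1
    centers, density = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        width = edges[b + 1] - edges[b]
        centers.append(np.sqrt(edges[b] * edges[b + 1]))
        density.append(probs[mask].sum() / width)
    return np.array(centers), np.array(density)


def degree_distribution_ensemble(
    spec: HiddenVariableSpec,
    n: int,
    mode: str = "analytic",
    k_max: int | None = None,
    rng=None,
    n_runs: int = 1,
) -> DegreeCurve:
    """Ensemble degree distribution P(k).

    ``analytic`` mixes the per-node Poisson law over the hidden-variable
    distribution and a uniform arrival time, with expected degree
    ``kbar(theta, t) = theta * ((t-1)/t + H_N - H_t)`` (harmonic numbers H);
    ``simulated`` averages the degree histogram of sampled realizations.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode == "simulated":
        if k_max is None:
            k_max = 10 * int(np.ceil(2 * (spec.theta_max if spec.family != "explicit"
                                          else max(spec.values, default=1))))
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        counts = np.zeros(k_max + 1)
        for _ in range(n_runs):
            g = grow(spec, n, rng)
            k = g.degrees()
            counts += np.bincount(np.minimum(k, k_max), minlength=k_max + 1)
        pk = counts / counts.sum()
    elif mode == "analytic":
        if k_max is None:
            k_max = 200
        if spec.family == "explicit":
            nodes, weights = np.unique(np.asarray(spec.values, float), return_counts=True)
            weights = weights / weights.sum()
        else:
            nodes, weights = _theta_quadrature(spec)
        harm = np.concatenate([[0.0], np.cumsum(1.0 / np.arange(1, n + 1))])
        t = np.unique(np.round(np.exp(np.linspace(0, np.log(n), 400))).astype(int))
        # weight each representative arrival time by the integer count it covers
        edges = np.concatenate([[0.5], np.sqrt(t[:-1] * t[1:]), [n + 0.5]])
        t_weight = np.diff(edges) / n
        kbar = nodes[:, None] * ((t - 1) / t + harm[n] - harm[t])[None, :]
        k = np.arange(k_max + 1)
        pk = np.zeros(k_max + 1)
        for a, wa in zip(range(len(nodes)), weights):
            pois = stats.poisson.pmf(k[None, :], kbar[a][:, None])
            pk += wa * (t_weight @ pois)
        pk = pk / pk.sum()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    k = np.arange(len(pk))
    centers, density = log_bin(k, pk)
    return DegreeCurve(k=k, pk=pk, logbin_centers=centers, logbin_density=density)


# ---------------------------------------------------------------------------
# arrival-time-averaged (permutation) marginal
# ---------------------------------------------------------------------------

def permutation_marginal(
    theta_i: float,
    theta_j: float,
    n: int,
    mean_theta: float,
    mode: str = "asymptotic",
) -> float:
    """Connection probability averaged over random arrival times.

    Averaging ``1 - exp(-theta_i theta_j / (<theta> tau))`` over the later
    arrival time ``tau`` (density ``2 tau / N^2`` on [1, N]) gives

        (2/N^2) * int_1^N tau (1 - exp(-a/tau)) d tau,   a = theta_i theta_j / <theta>

    whose sparse limit is ``2 a / N = 2 theta_i theta_j / (<theta> N)`` —
    exactly the marginal of an uncorrelated ensemble with expected degrees
    ``2 theta``.  The sparsity parameter ``a / N`` is checked in asymptotic
    mode and a warning is raised when the value exceeds 1.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if theta_i < 0 or theta_j < 0 or mean_theta <= 0:
        raise ValueError("invalid theta arguments")
    a = theta_i * theta_j / mean_theta
    if mode == "asymptotic":
        val = 2.0 * a / n
        if val > 1.0:
            warnings.warn(
                f"asymptotic marginal {val:.3g} > 1: structural cutoff violated",
                RuntimeWarning,
            )
        return val
    if mode == "integral":
        if a == 0:
            return 0.0
        res, _ = integrate.quad(
            lambda tau: tau * -np.expm1(-a / tau), 1.0, float(n),
            epsrel=1e-8, limit=200,
        )
        return 2.0 * res / n**2
    raise ValueError(f"unknown mode {mode!r}")
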