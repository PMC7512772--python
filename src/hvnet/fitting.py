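"""Discrete power-law tail fitting by maximum likelihood.

Estimates the exponent ``gamma`` of ``P(x) ∝ x**(-gamma)`` for integer data
``x >= x_min``, optionally truncated at ``x_max`` (bounded supports avoid the
bias a finite cutoff induces in the unbounded zeta-normalised fit).  Works
either from a sample of integers or from an analytic pmf, in which case the
population (expected) log-likelihood is maximised instead.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special

__all__ = ["fit_powerlaw_tail"]

_GAMMA_LO, _GAMMA_HI = 1.01, 8.0


def _log_norm(gamma: float, x_min: int, x_max: int | None) -> float:
    """log of sum_{x=x_min}^{x_max} x^(-gamma)."""
    if x_max is None:
        return np.log(special.zeta(gamma, x_min))
    x = np.arange(x_min, x_max + 1, dtype=float)
    return special.logsumexp(-gamma * np.log(x))


def fit_powerlaw_tail(
    data=None,
    *,
    pmf=None,
    x_min: int = 10,
    x_max: int | None = None,
) -> float:
    """Maximum-likelihood exponent of a discrete power-law tail.

    Parameters
    ----------
    data
        Sample of integers; values below ``x_min`` (or above ``x_max``) are
        discarded before fitting.
    pmf
        Alternative to ``data``: array ``p[s]`` of probabilities indexed by
        integer value ``s`` starting at 0.  The tail is renormalised on
        ``[x_min, x_max]`` and the expected log-likelihood is maximised.
    x_min, x_max
        Fitting window.  ``x_max=None`` uses the unbounded (Hurwitz-zeta)
        normalisation.

    Returns
    -------
    float
        The fitted exponent gamma.
    """
    if (data is None) == (pmf is None):
        raise ValueError("pass exactly one of data or pmf")

    if data is not None:
        x = np.asarray(data, dtype=float)
        x = x[x >= x_min]
        if x_max is not None:
            x = x[x <= x_max]
        if x.size < 10:
            raise ValueError("too few tail observations to fit")
        mean_log = float(np.mean(np.log(x)))
    else:
        p = np.asarray(pmf, dtype=float)
        s = np.arange(len(p))
        mask = s >= x_min
        if x_max is not None:
            mask &= s <= x_max
        w = p[mask]
        if w.sum() <= 0:
            raise ValueError("pmf has no mass in the fitting window")
        mean_log = float(np.sum(w * np.log(s[mask])) / w.sum())

    def neg_loglik(gamma: float) -> float:
        return gamma * mean_log + _log_norm(gamma, x_min, x_max)

    res = optimize.minimize_scalar(
        neg_loglik, bounds=(_GAMMA_LO, _GAMMA_HI), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)
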