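"""Linear birth-death primitives for the diversity-independent likelihood.

For a single island species subject to cladogenesis ``lam`` and extinction
``mu`` (no diversity dependence), with time ``t`` measured in Myr before
present:

* ``p0(t)``  - probability that the species leaves no extant descendant;
* ``eta(t)`` - geometric parameter of the number of extant reconstructed
  lineages conditional on survival;
* ``q1(t)``  - probability of exactly one extant descendant lineage,
  ``(1 - p0)(1 - eta)``; this is the per-branch factor of a reconstructed
  tree (all side branches doomed), and satisfies
  ``dq/dt = -(lam + mu - 2*lam*p0) q``.

Overflow-safe for large ``r*t`` by switching between the ``exp(r t)`` and
``exp(-r t)`` forms depending on the sign of ``r = lam - mu``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["p0", "eta", "q1", "bd_mean"]

_CRIT = 1e-10


def _grow_over_denom(lam: float, mu: float, t):
    """(exp(r t) - 1) / (lam exp(r t) - mu), computed stably."""
    t = np.asarray(t, dtype=float)
    r = lam - mu
    if abs(r) < _CRIT * max(lam, mu, 1.0):
        # critical case: limit t / (1 + lam t)
        return t / (1.0 + lam * t)
    if r > 0:
        em = np.exp(-r * t)
        return (1.0 - em) / (lam - mu * em)
    ep = np.exp(r * t)  # decays, safe
    return (ep - 1.0) / (lam * ep - mu)


def p0(lam: float, mu: float, t):
    """P(no extant descendants) for a lineage alive ``t`` Myr before present."""
    if mu == 0:
        return np.zeros_like(np.asarray(t, dtype=float))
    return mu * _grow_over_denom(lam, mu, t)


def eta(lam: float, mu: float, t):
    """Geometric parameter of the reconstructed-lineage count given survival."""
    if lam == 0:
        return np.zeros_like(np.asarray(t, dtype=float))
    return lam * _grow_over_denom(lam, mu, t)


def q1(lam: float, mu: float, t):
    """P(exactly one extant descendant lineage): the reconstructed-branch factor."""
    return (1.0 - p0(lam, mu, t)) * (1.0 - eta(lam, mu, t))


def bd_mean(gamma_total: float, r: float, t, n0: float = 0.0):
    """Expected diversity of an immigration-birth-death process at time ``t``.

    ``dN/dt = gamma_total + r N`` from ``N(0) = n0``; returns the closed form
    ``-G/r + (n0 + G/r) exp(r t)`` (linear in ``t`` when ``r == 0``).
    """
    t = np.asarray(t, dtype=float)
    if abs(r) < 1e-12:
        return n0 + gamma_total * t
    return -gamma_total / r + (n0 + gamma_total / r) * np.exp(r * t)
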