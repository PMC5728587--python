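"""Closed-form and semi-analytic results for the domain-wall model.

Everything here is desk arithmetic on the three key parameter combinations
of an inflating frontier:

* ``Ls = Dw / vw**2`` — the expansion length beyond which deterministic,
  selection-driven sector growth (``~ 2 vw L``) outruns diffusive wandering
  (``~ sqrt(4 Dw L)``);
* ``kappa = sqrt(R0 / Ls)`` — the strength of selection relative to
  inflation and drift on a ring of initial radius ``R0``;
* ``phi_c = sqrt(8 Dw / R0)`` — the characteristic angular correlation
  length of neutral genetic domains.

Plus the neutral voter-model laws (heterozygosity and two-point
correlations), the annihilation asymmetry for ``q`` equally inoculated
neutral strains, logarithmic-spiral sector growth, and the map from the
microscopic update rule (cell width ``a``, expansion ``d`` per generation,
bias ``r``) to ``(Dw, vw)``.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

__all__ = [
    "selection_length",
    "kappa",
    "angular_correlation_length",
    "inflationary_crossover",
    "delta_p_equal_fractions",
    "fractional_q",
    "neutral_heterozygosity",
    "neutral_two_point",
    "sector_mean_width",
    "sector_variance",
    "microscopic_map",
    "relative_fitness",
]


def selection_length(Dw: float, vw: float) -> float:
    """Selection length scale ``Ls = Dw / vw**2`` (length units).

    The neutral limit ``vw == 0`` returns ``inf``: drift never yields to
    selection.
    """
    if Dw <= 0:
        raise ValueError("Dw must be positive")
    if vw == 0:
        return np.inf
    return Dw / vw**2


def kappa(R0: float, Ls: float) -> float:
    """Inflationary selection strength ``kappa = sqrt(R0 / Ls)``."""
    if R0 <= 0 or Ls <= 0:
        raise ValueError("R0 and Ls must be positive")
    return float(np.sqrt(R0 / Ls))


def angular_correlation_length(Dw: float, R0: float) -> float:
    """Characteristic angular domain size ``phi_c = sqrt(8 Dw / R0)``."""
    if Dw <= 0 or R0 <= 0:
        raise ValueError("Dw and R0 must be positive")
    return float(np.sqrt(8.0 * Dw / R0))


def _crossover_residual(x: float, k: float) -> float:
    # deterministic sector width  kappa * ln(1 + L/R0)
    # vs diffusive width          sqrt(1 - (1 + L/R0)^-1)
    return k * np.log1p(x) - np.sqrt(x / (1.0 + x))


def inflationary_crossover(k: float, full_output: bool = False):
    """Ratio ``L_I / Ls`` where selection overtakes drift on an inflating ring.

    Solves the transcendental balance
    ``kappa * ln(1 + x) = sqrt(1 - 1/(1 + x))`` for ``x = L_I / R0`` by
    bracketed root finding (residual below 1e-10) and returns
    ``L_I / Ls = x * kappa**2``.  Asymptotics: ``L_I/Ls -> 1`` for
    ``kappa >> 1`` and ``L_I/Ls ~ kappa**2 * exp(1/kappa)`` for
    ``kappa << 1``; the ratio is monotone non-increasing in ``kappa``.
    """
    if k <= 0:
        raise ValueError("kappa must be positive")
    lo = 1e-9
    hi = max(1e3, 10.0 * np.exp(min(1.0 / k, 500.0)))
    x = brentq(_crossover_residual, lo, hi, args=(k,), xtol=1e-300, rtol=8.9e-16)
    ratio = x * k * k
    if full_output:
        return ratio, x, _crossover_residual(x, k)
    return ratio


def delta_p_equal_fractions(q: int) -> float:
    """Neutral annihilation asymmetry ``dP = (3 - q)/(q - 1)``.

    For ``q`` neutral strains inoculated in equal fractions: 1 for two
    strains (only annihilations), 0 for three, and -> -1 as q -> inf (only
    coalescences).
    """
    if q < 2:
        raise ValueError("q must be at least 2")
    return (3.0 - q) / (q - 1.0)


def fractional_q(delta_p: float) -> float:
    """Effective strain number ``q = (3 + dP)/(1 + dP)``.

    Inverts :func:`delta_p_equal_fractions`; defined for ``dP`` in
    ``(-1, 1]`` (the asymmetry diverges towards infinitely many strains as
    ``dP -> -1``).
    """
    if delta_p <= -1 or delta_p > 1:
        raise ValueError("delta_p must lie in (-1, 1]")
    return (3.0 + delta_p) / (1.0 + delta_p)


def _xi(phi, L, Dw, R0):
    phi_c = angular_correlation_length(Dw, R0)
    return np.sqrt(1.0 + R0 / L) * np.abs(phi) / phi_c


def neutral_heterozygosity(phi, L, Dw: float, R0: float, H0: float):
    """Neutral voter-model heterozygosity on an inflating ring.

    ``H(phi, L) = H0 * erf( sqrt(1 + R0/L) * |phi| / phi_c )``: the chance
    that a wall has wandered between two points an angle ``phi`` apart,
    given pair-separation variance ``4 Dw (1/R0 - 1/R)``.  ``H0`` is the
    heterozygosity of the inoculum (``1 - 1/q`` for ``q`` equal fractions).
    Vanishes at ``phi = 0``, rises monotonically to ``H0``, and decreases
    with ``L`` at fixed ``phi`` as domains coarsen.
    """
    if not (0.0 <= H0 <= 1.0):
        raise ValueError("H0 must lie in [0, 1]")
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("L must be positive (H = H0 identically at L = 0)")
    return H0 * erf(_xi(phi, L, Dw, R0))


def neutral_two_point(phi, L, Dw: float, R0: float, f) -> np.ndarray:
    """Neutral two-point correlation matrix ``F_ij(phi, L)``.

    Built from the heterozygosity law and exchangeability of neutral
    labels: with ``xi = sqrt(1 + R0/L) |phi| / phi_c``,

    * ``F_ij = f_i f_j erf(xi)``                     for ``i != j``,
    * ``F_ii = f_i**2 + f_i (1 - f_i) (1 - erf(xi))``.

    Marginalises correctly (``sum_j F_ij = f_i``) and its off-diagonal sum
    is ``H0 * erf(xi)`` with ``H0 = 1 - sum f_i**2``.  Output shape is
    ``(q, q) + shape(phi)``.
    """
    f = np.asarray(f, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("initial fractions must sum to 1")
    e = erf(_xi(np.asarray(phi, dtype=float), L, Dw, R0))
    q = f.size
    out = np.empty((q, q) + np.shape(e))
    for i in range(q):
        for j in range(q):
            if i == j:
                out[i, j] = f[i] ** 2 + f[i] * (1.0 - f[i]) * (1.0 - e)
            else:
                out[i, j] = f[i] * f[j] * e
    return out


def sector_mean_width(vw: float, R0: float, R) -> np.ndarray:
    """Logarithmic-spiral growth ``<phi - phi0> = 2 vw ln(R/R0)``."""
    R = np.asarray(R, dtype=float)
    if R0 <= 0 or np.any(R < R0):
        raise ValueError("require R >= R0 > 0")
    return 2.0 * vw * np.log(R / R0)


def sector_variance(Dw: float, R0: float, R) -> np.ndarray:
    """Sector-width variance ``Var(phi) = 4 Dw (1/R0 - 1/R)``.

    Saturates at ``4 Dw / R0`` as ``R -> inf``: inflation freezes angular
    diffusion.
    """
    R = np.asarray(R, dtype=float)
    if R0 <= 0 or np.any(R < R0):
        raise ValueError("require R >= R0 > 0")
    return 4.0 * Dw * (1.0 / R0 - 1.0 / R)


def microscopic_map(a: float, d: float, r) -> tuple[float, np.ndarray]:
    """Map the update rule onto ``(Dw, vw) = (a**2/(2d), a*r/d)``."""
    if a <= 0 or d <= 0:
        raise ValueError("a and d must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("|r| must not exceed 1")
    return a * a / (2.0 * d), a * r / d


def relative_fitness(u_i: float, u_ref: float) -> float:
    """Selective advantage from expansion velocities: ``s = u_i/u_ref - 1``."""
    if u_ref <= 0:
        raise ValueError("reference velocity must be positive")
    return u_i / u_ref - 1.0
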