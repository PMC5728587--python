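"""Inference procedures for drift and selection parameters.

Three estimators, mirroring how the corresponding experiments are analysed:

* :func:`fit_dw_heterozygosity` — the wall diffusion constant ``Dw`` from
  heterozygosity curves ``H(phi)`` at several expansion lengths, by
  per-length nonlinear least squares against the neutral erf law with
  ``Dw`` the single free parameter, averaged over lengths.
* :func:`fit_ls_correlation` — the selection length ``Ls`` (hence
  ``kappa = sqrt(R0/Ls)`` and ``vw = sqrt(Dw/Ls)``) by comparing an
  observed two-point correlation against simulated universal curves.
  Thanks to the collapse ``F_ij(phi, L) -> F_ij(phi/phi_c, L/Ls; kappa)``,
  one cached simulation per candidate ``kappa`` suffices, regardless of the
  simulated scales.  Each candidate ``Ls`` is scored by the sum of squared
  displacements weighted by the inverse squared standard error (WSSE);
  candidate probabilities are proportional to 1/WSSE, normalised, and the
  95% interval is read off that distribution.  This deliberately follows
  the WSSE-probability convention rather than a chi-square likelihood.
* :func:`fit_vw_sectors` — the wall velocity from single-sector angular
  growth: the slope of ``<phi - phi0>`` against ``ln(R/R0)`` is ``2 vw``.

:func:`predict_dynamics` closes the loop: given fitted key parameters it
simulates at matched ``kappa`` and returns observables rescaled to
physical units with no further free parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from . import theory
from .core import TWO_PI, EnsembleSummary, KeyParams, SimParams
from .simulator import run_ensemble

__all__ = [
    "ObservedCurve",
    "FitResult",
    "UniversalCurve",
    "UniversalCurveCache",
    "fit_dw_heterozygosity",
    "fit_ls_correlation",
    "fit_vw_sectors",
    "predict_dynamics",
]


@dataclass
class ObservedCurve:
    """One observed curve with pointwise standard errors.

    ``x`` is the abscissa (an angle grid for correlation/heterozygosity
    curves, ``ln(R/R0)`` for sector traces); ``L`` is the expansion length
    the curve refers to, where applicable.
    """

    x: np.ndarray
    y: np.ndarray
    se: Optional[np.ndarray] = None
    L: Optional[float] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.y.shape:
                raise ValueError("se must match y in shape")
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must match in shape")


@dataclass
class FitResult:
    """Point estimate with a 95% interval and optional candidate grid."""

    estimate: float
    ci_lo: float
    ci_hi: float
    objective: float
    grid: Optional[np.ndarray] = None
    probabilities: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.estimate <= self.ci_hi):
            raise ValueError("confidence bounds must bracket the estimate")
        if self.probabilities is not None:
            if abs(self.probabilities.sum() - 1.0) > 1e-9:
                raise ValueError("grid probabilities must sum to 1")


# ---------------------------------------------------------------------------
# Dw from heterozygosity


def fit_dw_heterozygosity(
    curves: Sequence[ObservedCurve], R0: float, H0: float
) -> FitResult:
    """Fit ``Dw`` to heterozygosity curves, one fit per expansion length.

    Each curve is fit by weighted nonlinear least squares with ``Dw`` the
    only free parameter; the estimate is the mean of the per-length fits
    and the interval is +-1.96 standard errors of that mean (degenerate
    with a single curve).  Curves must carry their ``L``.
    """
    if not curves:
        raise ValueError("need at least one heterozygosity curve")
    fits = []
    wsse = 0.0
    for c in curves:
        if c.L is None or c.L <= 0:
            raise ValueError("each curve must carry its expansion length L")
        if np.ptp(c.y) < 1e-6 * max(H0, 1e-12):
            raise ValueError("flat heterozygosity curve: Dw not identifiable")
        # initial guess from the half-height angle
        half = np.argmin(np.abs(c.y - 0.5 * H0))
        xi_half = 0.476936  # erf(xi) = 1/2
        phi_half = max(abs(c.x[half]), 1e-6)
        phi_c0 = np.sqrt(1.0 + R0 / c.L) * phi_half / xi_half
        Dw0 = max(phi_c0**2 * R0 / 8.0, 1e-8)
        sigma = c.se if c.se is not None else None

        def model(phi, Dw, L=c.L):
            return theory.neutral_heterozygosity(phi, L, Dw, R0, H0)

        popt, _ = optimize.curve_fit(
            model, c.x, c.y, p0=[Dw0], sigma=sigma, absolute_sigma=True,
            bounds=(1e-12, np.inf), maxfev=10000,
        )
        fits.append(float(popt[0]))
        resid = c.y - model(c.x, popt[0])
        w = 1.0 / sigma**2 if sigma is not None else np.ones_like(resid)
        wsse += float(np.sum(w * resid**2))
    est = float(np.mean(fits))
    if len(fits) > 1:
        sem = float(np.std(fits, ddof=1) / np.sqrt(len(fits)))
        lo, hi = est - 1.96 * sem, est + 1.96 * sem
    else:
        lo = hi = est
    return FitResult(est, lo, hi, wsse)


# ---------------------------------------------------------------------------
# universal correlation curves and the Ls fit


@dataclass
class UniversalCurve:
    """A simulated, rescaled correlation curve at one ``(kappa, L/R0)``.

    ``x = phi / phi_c`` (simulation units), ``y`` the cross-correlation
    ``F_ij`` between the competing pair with Monte-Carlo SE ``se``.
    """

    kappa: float
    L_over_R0: float
    x: np.ndarray
    y: np.ndarray
    se: np.ndarray


class UniversalCurveCache:
    """Cache of simulated universal two-point correlation curves.

    Keyed by ``(kappa, L/R0, fractions)`` on top of fixed simulation
    settings; repeated requests are served bit-identically.  The simulated
    scales are immaterial by the collapse, so modest ``N0`` suffices as
    long as ``phi_c`` stays well below the ring size (a request implying
    ``phi_c`` approaching 2*pi is rejected: such curves cannot collapse).
    """

    def __init__(
        self,
        N0: int = 1000,
        n_reps: int = 48,
        n_bins: int = 500,
        base_seed: int = 20240,
        a: float = 1.0,
    ):
        self.N0 = int(N0)
        self.n_reps = int(n_reps)
        self.n_bins = int(n_bins)
        self.base_seed = int(base_seed)
        self.a = float(a)
        self.Dw = a / 2.0  # d = a in the cached simulations
        self.R0 = self.N0 * a / TWO_PI
        self.phi_c = theory.angular_correlation_length(self.Dw, self.R0)
        if self.phi_c > 2.0:
            raise ValueError(
                "phi_c approaches the ring size; universal curves cannot "
                "be collapsed at this N0"
            )
        self._store: dict = {}

    def _key(self, kappa: float, L_over_R0: float, fractions) -> tuple:
        return (
            round(float(kappa), 9),
            round(float(L_over_R0), 9),
            tuple(round(float(x), 9) for x in fractions),
        )

    def curve(
        self, kappa: float, L_over_R0: float, fractions=(2.0 / 3.0, 1.0 / 3.0)
    ) -> UniversalCurve:
        """Simulated rescaled cross-correlation of strain 0 sweeping strain 1."""
        if kappa < 0:
            raise ValueError("kappa must be non-negative")
        key = self._key(kappa, L_over_R0, fractions)
        hit = self._store.get(key)
        if hit is not None:
            return hit
        vw = kappa * np.sqrt(self.Dw / self.R0)
        r = vw * 1.0 / self.a * self.a  # d = a: r = vw
        if abs(r) > 1:
            raise ValueError("kappa too large for this cache's N0 (|r| > 1)")
        L_sim = L_over_R0 * self.R0
        # stable per-key seed: integerised key fields under the base seed
        ints = [self.base_seed, int(kappa * 1e9), int(L_over_R0 * 1e6)]
        ints += [int(x * 1e9) for x in fractions]
        seed = int(np.random.SeedSequence(ints).generate_state(1)[0] % (2**31))
        p = SimParams(
            N0=self.N0, q=2, init_fractions=tuple(fractions),
            bias=[[0.0, r], [-r, 0.0]], geometry="radial", a=self.a,
            snapshot_lengths=(L_sim,),
        )
        _, summ = run_ensemble(p, self.n_reps, seed, n_bins=self.n_bins)
        half = self.n_bins // 2 + 1
        uc = UniversalCurve(
            kappa=float(kappa),
            L_over_R0=float(L_over_R0),
            x=summ.phi_grid[:half] / self.phi_c,
            y=summ.Fij[0, 1, :half, 0],
            se=summ.Fij_se[0, 1, :half, 0],
        )
        self._store[key] = uc
        return uc


def fit_ls_correlation(
    observed: ObservedCurve,
    Dw: float,
    R0: float,
    ls_grid: Optional[np.ndarray] = None,
    cache: Optional[UniversalCurveCache] = None,
    fractions=(2.0 / 3.0, 1.0 / 3.0),
) -> FitResult:
    """Fit the selection length from one observed cross-correlation curve.

    ``observed`` is ``F_ij(phi)`` between the competing pair at a single
    expansion length ``observed.L``, with standard errors.  Each candidate
    ``Ls`` sets ``kappa = sqrt(R0/Ls)``; the observation is rescaled
    (``phi/phi_c``, ``L/Ls``) and compared against the matching simulated
    universal curve by inverse-variance weighted SSE.
    """
    if observed.se is None or np.any(observed.se <= 0):
        raise ValueError("observed curve needs positive standard errors")
    if observed.L is None or observed.L <= 0:
        raise ValueError("observed curve must carry its expansion length L")
    if ls_grid is None:
        ls_grid = np.geomspace(R0 / 10.0, 100.0 * R0, 40)
    ls_grid = np.asarray(ls_grid, dtype=float)
    if np.any(ls_grid <= 0):
        raise ValueError("ls_grid must be positive")
    if cache is None:
        cache = UniversalCurveCache()
    phi_c_obs = theory.angular_correlation_length(Dw, R0)
    x_obs = np.abs(observed.x) / phi_c_obs
    ratio = observed.L / R0
    wsse = np.empty(ls_grid.size)
    for m, Ls in enumerate(ls_grid):
        kap = theory.kappa(R0, Ls)
        uc = cache.curve(kap, ratio, fractions)
        y_sim = np.interp(x_obs, uc.x, uc.y)
        wsse[m] = float(np.sum(((observed.y - y_sim) / observed.se) ** 2))
    probs = (1.0 / wsse) / np.sum(1.0 / wsse)
    best = int(np.argmin(wsse))
    if ls_grid.size == 1:
        return FitResult(float(ls_grid[0]), float(ls_grid[0]), float(ls_grid[0]),
                         float(wsse[0]), ls_grid, probs)
    if np.ptp(wsse) < 0.05 * wsse.min():
        warnings.warn(
            "objective is nearly flat over the Ls grid; the interval spans "
            "the whole grid", stacklevel=2,
        )
    order = np.argsort(ls_grid)
    cum = np.cumsum(probs[order])
    lo = float(ls_grid[order][np.searchsorted(cum, 0.025)])
    hi = float(ls_grid[order][min(np.searchsorted(cum, 0.975), ls_grid.size - 1)])
    est = float(ls_grid[best])
    lo, hi = min(lo, est), max(hi, est)
    return FitResult(est, lo, hi, float(wsse[best]), ls_grid, probs)


# ---------------------------------------------------------------------------
# vw from sector traces


def fit_vw_sectors(traces: Sequence[ObservedCurve]) -> FitResult:
    """Wall velocity from sector growth: OLS slope of ``<phi-phi0>`` vs
    ``ln(R/R0)`` divided by 2, with a 95% interval from the slope SE."""
    if not traces:
        raise ValueError("need at least one sector trace")
    x0 = traces[0].x
    if x0.size < 2:
        raise ValueError("need at least two abscissa points")
    for c in traces[1:]:
        if not np.array_equal(c.x, x0):
            raise ValueError("sector traces must share an abscissa grid")
    if np.ptp(x0) == 0:
        raise ValueError("degenerate abscissa: all points at one ln(R/R0)")
    Y = np.vstack([c.y for c in traces])
    with np.errstate(invalid="ignore"):
        ymean = np.nanmean(Y, axis=0)
    keep = np.isfinite(ymean)
    if keep.sum() < 2:
        raise ValueError("fewer than two usable mean points")
    res = stats.linregress(x0[keep], ymean[keep])
    vw = res.slope / 2.0
    half = 1.96 * res.stderr / 2.0 if np.isfinite(res.stderr) else 0.0
    sse = float(np.sum((ymean[keep] - (res.intercept + res.slope * x0[keep])) ** 2))
    return FitResult(float(vw), float(vw - half), float(vw + half), sse)


# ---------------------------------------------------------------------------
# forward prediction


def predict_dynamics(
    key: KeyParams,
    init_fractions: Sequence[float],
    L_grid: Sequence[float],
    N0_sim: int = 1000,
    n_reps: int = 64,
    base_seed: int = 7,
    n_bins: int = 500,
) -> EnsembleSummary:
    """Predict observables at the given key parameters, no free parameters.

    The collapse lets any simulated scale stand in: the signed
    ``kappa_ij = vw_ij * sqrt(R0/Dw)`` matrix is preserved while the
    simulation runs at its own convenient ``(Dw, R0)``; lengths map by
    ``R0_sim/R0`` and angles by ``phi_c_sim/phi_c``.  The returned summary
    carries physical grids.
    """
    f = np.asarray(init_fractions, dtype=float)
    kap_signed = key.vw * np.sqrt(key.R0 / key.Dw)
    if not np.allclose(kap_signed, -kap_signed.T):
        raise ValueError("implied kappa matrix is not antisymmetric")
    if kap_signed.shape != (f.size, f.size):
        raise ValueError("vw matrix must match the number of strains")
    a = 1.0
    Dw_sim = a / 2.0
    R0_sim = N0_sim * a / TWO_PI
    vw_sim = kap_signed * np.sqrt(Dw_sim / R0_sim)
    if np.any(np.abs(vw_sim) > 1):
        raise ValueError("kappa too large for this simulated N0 (|r| > 1)")
    scale = R0_sim / key.R0
    L_grid = np.asarray(L_grid, dtype=float)
    p = SimParams(
        N0=N0_sim, q=f.size, init_fractions=f, bias=vw_sim,
        geometry="radial", a=a, snapshot_lengths=tuple(L_grid * scale),
    )
    _, summ = run_ensemble(p, n_reps, base_seed, n_bins=n_bins)
    phi_c_sim = theory.angular_correlation_length(Dw_sim, R0_sim)
    summ.phi_grid = summ.phi_grid * (key.phi_c / phi_c_sim)
    summ.L_grid = L_grid
    return summ
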