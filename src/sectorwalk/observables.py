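"""Ensemble statistics of expanding frontiers.

Given trajectories (or externally supplied local-fraction fields) this
module computes the quantities used to compare model and experiment:

* the average fraction of each strain,
  ``F_i(L) = (1/2pi) \\int d(phi) <f_i(phi, L)>``;
* the symmetrised two-point correlation functions
  ``F_ij(phi, L) = (1/4pi) \\int d(phi') <f_i(phi') f_j(phi'+phi) + (i<->j)>``,
  the probability that two frontier points an angle ``phi`` apart carry
  strains ``i`` and ``j``;
* the heterozygosity ``H(phi, L) = sum_{i != j} F_ij(phi, L)``;
* the annihilation asymmetry ``dP = P_A - P_C`` per wall collision,
  measured as the slope of the mean cumulative (annihilations -
  coalescences) against the mean cumulative collision count;
* mean and variance of single-sector angular widths versus radius.

Angular integrals are evaluated as exact sums over a uniform grid of
``n_bins`` bins (default 500); occupancies are rasterised exactly from the
wall representation, not point-sampled.  Standard errors are between-
replicate standard errors of the mean throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import TWO_PI, EnsembleSummary, FrontierState, SimParams
from .simulator import SectorTraces, Trajectory

__all__ = [
    "FractionField",
    "DeltaPResult",
    "SectorStatistics",
    "occupancy_profile",
    "fields_from_trajectories",
    "average_fraction",
    "two_point_correlation",
    "heterozygosity",
    "annihilation_asymmetry",
    "cumulative_counts",
    "delta_p_curve",
    "sector_statistics",
    "summarize",
]


@dataclass
class FractionField:
    """Per-replicate local strain fractions on a (phi, L) grid.

    ``f`` has shape ``(n_reps, q, n_bins, nL)`` and satisfies
    ``sum_i f_i = 1`` at every grid point.  ``phi_grid`` holds bin centres.
    """

    phi_grid: np.ndarray
    L_grid: np.ndarray
    f: np.ndarray

    @property
    def n_reps(self) -> int:
        return self.f.shape[0]

    @property
    def q(self) -> int:
        return self.f.shape[1]

    @property
    def n_bins(self) -> int:
        return self.f.shape[2]

    def validate(self, atol: float = 1e-9) -> "FractionField":
        tot = self.f.sum(axis=1)
        if not np.allclose(tot, 1.0, atol=atol):
            raise ValueError("local fractions must sum to 1 at every point")
        return self


def occupancy_profile(state: FrontierState, n_bins: int, q: int) -> np.ndarray:
    """Exact angular occupancy of each strain, shape ``(q, n_bins)``.

    Each bin's value is the fraction of the bin's angular measure covered
    by the strain, computed from the wall positions; summing
    ``bin_width * f_i`` over bins returns each strain's total measure.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    f = np.zeros((q, n_bins))
    if state.n_walls == 0:
        f[state.fixed_label, :] = 1.0
        return f
    w = TWO_PI / n_bins
    phi = state.phi
    lab = state.arc_labels
    starts = phi
    ends = np.roll(phi, -1)
    ends = np.where(ends <= starts, ends + TWO_PI, ends)
    for s, e, i in zip(starts, ends, lab):
        _paint(f, int(i), s, e, w, n_bins)
    return f


def _paint(f: np.ndarray, i: int, s: float, e: float, w: float, n: int) -> None:
    """Add the arc [s, e) (e may exceed 2*pi) to strain i's bin coverage."""
    if e > TWO_PI:
        _paint(f, i, s, TWO_PI, w, n)
        _paint(f, i, 0.0, e - TWO_PI, w, n)
        return
    b0 = s / w
    b1 = e / w
    i0 = min(int(b0), n - 1)
    i1 = min(int(b1), n - 1) if b1 < n else n - 1
    if i0 == i1 and b1 <= i0 + 1:
        f[i, i0] += b1 - b0
        return
    f[i, i0] += (i0 + 1) - b0
    if i1 > i0 + 1:
        f[i, i0 + 1:i1] += 1.0
    frac = b1 - i1
    if i1 > i0 and frac > 0:
        f[i, i1] += frac


def fields_from_trajectories(
    trajectories: Sequence[Trajectory], q: int, n_bins: int = 500
) -> FractionField:
    """Rasterise every snapshot of every trajectory onto a common grid."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    L_grid = np.asarray(trajectories[0].snapshot_lengths, dtype=float)
    nL = L_grid.size
    f = np.empty((len(trajectories), q, n_bins, nL))
    for rep, tr in enumerate(trajectories):
        if len(tr.snapshots) != nL:
            raise ValueError("trajectories must share a snapshot schedule")
        for m, snap in enumerate(tr.snapshots):
            f[rep, :, :, m] = occupancy_profile(snap, n_bins, q)
    phi_grid = (np.arange(n_bins) + 0.5) * (TWO_PI / n_bins)
    return FractionField(phi_grid, L_grid, f)


def _mean_se(x: np.ndarray, axis: int = 0):
    n = x.shape[axis]
    mean = x.mean(axis=axis)
    if n < 2:
        return mean, None
    se = x.std(axis=axis, ddof=1) / np.sqrt(n)
    return mean, se


def average_fraction(field: FractionField):
    """Mean fraction of each strain vs L: ``(Fi, Fi_se)``, shape (q, nL)."""
    per_rep = field.f.mean(axis=2)  # angular mean, (reps, q, nL)
    return _mean_se(per_rep)


def two_point_correlation(field: FractionField):
    """Symmetrised angular correlations ``(Fij, Fij_se)``, (q, q, nphi, nL).

    Computed per replicate by circular (FFT) correlation on the uniform
    angular grid, then averaged over replicates.  The lag grid equals the
    field's ``phi_grid`` shifted to bin offsets ``m * 2*pi/n_bins``.
    """
    dphi = np.diff(field.phi_grid)
    if field.phi_grid.size > 1 and not np.allclose(dphi, dphi[0]):
        raise ValueError("two-point correlation requires a uniform angular grid")
    nb = field.n_bins
    F = np.fft.rfft(field.f, axis=2)  # (reps, q, K, nL)
    cross = np.conj(F[:, :, None]) * F[:, None, :]  # (reps, q, q, K, nL)
    C = np.fft.irfft(cross, n=nb, axis=3) / nb
    Fij_rep = 0.5 * (C + np.swapaxes(C, 1, 2))
    return _mean_se(Fij_rep)


def correlation_lags(n_bins: int) -> np.ndarray:
    """Angular lags corresponding to the FFT correlation output."""
    return np.arange(n_bins) * (TWO_PI / n_bins)


def heterozygosity(Fij: np.ndarray, Fij_se: Optional[np.ndarray] = None):
    """Off-diagonal sum of ``Fij``: the chance two points differ in strain.

    Returns ``(H, H_se)``; the SE combines the off-diagonal SEs in
    quadrature (an upper bound, since components covary).
    """
    q = Fij.shape[0]
    eye = np.eye(q, dtype=bool)
    H = Fij.sum(axis=(0, 1)) - Fij[eye].sum(axis=0)
    if Fij_se is None:
        return H, None
    se = np.sqrt((Fij_se**2).sum(axis=(0, 1)) - (Fij_se[eye] ** 2).sum(axis=0))
    return H, se


def heterozygosity_from_field(field: FractionField):
    """Direct ``sum_{i != j} <f_i(phi') f_j(phi' + phi)>`` on the field.

    Algebraically identical to ``heterozygosity(two_point_correlation(.))``
    since ``sum_{i != j} f_i f_j = 1 - sum_i f_i f_i``; kept as an
    independent route for cross-checks.
    """
    nb = field.n_bins
    F = np.fft.rfft(field.f, axis=2)
    auto = (np.conj(F) * F).sum(axis=1)  # sum_i |F_i|^2, (reps, K, nL)
    same = np.fft.irfft(auto, n=nb, axis=1) / nb
    H_rep = 1.0 - same
    return _mean_se(H_rep)


# ---------------------------------------------------------------------------
# annihilation asymmetry


@dataclass
class DeltaPResult:
    """Cumulative collision record and the fitted annihilation asymmetry.

    ``delta_p`` is the least-squares slope through the origin of
    ``<A - C>`` against ``<A + C>`` over the post-burn-in window; its SE
    comes from a between-replicate bootstrap.  ``delta_p`` is None when the
    logs contain no collisions.
    """

    L_grid: np.ndarray
    cum_annihilations: np.ndarray
    cum_coalescences: np.ndarray
    cum_annihilations_se: Optional[np.ndarray]
    cum_coalescences_se: Optional[np.ndarray]
    delta_p: Optional[float]
    delta_p_se: Optional[float]
    n_replicates: int


def cumulative_counts(event_L, event_kind, L_grid):
    """Cumulative (annihilations, coalescences) of one log on an L grid."""
    LA = np.sort(event_L[event_kind == 0])
    LC = np.sort(event_L[event_kind == 1])
    A = np.searchsorted(LA, L_grid, side="right").astype(float)
    C = np.searchsorted(LC, L_grid, side="right").astype(float)
    return A, C


_cumulative_counts = cumulative_counts


def delta_p_curve(
    trajectories: Sequence[Trajectory],
    L_grid: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
):
    """Cumulative annihilation asymmetry ``(<A>-<C>)/(<A>+<C>)`` vs ``L``.

    Returns ``(dp, dp_se)`` with the SE from a between-replicate bootstrap;
    grid points with no collisions yet give NaN.
    """
    L_grid = np.asarray(L_grid, dtype=float)
    A = np.empty((len(trajectories), L_grid.size))
    C = np.empty_like(A)
    for rep, tr in enumerate(trajectories):
        A[rep], C[rep] = cumulative_counts(tr.event_L, tr.event_kind, L_grid)
    with np.errstate(invalid="ignore", divide="ignore"):
        dp = (A - C).mean(axis=0) / (A + C).mean(axis=0)
    n = len(trajectories)
    if n < 2:
        return dp, None
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, L_grid.size))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        with np.errstate(invalid="ignore", divide="ignore"):
            boots[b] = (A[idx] - C[idx]).mean(axis=0) / (A[idx] + C[idx]).mean(axis=0)
    return dp, np.nanstd(boots, axis=0, ddof=1)


def annihilation_asymmetry(
    trajectories: Sequence[Trajectory],
    L_grid: Optional[np.ndarray] = None,
    n_grid: int = 200,
    burn_in: float = 0.05,
    n_boot: int = 200,
    seed: int = 0,
) -> DeltaPResult:
    """Estimate the annihilation asymmetry from ensemble event logs.

    The regression window drops points until the mean cumulative collision
    count has reached ``burn_in`` of its final value, and the slope is
    taken through the origin (both cumulative curves start at zero).
    """
    if not trajectories:
        raise ValueError("need at least one event log")
    if L_grid is None:
        Lmax = max((tr.event_L[-1] if tr.event_L.size else 0.0)
                   for tr in trajectories)
        if Lmax == 0.0:
            L_grid = np.array([0.0])
        else:
            L_grid = np.linspace(0.0, Lmax, n_grid)
    A = np.empty((len(trajectories), L_grid.size))
    C = np.empty_like(A)
    for rep, tr in enumerate(trajectories):
        A[rep], C[rep] = _cumulative_counts(tr.event_L, tr.event_kind, L_grid)
    mA, seA = _mean_se(A)
    mC, seC = _mean_se(C)
    tot = mA + mC
    if tot[-1] == 0.0:
        return DeltaPResult(L_grid, mA, mC, seA, seC, None, None, len(trajectories))

    def slope(a, c):
        x = a + c
        y = a - c
        keep = x >= burn_in * x[-1]
        x, y = x[keep], y[keep]
        return float(np.sum(x * y) / np.sum(x * x))

    dp = slope(mA, mC)
    dp_se = None
    n = len(trajectories)
    if n > 1:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            boots[b] = slope(A[idx].mean(axis=0), C[idx].mean(axis=0))
        dp_se = float(boots.std(ddof=1))
    return DeltaPResult(L_grid, mA, mC, seA, seC, dp, dp_se, n)


# ---------------------------------------------------------------------------
# sector statistics


@dataclass
class SectorStatistics:
    """Mean and variance of single-sector angular widths vs radius."""

    R_grid: np.ndarray
    R0: float
    mean_growth: np.ndarray  # <phi - phi0>
    mean_growth_se: np.ndarray
    var_width: np.ndarray
    var_width_se: np.ndarray
    n_surviving: np.ndarray
    n_excluded: np.ndarray


def sector_statistics(traces: SectorTraces) -> SectorStatistics:
    """Aggregate sector traces, excluding lost sectors from each R onward.

    A replicate whose sector (or background) is absorbed stops contributing
    at the radius of loss; the exclusion count is reported per radius.  The
    variance SE uses the normal-theory approximation
    ``Var * sqrt(2/(n-1))``.
    """
    nR = traces.R_grid.size
    mean = np.full(nR, np.nan)
    mean_se = np.full(nR, np.nan)
    var = np.full(nR, np.nan)
    var_se = np.full(nR, np.nan)
    n_surv = traces.alive.sum(axis=0)
    for m in range(nR):
        w = traces.widths[traces.alive[:, m], m]
        if w.size == 0:
            continue
        mean[m] = w.mean() - traces.phi0
        if w.size > 1:
            mean_se[m] = w.std(ddof=1) / np.sqrt(w.size)
            var[m] = w.var(ddof=1)
            var_se[m] = var[m] * np.sqrt(2.0 / (w.size - 1))
        else:
            var[m] = 0.0
    n_total = traces.widths.shape[0]
    return SectorStatistics(
        traces.R_grid, traces.R0, mean, mean_se, var, var_se,
        n_surv, n_total - n_surv,
    )


# ---------------------------------------------------------------------------
# full summary


def summarize(
    trajectories: Sequence[Trajectory],
    p: SimParams,
    n_bins: int = 500,
    delta_p_kwargs: Optional[dict] = None,
) -> EnsembleSummary:
    """Aggregate an ensemble into one :class:`EnsembleSummary`."""
    field = fields_from_trajectories(trajectories, p.q, n_bins)
    Fi, Fi_se = average_fraction(field)
    Fij, Fij_se = two_point_correlation(field)
    H, _ = heterozygosity(Fij)
    # per-replicate heterozygosity gives the statistically proper SE
    _, H_se = heterozygosity_from_field(field)
    L_grid = field.L_grid
    A = np.empty((len(trajectories), L_grid.size))
    C = np.empty_like(A)
    for rep, tr in enumerate(trajectories):
        A[rep], C[rep] = _cumulative_counts(tr.event_L, tr.event_kind, L_grid)
    mA, seA = _mean_se(A)
    mC, seC = _mean_se(C)
    return EnsembleSummary(
        L_grid=L_grid,
        phi_grid=correlation_lags(n_bins),
        Fi=Fi, Fi_se=Fi_se,
        Fij=Fij, Fij_se=Fij_se,
        H=H, H_se=H_se,
        cum_annihilations=mA, cum_annihilations_se=seA,
        cum_coalescences=mC, cum_coalescences_se=seC,
        n_replicates=len(trajectories),
    )
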