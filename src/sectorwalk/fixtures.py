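"""Synthetic, experiment-like datasets with known ground truth.

Every inference routine in :mod:`sectorwalk.fitting` can be exercised
without any laboratory data: the generators here run the simulator at a
stated truth (``Dw``, ``R0``, wall velocities, inoculated fractions),
rasterise the frontier into local-fraction fields the way an imaging
pipeline would, and hand the truth back alongside for recovery tests.

The fraction fields can optionally emulate the main image-analysis
artifact of fluorescence segmentation: where binary strain masks overlap
near a domain boundary, the local fraction is split equally among the
overlapping strains, so measured heterozygosity fails to vanish at zero
separation.  The emulation assigns the two flanking strains a fraction of
1/2 each within ``overlap_blur`` radians of every wall.  Because the wall
count falls as domains coarsen, the artifact weakens as the colony grows,
as it does in real images.

These are synthetic stand-ins for imaging-derived data, not reproductions
of any instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import observables
from .core import TWO_PI, KeyParams, SimParams
from .fitting import ObservedCurve
from .observables import FractionField
from .simulator import run_ensemble, run_sector_ensemble

__all__ = ["FixtureSpec", "make_fraction_fields", "make_sector_traces"]


@dataclass
class FixtureSpec:
    """Ground truth plus acquisition settings for one synthetic dataset.

    ``truth.vw`` fixes the wall-velocity matrix; the microscopic simulation
    realises ``truth`` exactly via ``a = 1``, ``d = 1/(2 Dw)``,
    ``r = vw * d`` and ``N0 = round(2 pi R0)``.  ``overlap_blur`` is the
    angular half-width (radians) of the boundary-overlap artifact; 0
    disables it.
    """

    truth: KeyParams
    init_fractions: Sequence[float]
    n_replicates: int = 50
    L_grid: Sequence[float] = field(default_factory=lambda: (50.0, 100.0, 200.0))
    phi_bins: int = 500
    overlap_blur: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.overlap_blur < 0:
            raise ValueError("overlap_blur must be non-negative")
        self.init_fractions = np.asarray(self.init_fractions, dtype=float)
        self.L_grid = tuple(float(x) for x in self.L_grid)

    def sim_params(self) -> SimParams:
        a = 1.0
        d = a * a / (2.0 * self.truth.Dw)
        r = self.truth.vw * d / a
        if np.any(np.abs(r) > 1.0):
            raise ValueError("truth vw not realisable: |r| exceeds 1")
        N0 = int(round(TWO_PI * self.truth.R0 / a))
        return SimParams(
            N0=N0, q=self.init_fractions.size,
            init_fractions=self.init_fractions, bias=r, geometry="radial",
            a=a, d=d, snapshot_lengths=self.L_grid,
        )

    def truth_record(self) -> dict:
        return {
            "Dw": float(self.truth.Dw),
            "R0": float(self.truth.R0),
            "vw": np.asarray(self.truth.vw).tolist(),
            "phi_c": float(self.truth.phi_c),
            "init_fractions": np.asarray(self.init_fractions).tolist(),
            "overlap_blur": float(self.overlap_blur),
            "n_replicates": int(self.n_replicates),
            "L_grid": list(self.L_grid),
            "seed": int(self.seed),
        }


def _apply_overlap_blur(
    f: np.ndarray, snap, blur: float, n_bins: int
) -> None:
    """Mix the two flanking strains 50/50 within ``blur`` of each wall."""
    if blur == 0.0 or snap.n_walls == 0:
        return
    centers = (np.arange(n_bins) + 0.5) * (TWO_PI / n_bins)
    lab = snap.arc_labels
    for k in range(snap.n_walls):
        left = int(lab[k - 1])
        right = int(lab[k])
        dist = np.abs((centers - snap.phi[k] + np.pi) % TWO_PI - np.pi)
        hit = dist <= blur
        f[:, hit] = 0.0
        f[left, hit] += 0.5
        f[right, hit] += 0.5


def make_fraction_fields(spec: FixtureSpec):
    """Simulate at the truth and rasterise local-fraction fields.

    Returns ``(FractionField, truth_dict)``; with ``overlap_blur == 0`` the
    fields equal the exact occupancy profiles.
    """
    p = spec.sim_params()
    trajs, _ = run_ensemble(p, spec.n_replicates, spec.seed, n_bins=spec.phi_bins)
    nL = len(spec.L_grid)
    fshape = (spec.n_replicates, p.q, spec.phi_bins, nL)
    f = np.empty(fshape)
    for rep, tr in enumerate(trajs):
        for m, snap in enumerate(tr.snapshots):
            prof = observables.occupancy_profile(snap, spec.phi_bins, p.q)
            _apply_overlap_blur(prof, snap, spec.overlap_blur, spec.phi_bins)
            f[rep, :, :, m] = prof
    phi_grid = (np.arange(spec.phi_bins) + 0.5) * (TWO_PI / spec.phi_bins)
    ff = FractionField(phi_grid, np.asarray(spec.L_grid), f).validate()
    return ff, spec.truth_record()


def make_sector_traces(spec: FixtureSpec, phi0: float = 0.5 * np.pi):
    """Single-sector traces for the wall-velocity fit, plus ground truth.

    The truth must contain exactly one focal pair: strain 0 (background)
    and strain 1 (sector) with wall velocity ``vw = truth.vw[1, 0]``.
    Returns ``(traces, truth_dict)`` where ``traces`` is one
    :class:`~sectorwalk.fitting.ObservedCurve` per replicate on the common
    grid ``x = ln(R/R0)`` (lost sectors carry NaN from the loss onward; the
    truth records how many were lost).
    """
    vw_mat = np.atleast_2d(spec.truth.vw)
    if vw_mat.shape != (2, 2):
        raise ValueError("sector traces need a single focal pair (2 strains)")
    vw = float(vw_mat[1, 0])
    a = 1.0
    d = a * a / (2.0 * spec.truth.Dw)
    N0 = int(round(TWO_PI * spec.truth.R0 / a))
    R_factors = 1.0 + np.asarray(spec.L_grid, dtype=float) / spec.truth.R0
    traces_raw = run_sector_ensemble(
        vw, N0, R_factors, spec.n_replicates, base_seed=spec.seed,
        a=a, d=d, phi0=phi0,
    )
    x = np.log(R_factors)
    curves = []
    for rep in range(spec.n_replicates):
        y = np.where(traces_raw.alive[rep], traces_raw.widths[rep] - phi0, np.nan)
        curves.append(ObservedCurve(x, y))
    truth = spec.truth_record()
    truth["phi0"] = float(phi0)
    truth["n_lost"] = traces_raw.n_lost
    return curves, truth
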