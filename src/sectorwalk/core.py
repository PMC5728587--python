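"""Domain types shared by the simulator, observables, theory and fitting layers.

The frontier of a radially expanding microbial colony is modelled as a ring
of genetic domain walls: points on the circle where the strain identity of
the frontier changes.  Everything downstream (the random-walk engine, the
ensemble statistics, the inference procedures) speaks in terms of these
types, so their invariants are checked eagerly here.

Conventions
-----------
* Angles are radians, half-open ``[0, 2*pi)``, periodic; wall positions are
  continuous reals (the model is off-lattice).
* Strains are labelled by small contiguous integers ``0..q-1``; optional
  free-text names (e.g. ``"eCFP"``) ride along in :class:`SimParams`.
* Lengths are in units of the cell width ``a`` unless stated otherwise.
* ``L = R - R0`` is the length expanded by the colony since local fixation
  into monoclonal sectors at the initial radius ``R0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

TWO_PI = 2.0 * np.pi

__all__ = [
    "TWO_PI",
    "StrainLabel",
    "WallType",
    "DomainWall",
    "FrontierState",
    "SimParams",
    "CollisionEvent",
    "KeyParams",
    "EnsembleSummary",
    "validate_params",
]


@dataclass(frozen=True)
class StrainLabel:
    """One of the ``q`` competing strains (alleles)."""

    id: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.id < 0:
            raise ValueError("strain id must be a non-negative integer")


@dataclass(frozen=True)
class WallType:
    """Type ``ij`` of a domain wall.

    ``left`` is the strain to the left of the wall (clockwise, i.e. at
    smaller angle) and ``right`` the strain to the right; a wall separates
    distinct strains by definition.
    """

    left: int
    right: int

    def __post_init__(self) -> None:
        if self.left == self.right:
            raise ValueError("a domain wall separates distinct strains")

    def reversed(self) -> "WallType":
        return WallType(self.right, self.left)


@dataclass(frozen=True)
class DomainWall:
    """A single wall: angular position plus type."""

    phi: float
    type: WallType

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi < TWO_PI):
            raise ValueError("wall angle must lie in [0, 2*pi)")


@dataclass
class FrontierState:
    """The frontier at one instant: walls on a (possibly inflating) ring.

    ``phi`` holds wall angles sorted ascending in ``[0, 2*pi)`` and
    ``arc_labels[k]`` is the strain occupying the arc counterclockwise of
    wall ``k`` (from ``phi[k]`` to ``phi[k+1]``, cyclically).  The type of
    wall ``k`` is therefore ``(arc_labels[k-1], arc_labels[k])``.

    When no walls remain the ring is monoclonal and ``fixed_label`` records
    the surviving strain.
    """

    phi: np.ndarray
    arc_labels: np.ndarray
    R0: float
    R: float
    L: float
    t: float
    geometry: str = "radial"
    fixed_label: Optional[int] = None

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.arc_labels = np.asarray(self.arc_labels, dtype=np.int64)

    @property
    def n_walls(self) -> int:
        return int(self.phi.size)

    @property
    def walls(self) -> list[DomainWall]:
        out = []
        for k in range(self.n_walls):
            wt = WallType(int(self.arc_labels[k - 1]), int(self.arc_labels[k]))
            out.append(DomainWall(float(self.phi[k]), wt))
        return out

    def wall_types(self) -> list[WallType]:
        return [w.type for w in self.walls]

    def arc_widths(self) -> np.ndarray:
        """Angular width of the arc counterclockwise of each wall."""
        if self.n_walls == 0:
            return np.array([TWO_PI])
        w = np.diff(self.phi, append=self.phi[0] + TWO_PI)
        return w

    def validate(self, atol: float = 1e-9) -> "FrontierState":
        if self.geometry not in ("linear", "radial"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.geometry == "linear" and abs(self.R - self.R0) > atol:
            raise ValueError("linear geometry requires R == R0 at all times")
        n = self.n_walls
        if n == 0:
            if self.fixed_label is None:
                raise ValueError("wall-free state needs a fixed_label")
            return self
        if self.arc_labels.size != n:
            raise ValueError("arc_labels must be parallel to phi")
        if np.any(np.diff(self.phi) <= 0):
            raise ValueError("wall angles must be strictly increasing")
        if self.phi[0] < 0 or self.phi[-1] >= TWO_PI:
            raise ValueError("wall angles must lie in [0, 2*pi)")
        widths = self.arc_widths()
        if np.any(widths <= 0):
            raise ValueError("arcs must have positive angular width")
        if abs(widths.sum() - TWO_PI) > atol:
            raise ValueError("arc widths must sum to 2*pi")
        if np.any(self.arc_labels == np.roll(self.arc_labels, 1)):
            raise ValueError("adjacent arcs must carry different strains")
        return self

    def copy(self) -> "FrontierState":
        return FrontierState(
            self.phi.copy(), self.arc_labels.copy(), self.R0, self.R,
            self.L, self.t, self.geometry, self.fixed_label,
        )


@dataclass
class SimParams:
    """All microscopic inputs of one simulation.

    Parameters
    ----------
    N0 : initial number of cells at the front (ring circumference ``N0*a``).
    q : number of strains.
    init_fractions : inoculated fraction of each strain; sums to 1.
    bias : antisymmetric ``q x q`` matrix ``r`` with ``r[i, j]`` the hop bias
        of an ``ij`` wall; ``|r| <= 1``.  ``r[i, j] > 0`` means strain ``i``
        deterministically displaces strain ``j``.
    geometry : ``"radial"`` (inflating ring) or ``"linear"`` (fixed ring).
    a : cell width, the hop length (length units; default 1).
    d : length expanded per generation (defaults to ``a``).
    seed : RNG seed used when no generator is supplied to ``run``.
    snapshot_lengths : increasing lengths expanded ``L`` at which the
        frontier is recorded.
    init_mode : ``"iid"`` draws each initial cell label independently from
        ``init_fractions``; ``"exact"`` places ``round(N0*f_i)`` cells of
        each strain in uniformly random order.
    """

    N0: int
    q: int
    init_fractions: Sequence[float]
    bias: Optional[Sequence[Sequence[float]]] = None
    geometry: str = "radial"
    a: float = 1.0
    d: Optional[float] = None
    seed: Optional[int] = None
    snapshot_lengths: Sequence[float] = field(default_factory=tuple)
    init_mode: str = "iid"
    strain_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.init_fractions = np.asarray(self.init_fractions, dtype=float)
        if self.bias is None:
            self.bias = np.zeros((self.q, self.q))
        self.bias = np.asarray(self.bias, dtype=float)
        if self.d is None:
            self.d = float(self.a)
        self.snapshot_lengths = tuple(float(x) for x in self.snapshot_lengths)

    @property
    def R0(self) -> float:
        """Initial radius: circumference ``N0*a`` wrapped onto a circle."""
        return self.N0 * self.a / TWO_PI

    @property
    def strains(self) -> list[StrainLabel]:
        names = self.strain_names or [""] * self.q
        return [StrainLabel(i, names[i]) for i in range(self.q)]

    def to_dict(self) -> dict:
        return {
            "N0": int(self.N0),
            "q": int(self.q),
            "init_fractions": [float(x) for x in self.init_fractions],
            "bias": np.asarray(self.bias).tolist(),
            "geometry": self.geometry,
            "a": float(self.a),
            "d": float(self.d),
            "seed": self.seed,
            "snapshot_lengths": list(self.snapshot_lengths),
            "init_mode": self.init_mode,
            "strain_names": list(self.strain_names) if self.strain_names else None,
        }

    @classmethod
    def from_dict(cls, cfg: dict) -> "SimParams":
        return cls(**cfg)


def validate_params(p: SimParams, tol: float = 1e-12) -> SimParams:
    """Check every :class:`SimParams` invariant; return ``p`` unchanged.

    Raises ``ValueError`` naming the first violated invariant.
    """
    if p.N0 < 2:
        raise ValueError("N0 must be at least 2")
    if p.q < 1:
        raise ValueError("q must be at least 1")
    f = np.asarray(p.init_fractions, dtype=float)
    if f.shape != (p.q,):
        raise ValueError("init_fractions must have length q")
    if np.any(f < 0):
        raise ValueError("fractions must be non-negative")
    if abs(f.sum() - 1.0) > tol:
        raise ValueError("fractions sum != 1")
    b = np.asarray(p.bias, dtype=float)
    if b.shape != (p.q, p.q):
        raise ValueError("bias must be a q x q matrix")
    if not np.allclose(b, -b.T, atol=tol):
        raise ValueError("bias not antisymmetric")
    if np.any(np.abs(b) > 1.0):
        raise ValueError("bias entries must satisfy |r| <= 1")
    if p.geometry not in ("linear", "radial"):
        raise ValueError(f"unknown geometry {p.geometry!r}")
    if p.a <= 0 or p.d <= 0:
        raise ValueError("a and d must be positive lengths")
    if p.init_mode not in ("iid", "exact"):
        raise ValueError(f"unknown init_mode {p.init_mode!r}")
    if list(p.snapshot_lengths) != sorted(p.snapshot_lengths) or any(
        x < 0 for x in p.snapshot_lengths
    ):
        raise ValueError("snapshot_lengths must be non-negative and increasing")
    return p


@dataclass(frozen=True)
class CollisionEvent:
    """One wall-wall reaction.

    ``consumed`` lists the two reacting wall types in spatial order (left
    wall first).  An annihilation removes both walls (outer flanking strains
    equal); a coalescence replaces them with a single wall joining the outer
    flanks (``produced``).
    """

    L_at: float
    kind: str  # "annihilation" | "coalescence"
    consumed: tuple[WallType, WallType]
    produced: Optional[WallType] = None

    def __post_init__(self) -> None:
        lw, rw = self.consumed
        if lw.right != rw.left:
            raise ValueError("consumed walls must share their inner strain")
        if self.kind == "annihilation":
            if lw.left != rw.right:
                raise ValueError("annihilation requires equal outer flanks")
            if self.produced is not None:
                raise ValueError("annihilation produces no wall")
        elif self.kind == "coalescence":
            if lw.left == rw.right:
                raise ValueError("coalescence requires distinct outer flanks")
            if self.produced is None or self.produced != WallType(lw.left, rw.right):
                raise ValueError("coalescence must produce the outer-flank wall")
        else:
            raise ValueError(f"unknown collision kind {self.kind!r}")


def _safe_sqrt_ratio(num: float, den: float) -> float:
    return float(np.sqrt(num / den))


@dataclass
class KeyParams:
    """The three key parameter combinations plus their microscopic inputs.

    ``vw`` is the antisymmetric matrix of dimensionless wall velocities (the
    deterministic transverse displacement per unit length expanded).  Per
    strain pair the derived quantities are

    * ``Ls = Dw / vw**2`` — selection length scale,
    * ``kappa = sqrt(R0 / Ls)`` — inflationary selection strength,
    * ``LI`` — inflationary crossover length (solves the transcendental
      balance between logarithmic sector growth and saturating diffusion),

    and globally ``phi_c = sqrt(8 * Dw / R0)``, the characteristic angular
    correlation length of neutral domains.  Neutral pairs (``vw == 0``) get
    infinite ``Ls``/``LI`` and ``kappa == 0``.
    """

    Dw: float
    R0: float
    vw: np.ndarray

    def __post_init__(self) -> None:
        self.vw = np.atleast_2d(np.asarray(self.vw, dtype=float))
        if self.Dw <= 0 or self.R0 <= 0:
            raise ValueError("Dw and R0 must be positive")
        if not np.allclose(self.vw, -self.vw.T):
            raise ValueError("wall-velocity matrix must be antisymmetric")

    @property
    def phi_c(self) -> float:
        return _safe_sqrt_ratio(8.0 * self.Dw, self.R0)

    @property
    def Ls(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return self.Dw / np.abs(self.vw) ** 2

    @property
    def kappa(self) -> np.ndarray:
        return np.sqrt(self.R0 / self.Ls)

    @property
    def LI(self) -> np.ndarray:
        from . import theory  # deferred: theory imports core

        k = self.kappa
        out = np.full_like(k, np.inf)
        for idx in np.ndindex(k.shape):
            if k[idx] > 0:
                out[idx] = theory.inflationary_crossover(k[idx]) * self.Ls[idx]
        return out

    @classmethod
    def from_microscopic(cls, a: float, d: float, bias: np.ndarray, N0: int) -> "KeyParams":
        """Map simulation inputs onto (Dw, R0, vw): Dw = a^2/(2d), vw = a*r/d."""
        bias = np.asarray(bias, dtype=float)
        return cls(Dw=a * a / (2.0 * d), R0=N0 * a / TWO_PI, vw=a * bias / d)


@dataclass
class EnsembleSummary:
    """Gridded ensemble statistics with between-replicate standard errors.

    Shapes: ``Fi`` is ``(q, nL)``, ``Fij`` is ``(q, q, nphi, nL)``, ``H`` is
    ``(nphi, nL)``; the cumulative collision counts are per ``L`` grid
    point.  Standard errors are ``None`` when ``n_replicates == 1``.
    """

    L_grid: np.ndarray
    phi_grid: np.ndarray
    Fi: np.ndarray
    Fi_se: Optional[np.ndarray]
    Fij: np.ndarray
    Fij_se: Optional[np.ndarray]
    H: np.ndarray
    H_se: Optional[np.ndarray]
    cum_annihilations: np.ndarray
    cum_annihilations_se: Optional[np.ndarray]
    cum_coalescences: np.ndarray
    cum_coalescences_se: Optional[np.ndarray]
    n_replicates: int

    def validate(self, atol: float = 1e-8) -> "EnsembleSummary":
        if not np.allclose(self.Fi.sum(axis=0), 1.0, atol=atol):
            raise ValueError("average fractions must sum to 1 at every L")
        if not np.allclose(self.Fij.sum(axis=(0, 1)), 1.0, atol=atol):
            raise ValueError("two-point correlations must sum to 1")
        if not np.allclose(self.Fij, np.swapaxes(self.Fij, 0, 1), atol=atol):
            raise ValueError("Fij must equal Fji")
        if not np.allclose(
            self.Fij, self.Fij[:, :, (-np.arange(self.phi_grid.size)) % self.phi_grid.size, :],
            atol=atol,
        ):
            raise ValueError("Fij must be even in phi")
        off = self.Fij.sum(axis=(0, 1)) - np.einsum("iipl->pl", self.Fij)
        if not np.allclose(off, self.H, atol=atol):
            raise ValueError("H must equal the off-diagonal sum of Fij")
        return self
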