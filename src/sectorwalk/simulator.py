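"""Annihilating-coalescing random-walk engine for expanding frontiers.

The frontier is a ring of domain walls.  One Monte-Carlo move picks a wall
uniformly at random and hops it a cell width ``a`` left or right, with a
rightward probability ``(1 + r_ij)/2`` set by the bias of its type; if the
hop reaches or crosses the nearest wall in the hop direction the two walls
react instantly (annihilate when the outer flanking strains match, coalesce
otherwise).  Each hop advances time by ``1/N`` generations and the length
expanded by ``d/N``, with ``N`` the wall count before the hop.  In radial
geometry the ring inflates, ``R(t) = R0 + a*t``, and the angular hop length
``a/R`` shrinks as the colony grows; in linear geometry ``R = R0`` forever.

Two execution paths share one kernel source (see ``_engine``): a compiled
fast path used by :func:`run`, and :func:`step`, a plain-Python reference
used for single-hop tests.  Both consume two uniforms per hop.

The module also provides engine-backed probes used for calibration and for
the sector statistics: :func:`probe_wall_motion` (transverse displacement
of isolated walls on a linear front) and :func:`run_sector_ensemble`
(single sectors of a fitter strain on an inflating ring).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _engine
from ._engine import REASON_FIXATION, REASON_L_STOP, REASON_REFILL
from .core import (
    TWO_PI,
    CollisionEvent,
    FrontierState,
    SimParams,
    WallType,
    validate_params,
)

__all__ = [
    "Trajectory",
    "SectorTraces",
    "WallMotionProbe",
    "init_frontier",
    "step",
    "run",
    "run_from_state",
    "run_ensemble",
    "probe_wall_motion",
    "run_sector_ensemble",
]

_BLOCK = 1 << 16


# ---------------------------------------------------------------------------
# initialisation


def _draw_labels(p: SimParams, rng: np.random.Generator) -> np.ndarray:
    f = np.asarray(p.init_fractions, dtype=float)
    if p.init_mode == "iid":
        return rng.choice(p.q, size=p.N0, p=f)
    # exact proportions via largest remainder, then a uniform random order
    ideal = f * p.N0
    counts = np.floor(ideal).astype(int)
    short = p.N0 - counts.sum()
    if short > 0:
        order = np.argsort(-(ideal - counts))
        counts[order[:short]] += 1
    labels = np.repeat(np.arange(p.q), counts)
    return rng.permutation(labels)


def init_frontier(p: SimParams, rng: np.random.Generator) -> FrontierState:
    """Place ``N0`` cells of width ``a`` on the ring and mark the walls.

    Cell ``k`` occupies angles ``[k, k+1) * 2*pi/N0``; a wall sits at each
    boundary between unlike neighbours.  Starts at ``t = L = 0``,
    ``R = R0 = N0*a/(2*pi)``.
    """
    validate_params(p)
    labels = _draw_labels(p, rng)
    return frontier_from_labels(labels, p)


def frontier_from_labels(labels: Sequence[int], p: SimParams) -> FrontierState:
    """Build the initial frontier from an explicit cell-label sequence."""
    labels = np.asarray(labels, dtype=np.int64)
    n0 = labels.size
    nxt_lab = np.roll(labels, -1)
    bnd = np.nonzero(labels != nxt_lab)[0]  # wall after cell k
    R0 = n0 * p.a / TWO_PI
    if bnd.size == 0:
        return FrontierState(
            np.empty(0), np.empty(0, dtype=np.int64), R0, R0, 0.0, 0.0,
            p.geometry, fixed_label=int(labels[0]),
        )
    phi = ((bnd + 1) % n0) * (TWO_PI / n0)
    rlab = nxt_lab[bnd]
    order = np.argsort(phi)
    return FrontierState(phi[order], rlab[order], R0, R0, 0.0, 0.0, p.geometry)


# ---------------------------------------------------------------------------
# reference single-hop dynamics


def step(
    state: FrontierState, p: SimParams, rng: np.random.Generator
) -> tuple[FrontierState, Optional[CollisionEvent]]:
    """Advance the frontier by one hop (reference implementation).

    Returns the new state and the collision event, if the hop triggered one.
    Stepping a wall-free (fixated) state is rejected.
    """
    n = state.n_walls
    if n == 0:
        raise ValueError("cannot step a fixated frontier (0 walls)")
    u1, u2 = rng.random(2)
    k = min(int(u1 * n), n - 1)
    phi = state.phi.copy()
    lab = state.arc_labels.copy()
    li = int(lab[k - 1])
    ri = int(lab[k])
    r = float(p.bias[li, ri])
    dphi = p.a / state.R

    inv = 1.0 / n
    t = state.t + inv
    L = state.L + p.d * inv
    R = state.R + (p.d * inv if state.geometry == "radial" else 0.0)

    event: Optional[CollisionEvent] = None
    fixed: Optional[int] = None
    if u2 < 0.5 * (1.0 + r):  # rightward hop
        j = (k + 1) % n
        gap = (phi[j] - phi[k]) % TWO_PI
        if gap == 0.0:
            gap = TWO_PI
        if gap <= dphi * (1.0 + 1e-9):
            lo, ro = li, int(lab[j])
            consumed = (WallType(li, ri), WallType(ri, ro))
            if lo == ro:
                event = CollisionEvent(L, "annihilation", consumed)
                keep = np.ones(n, bool)
                keep[[k, j]] = False
                phi, lab = phi[keep], lab[keep]
                if phi.size == 0:
                    fixed = lo
            else:
                event = CollisionEvent(L, "coalescence", consumed, WallType(lo, ro))
                phi, lab = np.delete(phi, k), np.delete(lab, k)
        else:
            phi[k] = (phi[k] + dphi) % TWO_PI
    else:  # leftward hop
        j = (k - 1) % n
        gap = (phi[k] - phi[j]) % TWO_PI
        if gap == 0.0:
            gap = TWO_PI
        if gap <= dphi * (1.0 + 1e-9):
            lo, ro = int(lab[j - 1]), ri
            consumed = (WallType(lo, li), WallType(li, ri))
            if lo == ro:
                event = CollisionEvent(L, "annihilation", consumed)
                keep = np.ones(n, bool)
                keep[[j, k]] = False
                phi, lab = phi[keep], lab[keep]
                if phi.size == 0:
                    fixed = lo
            else:
                event = CollisionEvent(L, "coalescence", consumed, WallType(lo, ro))
                lab[j] = ri
                phi, lab = np.delete(phi, k), np.delete(lab, k)
        else:
            phi[k] = (phi[k] - dphi) % TWO_PI
    if phi.size and np.any(np.diff(phi) < 0):  # a wall wrapped through 0
        order = np.argsort(phi)
        phi, lab = phi[order], lab[order]
    new = FrontierState(phi, lab, state.R0, R, L, t, state.geometry, fixed)
    return new, event


# ---------------------------------------------------------------------------
# fast engine


class _Engine:
    """Array-backed frontier driven by the compiled kernel."""

    def __init__(self, state: FrontierState, p: SimParams, rng: np.random.Generator):
        n = state.n_walls
        cap = max(n, 1)
        self.p = p
        self.rng = rng
        self.geometry = state.geometry
        self.R0 = state.R0
        self.fixed_label = state.fixed_label
        self.pos = np.ascontiguousarray(state.phi, dtype=np.float64)
        self.rlab = np.ascontiguousarray(state.arc_labels, dtype=np.int64)
        idx = np.arange(n, dtype=np.int64)
        self.nxt = np.roll(idx, -1) if n else idx
        self.prv = np.roll(idx, 1) if n else idx
        self.active = idx.copy()
        self.apos = idx.copy()
        self.scal = np.array([state.t, state.L, state.R], dtype=np.float64)
        self.cnt = np.array([n, 0, 0], dtype=np.int64)
        self.bias = np.ascontiguousarray(p.bias, dtype=np.float64)
        self.ev_L = np.zeros(cap, dtype=np.float64)
        self.ev_kind = np.zeros(cap, dtype=np.int8)
        self.ev_lab = np.full((cap, 6), -1, dtype=np.int64)
        self._us = np.empty(0, dtype=np.float64)

    @property
    def n_walls(self) -> int:
        return int(self.cnt[0])

    @property
    def L(self) -> float:
        return float(self.scal[1])

    def advance(self, L_stop: float) -> int:
        if self.cnt[0] == 0:
            return REASON_FIXATION
        radial = self.geometry == "radial"
        while True:
            reason = _engine._advance(
                self.pos, self.rlab, self.nxt, self.prv, self.active,
                self.apos, self.scal, self.cnt, self.bias,
                float(self.p.a), float(self.p.d), radial, float(L_stop),
                self._us, self.ev_L, self.ev_kind, self.ev_lab,
            )
            if reason == REASON_REFILL:
                self._us = self.rng.random(_BLOCK)
                self.cnt[2] = 0
                continue
            if reason == REASON_FIXATION and self.cnt[1] > 0:
                # the survivor is the outer flank of the final annihilation
                self.fixed_label = int(self.ev_lab[self.cnt[1] - 1, 0])
            return reason

    def snapshot(self) -> FrontierState:
        n = self.n_walls
        t, L, R = (float(x) for x in self.scal)
        if n == 0:
            return FrontierState(
                np.empty(0), np.empty(0, dtype=np.int64), self.R0, R, L, t,
                self.geometry, self.fixed_label,
            )
        slots = np.empty(n, dtype=np.int64)
        s = self.active[0]
        for k in range(n):
            slots[k] = s
            s = self.nxt[s]
        phi = self.pos[slots]
        lab = self.rlab[slots]
        start = int(np.argmin(phi))
        phi = np.roll(phi, -start)
        lab = np.roll(lab, -start)
        return FrontierState(phi, lab, self.R0, R, L, t, self.geometry)

    def event_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ne = int(self.cnt[1])
        return (
            self.ev_L[:ne].copy(),
            self.ev_kind[:ne].copy(),
            self.ev_lab[:ne].copy(),
        )


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """One realisation: snapshots at requested lengths plus the event log.

    ``event_L``/``event_kind`` are flat arrays (kind 0 = annihilation,
    1 = coalescence) for fast aggregation; :attr:`events` materialises the
    typed :class:`~sectorwalk.core.CollisionEvent` list on demand.
    """

    snapshots: list[FrontierState]
    snapshot_lengths: tuple[float, ...]
    final_state: FrontierState
    event_L: np.ndarray
    event_kind: np.ndarray
    event_labels: np.ndarray
    _events: Optional[list[CollisionEvent]] = field(default=None, repr=False)

    @property
    def events(self) -> list[CollisionEvent]:
        if self._events is None:
            out = []
            for L, kd, lb in zip(self.event_L, self.event_kind, self.event_labels):
                consumed = (WallType(int(lb[0]), int(lb[1])),
                            WallType(int(lb[2]), int(lb[3])))
                if kd == 0:
                    out.append(CollisionEvent(float(L), "annihilation", consumed))
                else:
                    out.append(CollisionEvent(
                        float(L), "coalescence", consumed,
                        WallType(int(lb[4]), int(lb[5])),
                    ))
            self._events = out
        return self._events

    @property
    def n_annihilations(self) -> int:
        return int(np.sum(self.event_kind == 0))

    @property
    def n_coalescences(self) -> int:
        return int(np.sum(self.event_kind == 1))


def run(
    p: SimParams,
    rng: Optional[np.random.Generator] = None,
    L_max: Optional[float] = None,
    engine: str = "fast",
) -> Trajectory:
    """Run one expansion until fixation or until ``L`` exceeds the last target.

    Snapshots are recorded at the first hop where ``L`` reaches each entry
    of ``p.snapshot_lengths``.  For radial geometry a finite stopping length
    (snapshots or ``L_max``) is required: inflation makes fixation times
    unbounded, so an open-ended radial run may never terminate.
    """
    validate_params(p)
    if rng is None:
        rng = np.random.default_rng(p.seed)
    state = init_frontier(p, rng)
    return run_from_state(state, p, rng, L_max=L_max, engine=engine)


def run_from_state(
    state: FrontierState,
    p: SimParams,
    rng: np.random.Generator,
    L_max: Optional[float] = None,
    engine: str = "fast",
) -> Trajectory:
    """As :func:`run` but starting from an explicit frontier state."""
    targets = sorted(p.snapshot_lengths)
    if L_max is None:
        if targets:
            L_max = targets[-1]
        elif p.geometry == "linear":
            L_max = np.inf
        else:
            raise ValueError(
                "radial runs need snapshot_lengths or an explicit L_max; "
                "an inflating ring need not fixate in finite length"
            )
    if engine == "fast":
        eng = _Engine(state, p, rng)
        snapshots = []
        for tgt in targets:
            if eng.L < tgt and eng.n_walls > 0:
                eng.advance(tgt)
            snapshots.append(eng.snapshot())
        if eng.n_walls > 0 and eng.L < L_max:
            eng.advance(L_max)
        ev_L, ev_kind, ev_lab = eng.event_arrays()
        return Trajectory(snapshots, tuple(targets), eng.snapshot(),
                          ev_L, ev_kind, ev_lab)
    if engine != "reference":
        raise ValueError(f"unknown engine {engine!r}")
    # slow path: repeated single hops through `step`
    snapshots = []
    events: list[CollisionEvent] = []
    ti = 0
    cur = state
    while True:
        while ti < len(targets) and cur.L >= targets[ti]:
            snapshots.append(cur.copy())
            ti += 1
        if cur.n_walls == 0 or cur.L >= L_max:
            break
        cur, ev = step(cur, p, rng)
        if ev is not None:
            events.append(ev)
    while ti < len(targets):
        snapshots.append(cur.copy())
        ti += 1
    ev_L = np.array([e.L_at for e in events])
    ev_kind = np.array(
        [0 if e.kind == "annihilation" else 1 for e in events], dtype=np.int8
    )
    ev_lab = np.full((len(events), 6), -1, dtype=np.int64)
    for m, e in enumerate(events):
        ev_lab[m, :4] = [e.consumed[0].left, e.consumed[0].right,
                         e.consumed[1].left, e.consumed[1].right]
        if e.produced is not None:
            ev_lab[m, 4:] = [e.produced.left, e.produced.right]
    traj = Trajectory(snapshots, tuple(targets), cur, ev_L, ev_kind, ev_lab)
    traj._events = events
    return traj


def replicate_rngs(base_seed: int, n_reps: int) -> list[np.random.Generator]:
    """Independent, order-stable per-replicate generators."""
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(base_seed).spawn(n_reps)]


def run_ensemble(
    p: SimParams,
    n_reps: int,
    base_seed: int,
    n_bins: int = 500,
    L_max: Optional[float] = None,
):
    """Run ``n_reps`` independent expansions and aggregate the observables.

    Replicate seeds are spawned deterministically from ``base_seed``, so the
    result is reproducible bit for bit for a given ``(p, n_reps,
    base_seed)``.  Returns ``(trajectories, EnsembleSummary)``.
    """
    from . import observables  # deferred: observables imports this module

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    validate_params(p)
    trajs = [run(p, rng, L_max=L_max) for rng in replicate_rngs(base_seed, n_reps)]
    summary = observables.summarize(trajs, p, n_bins=n_bins)
    return trajs, summary


# ---------------------------------------------------------------------------
# engine-backed probes


@dataclass
class WallMotionProbe:
    """Transverse displacement record of isolated walls on a linear front.

    ``x`` has shape ``(n_walls_total, n_records)``: displacement (length
    units, origin at the segment start) of each tracked wall at each
    recorded length; ``L_grid`` is the length expanded since the segment
    start.  Used to measure the diffusion constant ``Dw = a**2/(2*d)`` and
    the drift ``vw = a*r/d`` realised by the microscopic update rule.
    """

    L_grid: np.ndarray
    x: np.ndarray
    a: float
    d: float
    r: float

    def diffusion_estimate(self) -> tuple[float, float]:
        """(Dw, SE) from non-overlapping increments.

        Successive displacement increments of a wall are independent, so
        each gives an unbiased sample of ``2*Dw`` per unit length after the
        ensemble-mean drift is removed; pooling them over records and walls
        gives a tight estimate with a clean between-wall standard error.
        """
        dx = np.diff(self.x, axis=1, prepend=0.0)
        dL = np.diff(self.L_grid, prepend=0.0)
        c = dx - dx.mean(axis=0, keepdims=True)
        per_wall = np.mean(c * c / (2.0 * dL), axis=1)
        n = per_wall.size
        # undo the variance shrinkage from centring on the empirical mean
        per_wall = per_wall * n / (n - 1)
        return float(per_wall.mean()), float(per_wall.std(ddof=1) / np.sqrt(n))

    def variance_curve(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(L, Var(x), SE): between-wall displacement variance vs length."""
        var = self.x.var(axis=0, ddof=1)
        n = self.x.shape[0]
        se = var * np.sqrt(2.0 / (n - 1))
        return self.L_grid, var, se

    def drift_estimate(self) -> tuple[float, float]:
        """(vw, SE): per-wall final displacement over length expanded."""
        v = self.x[:, -1] / self.L_grid[-1]
        n = v.size
        return float(v.mean()), float(v.std(ddof=1) / np.sqrt(n))


def probe_wall_motion(
    n_wall_steps: int,
    n_reps: int,
    r: float = 0.0,
    a: float = 1.0,
    d: Optional[float] = None,
    n_records: int = 25,
    N0: int = 20000,
    base_seed: int = 0,
) -> WallMotionProbe:
    """Track two far-separated walls on a large linear ring with the engine.

    Each replicate holds a single sector (two walls, types ``01`` and
    ``10``) diametrically apart on a ring large enough that collisions are
    negligible over the run; each wall receives ``n_wall_steps`` hops on
    average.  With ``bias[1, 0] = r`` the ``10`` wall drifts at ``+vw`` and
    the ``01`` wall at ``-vw``; the latter's displacement is sign-flipped
    before pooling so every tracked wall drifts at ``+vw``.
    """
    d = a if d is None else d
    p = SimParams(
        N0=N0, q=2, init_fractions=(0.5, 0.5),
        bias=[[0.0, -r], [r, 0.0]], geometry="linear", a=a, d=d,
    )
    # total hops = 2 * n_wall_steps; L advances d/2 per hop
    L_total = n_wall_steps * d
    L_grid = L_total * np.arange(1, n_records + 1) / n_records
    R0 = p.R0
    x = np.empty((2 * n_reps, n_records))
    for rep, rng in enumerate(replicate_rngs(base_seed, n_reps)):
        state = FrontierState(
            np.array([0.0, np.pi]), np.array([1, 0]), R0, R0, 0.0, 0.0, "linear"
        )
        eng = _Engine(state, p, rng)
        prev = np.array([0.0, np.pi])
        unwrapped = np.zeros(2)
        for m, Lt in enumerate(L_grid):
            eng.advance(Lt)
            if eng.n_walls < 2:
                raise RuntimeError("probe walls collided; increase N0")
            snap = eng.snapshot()
            # identify walls by type: arc label right of the 01 wall is 1
            i01 = int(np.nonzero(snap.arc_labels == 1)[0][0])
            cur = np.array([snap.phi[i01], snap.phi[1 - i01]])
            delta = (cur - prev + np.pi) % TWO_PI - np.pi
            unwrapped += delta
            prev = cur
            x[2 * rep, m] = -unwrapped[0] * R0
            x[2 * rep + 1, m] = unwrapped[1] * R0
    return WallMotionProbe(L_grid, x, a, d, r)


@dataclass
class SectorTraces:
    """Angular width of single sectors on an inflating ring.

    ``widths[rep, m]`` is the sector's angular width at ``R_grid[m]``;
    ``alive[rep, m]`` is False from the record where the sector (or the
    background) was lost onward.  ``phi0`` is the common initial width.
    """

    R_grid: np.ndarray
    R0: float
    widths: np.ndarray
    alive: np.ndarray
    phi0: float
    vw: float
    Dw: float

    @property
    def n_lost(self) -> int:
        return int(np.sum(~self.alive[:, -1]))


def run_sector_ensemble(
    vw: float,
    N0: int,
    R_factors: Sequence[float],
    n_reps: int,
    base_seed: int = 0,
    a: float = 1.0,
    d: Optional[float] = None,
    phi0: float = 0.5 * np.pi,
) -> SectorTraces:
    """Simulate single sectors of a fitter strain on an inflating ring.

    Strain 1 (the sector, initial angular width ``phi0``) sweeps through
    strain 0 with wall velocity ``vw = a*r/d``; the frontier is recorded at
    radii ``R_factors * R0``.
    """
    d = a if d is None else d
    r = vw * d / a
    if abs(r) > 1:
        raise ValueError("requested vw needs |r| > 1; increase d or reduce vw")
    p = SimParams(
        N0=N0, q=2, init_fractions=(0.5, 0.5),
        bias=[[0.0, -r], [r, 0.0]], geometry="radial", a=a, d=d,
    )
    R0 = p.R0
    R_factors = np.asarray(R_factors, dtype=float)
    L_grid = (R_factors - 1.0) * R0  # radial geometry: L = R - R0
    widths = np.full((n_reps, R_factors.size), np.nan)
    alive = np.zeros((n_reps, R_factors.size), dtype=bool)
    for rep, rng in enumerate(replicate_rngs(base_seed, n_reps)):
        state = FrontierState(
            np.array([0.0, phi0]), np.array([1, 0]), R0, R0, 0.0, 0.0, "radial"
        )
        eng = _Engine(state, p, rng)
        for m, Lt in enumerate(L_grid):
            if eng.n_walls == 2:
                eng.advance(Lt)
            if eng.n_walls < 2:
                break
            snap = eng.snapshot()
            i01 = int(np.nonzero(snap.arc_labels == 1)[0][0])
            w = (snap.phi[1 - i01] - snap.phi[i01]) % TWO_PI
            widths[rep, m] = w
            alive[rep, m] = True
    Dw = a * a / (2.0 * d)
    return SectorTraces(R_factors * R0, R0, widths, alive, phi0, vw, Dw)
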