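"""Engine behaviour: initialisation, single hops, collisions, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sectorwalk.core import FrontierState, SimParams, WallType
from sectorwalk import simulator as sim


class _FixedUniforms:
    """Minimal rng stand-in yielding a scripted uniform stream."""

    def __init__(self, values):
        self._vals = list(values)

    def random(self, n=None):
        if n is None:
            return self._vals.pop(0)
        out = np.array([self._vals.pop(0) for _ in range(n)])
        return out


class TestInitFrontier:
    def test_alternating_labels_give_lattice_walls(self):
        p = SimParams(N0=4, q=2, init_fractions=(0.5, 0.5))
        st_ = sim.frontier_from_labels([0, 1, 0, 1], p)
        assert np.allclose(st_.phi, [0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert st_.n_walls == 4
        st_.validate()

    def test_single_strain_fixates_immediately(self, rng):
        p = SimParams(N0=50, q=1, init_fractions=(1.0,))
        st_ = sim.init_frontier(p, rng)
        assert st_.n_walls == 0
        assert st_.fixed_label == 0

    def test_iid_wall_count_matches_mismatch_probability(self):
        # P(adjacent labels differ) = 1 - sum f_i^2 = 2/3 for 3 equal strains
        p = SimParams(N0=1000, q=3, init_fractions=(1 / 3,) * 3)
        counts = [
            sim.init_frontier(p, np.random.default_rng(s)).n_walls
            for s in range(100)
        ]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / 10.0
        assert abs(mean - 1000 * 2 / 3) < 3 * se

    def test_exact_mode_places_rounded_counts(self, rng):
        p = SimParams(N0=10, q=3, init_fractions=(0.21, 0.33, 0.46),
                      init_mode="exact")
        labels = sim._draw_labels(p, rng)
        assert list(np.bincount(labels, minlength=3)) == [2, 3, 5]


def _two_wall_state(R0=100 / (2 * np.pi)):
    return FrontierState(np.array([0.0, np.pi]), np.array([1, 0]),
                         R0, R0, 0.0, 0.0, "radial")


class TestStep:
    def test_zero_wall_state_rejected(self, neutral_q2, rng):
        st_ = FrontierState(np.empty(0), np.empty(0), 10.0, 10.0, 0.0, 0.0,
                            "radial", fixed_label=0)
        with pytest.raises(ValueError, match="fixated"):
            sim.step(st_, neutral_q2, rng)

    def test_neutral_hop_direction_is_unbiased(self):
        # empirical rightward frequency over 1e5 single hops of one wall
        p = SimParams(N0=100000, q=2, init_fractions=(0.5, 0.5))
        st_ = _two_wall_state(R0=p.R0)
        rng = np.random.default_rng(0)
        right = 0
        n = 100000
        for _ in range(n):
            new, ev = sim.step(st_, p, rng)
            assert ev is None
            moved = np.setdiff1d(new.phi, st_.phi)
            old = np.setdiff1d(st_.phi, new.phi)
            right += ((moved - old + np.pi) % (2 * np.pi) - np.pi > 0)[0]
            st_ = new
        freq = right / n
        assert abs(freq - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_forced_annihilation_merges_to_fixation(self):
        p = SimParams(N0=100, q=2, init_fractions=(0.5, 0.5))
        dphi = 2 * np.pi / 100
        st_ = FrontierState(np.array([0.0, dphi]), np.array([1, 0]),
                            p.R0, p.R0, 0.0, 0.0, "radial")
        # wall 0 (type 01) hops right onto wall 1 (type 10): outer flanks 0 == 0
        new, ev = sim.step(st_, p, _FixedUniforms([0.0, 0.0]))
        assert ev is not None and ev.kind == "annihilation"
        assert new.n_walls == 0 and new.fixed_label == 0

    def test_forced_coalescence_produces_outer_wall(self):
        p = SimParams(N0=100, q=3, init_fractions=(1 / 3,) * 3)
        dphi = 2 * np.pi / 100
        st_ = FrontierState(np.array([0.0, dphi, np.pi]),
                            np.array([1, 2, 0]), p.R0, p.R0, 0.0, 0.0, "radial")
        # wall 0 is AB (0,1); wall 1 is BC (1,2); force wall 0 rightward
        new, ev = sim.step(st_, p, _FixedUniforms([0.0, 0.0]))
        assert ev is not None and ev.kind == "coalescence"
        assert ev.produced == WallType(0, 2)
        assert new.n_walls == 2
        new.validate()

    def test_biased_wall_mean_displacement(self):
        # engine-backed probe: drift per length expanded equals r for d = a
        probe = sim.probe_wall_motion(2000, 100, r=0.06, base_seed=11)
        v, se = probe.drift_estimate()
        assert abs(v - 0.06) < 3 * se


class TestRun:
    def test_single_strain_trajectory_is_inert(self):
        p = SimParams(N0=30, q=1, init_fractions=(1.0,),
                      snapshot_lengths=(1.0, 2.0))
        tr = sim.run(p, np.random.default_rng(0))
        assert tr.event_L.size == 0
        assert all(s.n_walls == 0 for s in tr.snapshots)

    def test_two_strains_only_annihilate(self, neutral_q2):
        tr = sim.run(neutral_q2, np.random.default_rng(3), L_max=8 * neutral_q2.R0)
        assert tr.event_L.size > 0
        assert np.all(tr.event_kind == 0)

    def test_wall_count_bookkeeping_identity(self, neutral_q3):
        rng = np.random.default_rng(5)
        w0 = sim.init_frontier(neutral_q3, np.random.default_rng(5)).n_walls
        tr = sim.run(neutral_q3, rng, L_max=5 * neutral_q3.R0)
        assert w0 - 2 * tr.n_annihilations - tr.n_coalescences \
            == tr.final_state.n_walls

    def test_events_nondecreasing_and_snapshots_coarsen(self):
        p = SimParams(N0=300, q=3, init_fractions=(1 / 3,) * 3,
                      snapshot_lengths=(1.0, 5.0, 20.0, 100.0))
        tr = sim.run(p, np.random.default_rng(8))
        assert np.all(np.diff(tr.event_L) >= 0)
        counts = [s.n_walls for s in tr.snapshots]
        assert counts == sorted(counts, reverse=True)
        for s in tr.snapshots:
            s.validate()

    def test_radial_run_requires_a_stopping_length(self, neutral_q2):
        with pytest.raises(ValueError, match="L_max"):
            sim.run(neutral_q2, np.random.default_rng(0))

    def test_reference_engine_matches_fast_engine_statistics(self):
        # same model, two independent code paths: compare collision totals
        p = SimParams(N0=120, q=3, init_fractions=(0.2, 0.3, 0.5))
        stats = {}
        for eng in ("fast", "reference"):
            A = C = walls = 0
            for rngs in sim.replicate_rngs(42, 40):
                tr = sim.run(p, rngs, L_max=4 * p.R0, engine=eng)
                A += tr.n_annihilations
                C += tr.n_coalescences
                walls += tr.final_state.n_walls
            stats[eng] = (A, C, walls)
        Af, Cf, _ = stats["fast"]
        Ar, Cr, _ = stats["reference"]
        for xf, xr in [(Af, Ar), (Cf, Cr)]:
            assert abs(xf - xr) < 4 * np.sqrt(max(xf, xr))

    def test_ensemble_is_deterministic(self, neutral_q3):
        p = SimParams(N0=100, q=3, init_fractions=(1 / 3,) * 3,
                      snapshot_lengths=(5.0, 20.0))
        _, s1 = sim.run_ensemble(p, 5, base_seed=9)
        _, s2 = sim.run_ensemble(p, 5, base_seed=9)
        assert np.array_equal(s1.Fij, s2.Fij)
        assert np.array_equal(s1.cum_annihilations, s2.cum_annihilations)

    def test_single_replicate_reports_no_standard_errors(self):
        p = SimParams(N0=100, q=2, init_fractions=(0.5, 0.5),
                      snapshot_lengths=(5.0,))
        _, s = sim.run_ensemble(p, 1, base_seed=0)
        assert s.Fi_se is None and s.H_se is None


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000),
       q=st.integers(2, 4),
       n0=st.integers(20, 150))
def test_arc_widths_always_sum_to_full_circle(seed, q, n0):
    """Conservation of angular measure after arbitrarily many steps."""
    p = SimParams(N0=n0, q=q, init_fractions=(1 / q,) * q,
                  snapshot_lengths=(0.5 * n0 / (2 * np.pi),))
    tr = sim.run(p, np.random.default_rng(seed), L_max=2 * p.R0)
    for state in tr.snapshots + [tr.final_state]:
        if state.n_walls:
            assert abs(state.arc_widths().sum() - 2 * np.pi) < 1e-9
            state.validate()


class TestMicroscopicLaws:
    def test_neutral_wall_diffusion_constant(self):
        # Var(x) grows as 2 Dw L with Dw = a^2/(2d)
        probe = sim.probe_wall_motion(3000, 120, r=0.0, base_seed=2)
        Dw, se = probe.diffusion_estimate()
        assert abs(Dw - 0.5) < 4 * se
        L, var, var_se = probe.variance_curve()
        assert abs(var[-1] - 2 * 0.5 * L[-1]) < 3 * var_se[-1]

    def test_general_d_rescales_diffusion(self):
        probe = sim.probe_wall_motion(2000, 80, r=0.0, d=2.0, base_seed=6)
        Dw, se = probe.diffusion_estimate()
        assert abs(Dw - 0.25) < 4 * se

    def test_sector_traces_absorb_and_report_losses(self):
        tr = sim.run_sector_ensemble(0.0, 200, np.linspace(1, 6, 8), 200,
                                     base_seed=4, phi0=0.15)
        assert tr.n_lost > 0
        # widths frozen to NaN after loss
        lost = ~tr.alive
        assert np.all(np.isnan(tr.widths[lost]))
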