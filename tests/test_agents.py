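import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mslesion import (
    AgentPopulation,
    SimulationConfig,
    antigen_presentation,
    apply_boundaries,
    apply_death,
    attempt_bbb_cross,
    biased_move_probs,
    build_region_map,
    death_probability,
    init_fields,
    nearest_eligible_myelin,
    seed_pvms,
    spawn_primed,
    unbiased_step,
)
from mslesion.agents import BiasResult, REMOVE
from mslesion._kernels import nearest_eligible


class TestSpawning:
    def test_mean_spawn_rates_match_relapse_and_remission(self, rng):
        cfg = SimulationConfig()
        n_rel = sum(len(spawn_primed(cfg, True, rng)) for _ in range(4000))
        n_rem = sum(len(spawn_primed(cfg, False, rng)) for _ in range(4000))
        # 900 blood sites at rho_R = 0.0025 / rho_NR = 0.0002
        assert n_rel / 4000 == pytest.approx(2.25, rel=0.1)
        assert n_rem / 4000 == pytest.approx(0.18, rel=0.25)

    def test_zero_rate_never_spawns(self, rng):
        cfg = SimulationConfig(rho_R=0.0, rho_NR=0.0)
        assert len(spawn_primed(cfg, True, rng)) == 0

    def test_spawns_lie_in_blood(self, rng):
        cfg = SimulationConfig(rho_R=0.5)
        pos = spawn_primed(cfg, True, rng)
        assert np.all(pos[:, 0] >= 1) and np.all(pos[:, 0] <= 3)
        assert np.all(pos[:, 1] >= 1) and np.all(pos[:, 1] <= 300)


class TestPVMs:
    def test_seeding_in_pvs(self, rng):
        cfg = SimulationConfig()
        region = build_region_map(cfg)
        pos = seed_pvms(cfg, region, rng)
        assert len(pos) == 45
        assert set(pos[:, 0]).issubset({4, 5, 6, 7, 8})
        # without replacement: all sites distinct
        assert len({(c, r) for c, r in pos}) == 45

    def test_capacity_error(self, rng):
        cfg = SimulationConfig(pvm_count=1501)
        with pytest.raises(ValueError):
            seed_pvms(cfg, build_region_map(cfg), rng)


class TestUnbiasedWalk:
    def test_direction_frequencies_are_quarter_each(self, rng):
        counts = {}
        for _ in range(8000):
            step = unbiased_step((10, 10), rng)
            counts[step] = counts.get(step, 0) + 1
        assert set(counts) == {(11, 10), (9, 10), (10, 11), (10, 9)}
        for v in counts.values():
            assert v / 8000 == pytest.approx(0.25, abs=0.02)

    def test_proposal_is_von_neumann_neighbour(self, rng):
        for _ in range(50):
            c, r = unbiased_step((5, 5), rng)
            assert abs(c - 5) + abs(r - 5) == 1


def _brute_nearest(pos, field):
    """Independent oracle: exhaustive scan with the lowest-row/-column tie rule."""
    col0, row0 = pos
    best = None
    h, w = field.state.shape
    for r in range(h):
        for c in range(w):
            if field.state[r, c] >= 2:
                d2 = (r + 1 - row0) ** 2 + (c + field.col_offset - col0) ** 2
                key = (d2, r, c)
                if best is None or key < best:
                    best = key
    return best


class TestNearestMyelin:
    def test_three_four_five_triangle(self):
        cfg = SimulationConfig()
        field, _ = init_fields(cfg)
        field.state[:] = 1
        field.state[5, 4] = 3   # lattice (13, 6)
        res = nearest_eligible_myelin((10, 10), field)
        assert res.target == (13, 6)
        assert res.distance == pytest.approx(5.0)
        assert res.s_bias == pytest.approx(0.5 * math.exp(-0.033 * 5.0))

    def test_equidistant_tie_prefers_lower_row(self):
        cfg = SimulationConfig()
        field, _ = init_fields(cfg)
        field.state[:] = 1
        field.state[10, 5], field.state[4, 5] = 5, 5  # rows 11 and 5, same col
        res = nearest_eligible_myelin((14, 8), field)  # equidistant (dy = +-3)
        assert res.target == (14, 5)

    def test_fully_demyelinated_returns_none(self):
        field, _ = init_fields(SimulationConfig())
        field.state[:] = 1
        assert nearest_eligible_myelin((10, 10), field) is None

    def test_kernel_matches_brute_force_oracle(self, rng):
        cfg = SimulationConfig(lattice_height=25, parenchyma_width=20,
                               oligo_block=5, lattice_width=28)
        for _ in range(25):
            field, _ = init_fields(cfg)
            field.state[:] = rng.integers(1, 6, size=field.state.shape)
            col0 = int(rng.integers(1, 29))
            row0 = int(rng.integers(1, 26))
            res = nearest_eligible_myelin((col0, row0), field)
            expect = _brute_nearest((col0, row0), field)
            if expect is None:
                assert res is None
            else:
                d2, r, c = expect
                assert res.target == (c + field.col_offset, r + 1)
                assert res.distance == pytest.approx(math.sqrt(d2))

    def test_kernel_batch_against_oracle_sparse(self, rng):
        # sparse fields exercise the row-band search far from the agent
        mask = np.zeros((40, 30), bool)
        mask[rng.random((40, 30)) < 0.01] = True
        mask[35, 28] = True
        rows = rng.integers(0, 40, 15)
        cols = rng.integers(-8, 30, 15)
        tr, tc, d2, found = nearest_eligible(rows, cols, mask)
        er, ec = np.nonzero(mask)
        for i in range(15):
            dd = (er - rows[i]) ** 2 + (ec - cols[i]) ** 2
            j = int(np.argmin(dd))   # row-major argmin = same tie rule
            assert found[i]
            assert (tr[i], tc[i], d2[i]) == (er[j], ec[j], dd[j])


class TestBiasedProbabilities:
    def test_target_due_east_with_full_bias(self):
        # k -> 0 and beta = 0.5 give s_bias = 0.5; the favoured x direction
        # absorbs all of it, the zero-weight y axis keeps north at 0.25
        bias = BiasResult(s_bias=0.5, target=(20, 10), distance=10.0)
        p = biased_move_probs((10, 10), bias)
        n, s, e, w = p
        assert e == pytest.approx(0.75)
        assert w == pytest.approx(0.0)
        assert sorted([n, s]) == pytest.approx([0.0, 0.25])
        assert p.sum() == pytest.approx(1.0)

    def test_south_east_target_three_four_five(self):
        d = 5.0
        s_bias = 0.5 * math.exp(-0.005 * d)
        bias = BiasResult(s_bias=s_bias, target=(13, 14), distance=d)
        p = biased_move_probs((10, 10), bias)  # dx=3, dy=4
        n, s, e, w = p
        assert e == pytest.approx(0.25 + s_bias * 3 / 7)
        assert s == pytest.approx(0.25 + s_bias * 4 / 7)
        assert n == pytest.approx(0.25 - s_bias / 2)
        assert w == pytest.approx(0.25 - s_bias / 2)
        assert e == pytest.approx(0.459, abs=0.001)
        assert s == pytest.approx(0.529, abs=0.001)
        assert p.sum() == pytest.approx(1.0)

    def test_zero_beta_reduces_to_unbiased(self):
        bias = BiasResult(s_bias=0.0, target=(13, 14), distance=5.0)
        assert biased_move_probs((10, 10), bias) == pytest.approx([0.25] * 4)

    def test_zero_distance_is_an_error(self):
        bias = BiasResult(s_bias=0.5, target=(10, 10), distance=0.0)
        with pytest.raises(ValueError):
            biased_move_probs((10, 10), bias)

    def test_beyond_half_beta_clamps_and_renormalises(self):
        bias = BiasResult(s_bias=0.7, target=(20, 10), distance=1.0)
        p = biased_move_probs((10, 10), bias)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("dx,dy", [(3, 4), (-2, 5), (7, -1), (-3, -3), (0, 4), (6, 0)])
    def test_probabilities_valid_for_any_direction(self, dx, dy):
        d = math.hypot(dx, dy)
        bias = BiasResult(s_bias=0.5 * math.exp(-0.005 * d),
                          target=(10 + dx, 10 + dy), distance=d)
        p = biased_move_probs((10, 10), bias)
        assert np.all(p >= 0) and np.all(p <= 1)
        assert p.sum() == pytest.approx(1.0)


class TestBiasedWalkProperties:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(dx=st.integers(-99, 99), dy=st.integers(-299, 299),
           beta=st.floats(0.0, 0.75))
    def test_probabilities_valid_and_pull_toward_target(self, dx, dy, beta):
        if dx == 0 and dy == 0:
            return
        d = math.hypot(dx, dy)
        s = beta * math.exp(-0.033 * d)
        p = biased_move_probs((50, 400), BiasResult(s, (50 + dx, 400 + dy), d))
        assert np.all(p >= 0) and np.all(p <= 1)
        assert p.sum() == pytest.approx(1.0)
        n, so, e, w = p
        if dx > 0:
            assert e >= w
        elif dx < 0:
            assert w >= e
        if dy > 0:
            assert so >= n
        elif dy < 0:
            assert n >= so

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), density=st.floats(0.005, 0.9))
    def test_nearest_site_matches_row_major_argmin(self, seed, density):
        """The kernel's tie rule equals the first minimum in row-major order."""
        rng = np.random.default_rng(seed)
        mask = rng.random((25, 18)) < density
        r0 = int(rng.integers(0, 25))
        c0 = int(rng.integers(-6, 18))
        tr, tc, d2, found = nearest_eligible(
            np.array([r0]), np.array([c0]), mask)
        er, ec = np.nonzero(mask)
        if er.size == 0:
            assert not found[0]
            return
        dd = (er - r0) ** 2 + (ec - c0) ** 2
        j = int(np.argmin(dd))
        assert (tr[0], tc[0], d2[0]) == (er[j], ec[j], dd[j])


class TestBBBCrossing:
    def test_certain_and_impossible_crossings(self, rng):
        cfg = SimulationConfig(b_R=1.0, b_L=0.0)
        assert all(attempt_bbb_cross("E", cfg, rng) for _ in range(20))
        assert not any(attempt_bbb_cross("W", cfg, rng) for _ in range(20))

    def test_long_run_crossing_frequency(self, rng):
        cfg = SimulationConfig(b_R=0.1)
        freq = np.mean([attempt_bbb_cross("E", cfg, rng) for _ in range(5000)])
        assert freq == pytest.approx(0.1, abs=0.02)

    def test_vertical_direction_rejected(self, rng):
        with pytest.raises(ValueError):
            attempt_bbb_cross("N", SimulationConfig(), rng)


class TestBoundaries:
    def test_periodic_wrap_top_and_bottom(self, small_region):
        assert apply_boundaries((10, 30), (10, 31), "tcell", small_region) == (10, 1)
        assert apply_boundaries((10, 1), (10, 0), "tcell", small_region) == (10, 30)

    def test_right_edge_removes(self, small_region):
        assert apply_boundaries((28, 5), (29, 5), "tcell", small_region) is REMOVE

    def test_left_edge_reflects(self, small_region):
        assert apply_boundaries((1, 5), (0, 5), "tcell", small_region) == (1, 5)

    def test_pvm_confined_to_pvs(self, small_region):
        assert apply_boundaries((8, 5), (9, 5), "pvm", small_region) == (8, 5)
        assert apply_boundaries((4, 5), (3, 5), "pvm", small_region) == (4, 5)
        assert apply_boundaries((5, 5), (6, 5), "pvm", small_region) == (6, 5)


class TestAntigenPresentation:
    def test_colocated_primed_converts(self):
        pop = AgentPopulation(
            primed=np.array([[5, 7]]), pvms=np.array([[5, 7]]),
            reactivated=np.empty((0, 2), np.int64), engaged=np.empty(0, bool))
        pop = antigen_presentation(pop)
        assert len(pop.primed) == 0
        assert pop.reactivated.tolist() == [[5, 7]]
        assert len(pop.pvms) == 1    # the PVM persists

    def test_no_colocation_no_conversion(self):
        pop = AgentPopulation(primed=np.array([[5, 7]]), pvms=np.array([[6, 7]]))
        pop = antigen_presentation(pop)
        assert len(pop.primed) == 1 and len(pop.reactivated) == 0

    def test_two_primed_one_pvm_site_gives_two_reactivated(self):
        pop = AgentPopulation(
            primed=np.array([[5, 7], [5, 7], [4, 2]]), pvms=np.array([[5, 7]]))
        pop = antigen_presentation(pop)
        assert len(pop.reactivated) == 2
        assert pop.primed.tolist() == [[4, 2]]


class TestDeath:
    def test_half_life_survival_over_48h(self, rng):
        cfg = SimulationConfig()
        pop = AgentPopulation(primed=np.zeros((10000, 2), np.int64))
        for _ in range(144):
            pop = apply_death(pop, cfg, rng)
        # (1 - 0.0049)^144 ~ 0.493: the 48 h half-life
        assert len(pop.primed) / 10000 == pytest.approx(0.493, abs=0.02)

    def test_extreme_rates(self, rng):
        pop = AgentPopulation(primed=np.zeros((50, 2), np.int64),
                              reactivated=np.zeros((50, 2), np.int64),
                              engaged=np.zeros(50, bool))
        pop = apply_death(pop, SimulationConfig(rho_d=0.0), rng)
        assert len(pop.primed) == len(pop.reactivated) == 50
        pop = apply_death(pop, SimulationConfig(rho_d=1.0), rng)
        assert len(pop.primed) == len(pop.reactivated) == 0

    def test_death_probability_closed_form(self):
        # 48 h half-life -> 0.35 / day -> 0.0049 per 20-minute step (2 s.f.)
        assert death_probability(0.35, 20.0) == pytest.approx(0.0049, abs=5e-5)
        assert float(f"{death_probability():.2g}") == 0.0049
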