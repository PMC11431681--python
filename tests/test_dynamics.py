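import numpy as np
import pytest

from natind import (
    SimulationConfig,
    Spring,
    SpringNetwork,
    disturb,
    generate_random_network,
    net_forces,
    potential_energy,
    settle,
)
from natind.dynamics import resolve_tolerance
from natind.errors import DegenerateGeometryError


def _rigid_motion(positions, angle, shift, rng=None):
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return positions @ rot.T + shift


class TestPotentialEnergy:
    def test_zero_when_all_springs_at_natural_length(self):
        pos = np.array([[0.0, 0.0], [10.0, 0.0]])
        net = SpringNetwork(pos, [Spring(0, 1, 10.0, 10.0)])
        assert potential_energy(net) == 0.0

    def test_single_stretched_spring(self):
        pos = np.array([[0.0, 0.0], [11.0, 0.0]])
        net = SpringNetwork(pos, [Spring(0, 1, 10.0, 10.0)])
        assert potential_energy(net) == pytest.approx(5.0)  # 0.5*10*1^2

    def test_matches_per_spring_sum(self, small_net):
        expected = 0.0
        for s in small_net.springs:
            r = np.linalg.norm(small_net.positions[s.i] - small_net.positions[s.j])
            expected += 0.5 * s.stiffness * (r - s.natural_length) ** 2
        assert potential_energy(small_net) == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_rigid_motions(self, small_net, rng):
        v0 = potential_energy(small_net)
        moved = small_net.copy()
        moved.positions = _rigid_motion(
            small_net.positions, rng.uniform(0, 2 * np.pi), rng.uniform(-50, 50, 2)
        )
        assert potential_energy(moved) == pytest.approx(v0, rel=1e-9)

    def test_layer_selection_partitions_total(self):
        pos = np.array([[0.0, 0.0], [12.0, 0.0]])
        net = SpringNetwork(
            pos,
            [Spring(0, 1, 10.0, 10.0), Spring(0, 1, 1.0, 5.0, plastic=True)],
        )
        total = potential_energy(net)
        assert potential_energy(net, "elastic") + potential_energy(
            net, "plastic"
        ) == pytest.approx(total)


class TestNetForces:
    def test_zero_at_natural_length(self):
        pos = np.array([[0.0, 0.0], [10.0, 0.0]])
        net = SpringNetwork(pos, [Spring(0, 1, 10.0, 10.0)])
        assert np.allclose(net_forces(net), 0.0)

    def test_stretched_attracts_compressed_repels(self):
        stretched = SpringNetwork(
            np.array([[0.0, 0.0], [12.0, 0.0]]), [Spring(0, 1, 10.0, 10.0)]
        )
        f = net_forces(stretched)
        assert f[0, 0] > 0 and f[1, 0] < 0  # pulled toward each other
        compressed = SpringNetwork(
            np.array([[0.0, 0.0], [8.0, 0.0]]), [Spring(0, 1, 10.0, 10.0)]
        )
        f = net_forces(compressed)
        assert f[0, 0] < 0 and f[1, 0] > 0  # pushed apart

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_total_force_vanishes(self, seed):
        net = generate_random_network(20, 0.6, seed=seed)
        f = net_forces(net)
        typical = np.abs(f).max()
        assert np.abs(f.sum(axis=0)).max() < 1e-10 * typical

    def test_newtons_third_law_pairwise(self):
        pos = np.array([[0.0, 0.0], [3.0, 4.0]])
        net = SpringNetwork(pos, [Spring(0, 1, 2.0, 1.0)])
        f = net_forces(net)
        assert np.allclose(f[0], -f[1])

    def test_coincident_masses_raise(self):
        pos = np.array([[1.0, 1.0], [1.0, 1.0]])
        net = SpringNetwork(pos, [Spring(0, 1, 1.0, 1.0)])
        with pytest.raises(DegenerateGeometryError):
            net_forces(net)


class TestSettle:
    def test_settled_network_is_a_fixed_point(self, small_net, config):
        first = settle(small_net, config)
        before = small_net.positions.copy()
        second = settle(small_net, config)
        assert second.settle_steps <= 1
        assert np.abs(small_net.positions - before).max() < 1e-6
        assert second.energy_current == pytest.approx(first.energy_current)

    def test_equilibrium_is_a_critical_point(self, small_net, config):
        settle(small_net, config)
        tol = resolve_tolerance(small_net, config)
        f = net_forces(small_net)
        assert np.hypot(f[:, 0], f[:, 1]).max() < tol

    def test_two_body_closed_form_relaxation(self):
        """Separation of one overdamped spring decays as
        l + (r0 - l) exp(-2 k t / gamma), checked at 5 times to 1e-4."""
        k, l, r0, gamma = 10.0, 10.0, 15.0, 1.0
        h = 1e-5
        net = SpringNetwork(
            np.array([[0.0, 0.0], [r0, 0.0]]), [Spring(0, 1, k, l)]
        )
        cfg = SimulationConfig(
            damping=gamma, step_size=h, equilibrium_tolerance=1e-300,
            max_displacement=1e9,
        )
        t = 0.0
        for _ in range(5):
            n_steps = 2000
            cfg = cfg.replace(max_settle_steps=n_steps)
            rec = settle(net, cfg)
            assert rec.settle_steps == n_steps
            t += n_steps * h
            expected = l + (r0 - l) * np.exp(-2 * k * t / gamma)
            assert net.spring_separations()[0] == pytest.approx(expected, rel=1e-4)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_energy_is_nonincreasing_along_trajectory(self, seed, config):
        net = generate_random_network(12, 0.8, seed=seed)
        rec = settle(net, config, record_trajectory=True)
        v = rec.energy_trace
        assert v is not None and v.size > 10
        diffs = np.diff(v)
        assert np.all(diffs <= 1e-12 * (np.abs(v[:-1]) + 1.0))

    def test_frame_invariant_attractor(self, config, rng):
        net = generate_random_network(10, 0.9, seed=6)
        start = net.positions.copy()
        rec = settle(net, config)
        moved = generate_random_network(10, 0.9, seed=6)
        moved.positions = _rigid_motion(start, 0.7, np.array([5.0, -3.0]))
        rec2 = settle(moved, config)
        scale = np.linalg.norm(rec.distance_vector)
        assert (
            np.linalg.norm(rec.distance_vector - rec2.distance_vector) < 1e-6 * scale
        )

    def test_nonconvergence_is_flagged_not_fatal(self, small_net):
        cfg = SimulationConfig(max_settle_steps=3, seed=0)
        disturb(small_net, cfg, np.random.default_rng(0))
        rec = settle(small_net, cfg)
        assert not rec.converged
        assert rec.settle_steps == 3


class TestDisturb:
    def test_springs_untouched(self, small_net, config, rng):
        before_l = small_net.natural_length.copy()
        before_k = small_net.stiffness.copy()
        disturb(small_net, config, rng)
        assert np.array_equal(small_net.natural_length, before_l)
        assert np.array_equal(small_net.stiffness, before_k)

    def test_deterministic_under_seed(self, small_net, config):
        a = disturb(small_net.copy(), config, np.random.default_rng(5)).positions
        b = disturb(small_net.copy(), config, np.random.default_rng(5)).positions
        assert np.array_equal(a, b)

    def test_energy_far_above_settled(self, small_net, config, rng):
        settle(small_net, config)
        settled = potential_energy(small_net)
        disturb(small_net, config, rng)
        assert potential_energy(small_net) > 10 * max(settled, 1.0)

    def test_anchors_never_move(self, config, rng):
        from natind import generate_spinglass_problem

        _, combined = generate_spinglass_problem(6, 0.5, seed=1)
        anchors_before = combined.positions[~combined.mobile].copy()
        disturb(combined, config, rng)
        assert np.array_equal(combined.positions[~combined.mobile], anchors_before)
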