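import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from natind import (
    EquilibriumRecord,
    SimulationConfig,
    binarised_energy,
    cluster_attractors,
    generate_spinglass_problem,
    generate_two_layer_problem,
    neutrality_check,
    pca_embed,
    potential_energy,
    resettle_energy,
    settle,
    std_score,
)
from natind.errors import AssayError, ContractError


def _rec(vec, energy=1.0, positions=None):
    vec = np.asarray(vec, dtype=float)
    return EquilibriumRecord(
        reset_index=0,
        positions=positions if positions is not None else np.zeros((2, 2)),
        distance_vector=vec,
        energy_current=energy,
    )


class TestResettleEnergy:
    def test_pure_and_repeatable(self, small_net, config, rng):
        original = small_net.copy()
        positions = rng.uniform(0, 30, size=small_net.positions.shape)
        l_before = small_net.natural_length.copy()
        e1 = resettle_energy(small_net, positions, config)
        e2 = resettle_energy(small_net, positions, config)
        assert e1 == e2
        assert np.array_equal(small_net.natural_length, l_before)
        assert np.array_equal(small_net.positions, original.positions)

    def test_fixed_point_returns_own_energy(self, small_net, config):
        rec = settle(small_net, config)
        e = resettle_energy(small_net, rec.positions, config)
        assert e == pytest.approx(rec.energy_current, rel=1e-6)

    def test_never_exceeds_unrelaxed_energy(self, small_net, config, rng):
        positions = rng.uniform(0, 30, size=small_net.positions.shape)
        probe = small_net.copy()
        probe.positions[:] = positions
        v_raw = potential_energy(probe)
        assert resettle_energy(small_net, positions, config) <= v_raw


class TestPCAEmbed:
    def test_needs_three_records(self):
        with pytest.raises(AssayError):
            pca_embed([_rec([1.0, 2.0])] * 2)

    def test_identical_records_embed_at_origin(self):
        emb = pca_embed([_rec([1.0, 2.0, 3.0])] * 5)
        assert np.allclose(emb.coords, 0.0)

    def test_rigid_motion_invariance(self, small_net, config, rng):
        """The embedding is built on pairwise distances, so rigidly moving
        every configuration leaves the coordinates unchanged."""
        from scipy.spatial.distance import pdist

        recs = []
        moved = []
        for _ in range(6):
            pos = rng.uniform(0, 30, size=(8, 2))
            recs.append(_rec(pdist(pos)))
            ang = rng.uniform(0, 2 * np.pi)
            rot = np.array(
                [[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]
            )
            moved.append(_rec(pdist(pos @ rot.T + rng.uniform(-9, 9, 2))))
        a = pca_embed(recs)
        b = a.transform(moved)
        assert np.allclose(a.coords, b, atol=1e-6)

    def test_projects_other_records_through_fitted_transform(self):
        base = [_rec([float(i), 0.0]) for i in range(5)]
        emb = pca_embed([_rec([10.0, 0.0])], fit_records=base)
        assert emb.coords.shape == (1, 2)
        assert emb.explained_variance_ratio[0] == pytest.approx(1.0)


class TestClusterAttractors:
    def test_identical_records_form_one_cluster(self):
        res = cluster_attractors([_rec([5.0, 5.0])] * 4)
        assert res.n_clusters == 1
        assert res.counts.tolist() == [4]

    def test_two_separated_configurations(self):
        recs = [_rec([0.0, 0.0, 1.0])] * 5 + [_rec([10.0, 10.0, 10.0])] * 5
        res = cluster_attractors(recs)
        assert res.n_clusters == 2
        assert res.counts.tolist() == [5, 5]
        assert res.labels[:5].tolist() == [0] * 5

    def test_matches_threshold_graph_components(self, rng):
        """Independent oracle: single-linkage clusters are exactly the
        connected components of the pairwise threshold graph (union-find)."""
        vecs = [rng.uniform(0, 10, size=4) for _ in range(30)]
        recs = [_rec(v) for v in vecs]
        res = cluster_attractors(recs, tol=0.25)
        parent = list(range(30))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i in range(30):
            for j in range(i + 1, 30):
                if np.linalg.norm(vecs[i] - vecs[j]) <= res.threshold:
                    parent[find(i)] = find(j)
        roots = [find(i) for i in range(30)]
        oracle = np.unique(roots, return_inverse=True)[1]
        same_oracle = oracle[:, None] == oracle[None, :]
        same_ours = res.labels[:, None] == res.labels[None, :]
        assert np.array_equal(same_oracle, same_ours)


class TestStdScore:
    def test_constructed_example(self):
        baseline = np.exp([0.0, 1.0, 2.0])
        assert std_score(baseline, np.exp(-2.4)) == pytest.approx(3.4)

    def test_zero_when_learned_equals_mean(self):
        baseline = np.exp([0.0, 1.0, 2.0])
        assert std_score(baseline, np.exp(1.0)) == pytest.approx(0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_invariant_under_positive_rescaling(self, scale):
        baseline = np.array([2.0, 3.0, 7.0, 11.0])
        s0 = std_score(baseline, 1.5)
        s1 = std_score(baseline * scale, 1.5 * scale)
        assert s1 == pytest.approx(s0, rel=1e-9)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(AssayError):
            std_score(np.array([2.0, 2.0, 2.0]), 1.0)

    def test_plain_scale_for_signed_energies(self):
        baseline = np.array([0.0, -2.0, -4.0])
        assert std_score(baseline, -6.0, log=False) == pytest.approx(2.0)


class TestNeutralityCheck:
    def test_pristine_learning_layer_is_initially_neutral(self):
        """Adding the weak unlearned L-layer must not distort the P-spring
        equilibrium energy distribution (small KS statistic)."""
        problem, combined = generate_two_layer_problem(100, seed=8)
        cfg = SimulationConfig(seed=8)
        res = neutrality_check(problem, combined, cfg, n_samples=40)
        assert res.ks_statistic < 0.3

    def test_strong_learning_layer_breaks_neutrality(self):
        """Sanity inversion: an L-layer 10x stiffer than the problem springs
        visibly displaces the start-by-start resettled energies."""
        problem, combined = generate_two_layer_problem(100, seed=8)
        cfg = SimulationConfig(seed=8)
        neutral = neutrality_check(problem, combined, cfg, n_samples=40)
        broken_net = combined.copy()
        broken_net.stiffness[broken_net.plastic] = 10.0
        broken = neutrality_check(problem, broken_net, cfg, n_samples=40)
        assert broken.paired_median_abs_diff > 2 * neutral.paired_median_abs_diff

    def test_vanishing_learning_layer_is_exactly_neutral(self):
        """kL -> 0 limit: samples A and B coincide start by start."""
        problem, combined = generate_two_layer_problem(20, seed=9)
        weak = combined.copy()
        weak.stiffness[weak.plastic] = 1e-12
        cfg = SimulationConfig(seed=9)
        res = neutrality_check(problem, weak, cfg, n_samples=10)
        assert np.allclose(res.energies_p_only, res.energies_resettled, rtol=1e-6)


class TestBinarisedEnergy:
    def test_two_spin_ferromagnet(self):
        problem, _ = generate_spinglass_problem(2, 1.0, coupling_values=(1.0,), seed=0)
        pos = problem.p_springs.positions.copy()
        pos[problem.variables, 0] = (0.7, 1.2)
        spins, e = binarised_energy(problem, pos)
        assert spins.tolist() == [1, 1]
        assert e == -1.0

    def test_global_spin_flip_leaves_energy_unchanged(self):
        problem, _ = generate_spinglass_problem(8, 0.6, seed=5)
        pos = problem.p_springs.positions.copy()
        _, e = binarised_energy(problem, pos)
        pos[problem.variables, 0] *= -1
        _, e_flipped = binarised_energy(problem, pos)
        assert e_flipped == e

    def test_requires_couplings(self, small_net):
        from natind import ProblemInstance

        plain = ProblemInstance(
            generate_two_layer_problem(10, seed=0)[0].p_springs
        )
        with pytest.raises(ContractError):
            binarised_energy(plain, plain.p_springs.positions)
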