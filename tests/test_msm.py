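"""MSM estimation, spectra, PCCA+, CK, TPT and representative selection."""

import numpy as np
import pytest

from oracles import simulate_first_passage, representative_bruteforce, quaternion_rmsd
from condyn.trajgen import ChainSpec, sample_markov_chain
from condyn.msm import (ck_test, cluster_microstates, count_transitions,
                        estimate_transition_matrix, implied_timescales,
                        pcca_plus, select_representative, timescales_from_matrix,
                        tpt_analysis)


@pytest.fixture(scope="module")
def two_state_chain():
    T = np.array([[0.95, 0.05], [0.10, 0.90]])
    return T, sample_markov_chain(ChainSpec(T, 300_000, seed=21))


class TestClustering:
    def test_separated_blobs_recovered(self, rng):
        a = rng.standard_normal((100, 2))
        b = rng.standard_normal((120, 2)) + 50.0
        res = cluster_microstates(np.vstack([a, b]), k=2, seed=0)
        assert len(set(res.labels[:100])) == 1
        assert len(set(res.labels[100:])) == 1
        assert res.labels[0] != res.labels[-1]

    def test_k_equals_frames_zero_inertia(self, rng):
        X = rng.standard_normal((30, 2))
        res = cluster_microstates(X, k=30, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-9)

    def test_beats_random_labelings(self, rng):
        X = rng.standard_normal((200, 2))
        res = cluster_microstates(X, k=5, seed=0)
        for _ in range(50):
            labels = rng.integers(0, 5, 200)
            inertia = sum(np.sum((X[labels == c] - X[labels == c].mean(axis=0)) ** 2)
                          for c in range(5) if np.any(labels == c))
            assert res.inertia <= inertia + 1e-9

    def test_k_exceeding_frames_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_microstates(rng.standard_normal((10, 2)), k=11)


class TestCounting:
    def test_hand_countable_sequence(self):
        C = count_transitions(np.array([0, 1, 0, 1]), lag=1)
        assert C.tolist() == [[0, 2], [1, 0]]

    def test_lag_equal_length_minus_one(self):
        C = count_transitions(np.array([0, 0, 0, 1]), lag=3)
        assert C.sum() == 1 and C[0, 1] == 1

    def test_sliding_vs_strided_convention(self):
        seq = np.array([0, 0, 1, 1])
        sliding = count_transitions(seq, lag=2, sliding=True)
        strided = count_transitions(seq, lag=2, sliding=False)
        assert sliding.tolist() == [[0, 2], [0, 0]]   # (s0,s2), (s1,s3)
        assert strided.tolist() == [[0, 1], [0, 0]]   # (s0,s2) only

    def test_counts_never_cross_trajectory_boundaries(self):
        parts = [np.array([0, 0, 0]), np.array([1, 1, 1])]
        C = count_transitions(parts, lag=1)
        assert C[0, 1] == 0 and C[1, 0] == 0

    def test_overlong_lag_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            count_transitions(np.array([0, 1]), lag=5)


class TestEstimation:
    def test_row_normalization_example(self):
        C = np.array([[9, 1], [1, 9]])
        model = estimate_transition_matrix(C, reversible=False)
        assert np.allclose(model.transition_matrix, [[0.9, 0.1], [0.1, 0.9]])

    def test_symmetric_counts_reversible_equals_nonreversible(self):
        C = np.array([[40, 6, 2], [6, 30, 5], [2, 5, 50]])
        rev = estimate_transition_matrix(C, reversible=True)
        non = estimate_transition_matrix(C, reversible=False)
        assert np.allclose(rev.transition_matrix, non.transition_matrix, atol=1e-10)

    def test_recovers_generating_matrix(self, two_state_chain):
        T, seq = two_state_chain
        model = estimate_transition_matrix(count_transitions(seq, 1), reversible=True)
        assert np.abs(model.transition_matrix - T).max() < 0.01
        assert np.abs(model.stationary_distribution - [2 / 3, 1 / 3]).max() < 0.005

    def test_detailed_balance_and_row_sums(self, two_state_chain):
        _, seq = two_state_chain
        model = estimate_transition_matrix(count_transitions(seq, 5), reversible=True, lag=5)
        T, pi = model.transition_matrix, model.stationary_distribution
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(pi[:, None] * T, pi[None, :] * T.T, atol=1e-8)
        assert np.allclose(pi @ T, pi, atol=1e-8)

    def test_disconnected_states_dropped(self):
        C = np.zeros((3, 3), dtype=int)
        C[0, 1] = C[1, 0] = 10
        C[2, 2] = 5   # isolated self-looping state
        model = estimate_transition_matrix(C)
        assert model.active_set.tolist() == [0, 1]


class TestImpliedTimescales:
    def test_closed_form_eigenvalue(self):
        # lambda2 = 0.9 at lag 1 -> t2 = -1/ln 0.9
        T = np.array([[0.95, 0.05], [0.05, 0.95]])
        ts = timescales_from_matrix(T, lag=1, n_timescales=1)
        assert ts[0] == pytest.approx(-1 / np.log(0.9), rel=1e-12)

    def test_exact_markov_input_is_lag_independent(self):
        T = np.array([[0.9, 0.08, 0.02], [0.1, 0.85, 0.05], [0.05, 0.05, 0.9]])
        t_base = timescales_from_matrix(T, lag=1, n_timescales=2)
        for k in (2, 3, 5):
            tk = timescales_from_matrix(np.linalg.matrix_power(T, k), lag=k,
                                        n_timescales=2)
            assert np.allclose(tk, t_base, rtol=1e-10)

    def test_sampled_chain_its_stable_over_lags(self, two_state_chain):
        T, seq = two_state_chain
        truth = timescales_from_matrix(T, 1, 1)[0]
        its = implied_timescales(seq, [1, 2, 5, 10], n_timescales=1)
        assert np.nanmax(np.abs(its.timescales[:, 0] - truth)) / truth < 0.10


class TestPcca:
    def test_two_block_chain_assignment(self):
        T = np.array([[0.45, 0.45, 0.05, 0.05],
                      [0.45, 0.45, 0.05, 0.05],
                      [0.05, 0.05, 0.45, 0.45],
                      [0.05, 0.05, 0.45, 0.45]])
        seq = sample_markov_chain(ChainSpec(T, 100_000, seed=4))
        model = estimate_transition_matrix(count_transitions(seq, 1), reversible=True)
        decomp = pcca_plus(model, 2)
        labels = decomp.macrostate_of[np.argsort(model.active_set)]
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_m_equals_n_is_identity(self):
        C = np.array([[50, 5, 2], [5, 60, 4], [2, 4, 40]])
        model = estimate_transition_matrix(C, reversible=True)
        decomp = pcca_plus(model, 3)
        perm = decomp.macrostate_of
        assert sorted(perm.tolist()) == [0, 1, 2]
        assert np.allclose(np.sort(decomp.memberships, axis=1)[:, -1], 1.0, atol=1e-8)

    def test_memberships_row_stochastic_and_mass_conserved(self, two_state_chain):
        _, seq = two_state_chain
        model = estimate_transition_matrix(count_transitions(seq, 2), reversible=True, lag=2)
        decomp = pcca_plus(model, 2)
        assert np.allclose(decomp.memberships.sum(axis=1), 1.0, atol=1e-10)
        assert decomp.macrostate_probabilities.sum() == pytest.approx(1.0, abs=1e-10)
        assert decomp.macrostate_probabilities_weighted.sum() == pytest.approx(1.0, abs=1e-10)

    def test_non_reversible_model_rejected(self):
        C = np.array([[5, 5, 0], [0, 5, 5], [5, 0, 5]])
        model = estimate_transition_matrix(C, reversible=False)
        with pytest.raises(ValueError, match="reversible"):
            pcca_plus(model, 2)


class TestCK:
    def test_exact_deterministic_input_identical_curves(self):
        # alternating chain: every odd-lag estimate is the exact matrix
        seq = np.tile([0, 1], 2000)
        res = ck_test(seq, lag=1, m=2, factors=(1, 3, 5))
        assert res.valid.all()
        assert np.allclose(res.predicted, res.estimated, atol=1e-12)
        assert res.passed

    def test_sampled_two_state_chain_within_band(self, two_state_chain):
        _, seq = two_state_chain
        res = ck_test(seq, lag=1, m=2, factors=(1, 2, 3, 4, 5), tolerance=0.05)
        assert res.max_deviation < 0.02
        assert res.passed

    def test_semi_markov_dwell_times_fail_the_band(self, rng):
        # two states alternating with Pareto (heavy-tailed) dwell times is
        # far from geometric: T(tau)^k systematically overestimates mixing
        dwell = lambda size: np.clip(rng.pareto(1.3, size) + 1, 1, 2000).astype(int)
        states = []
        s = 0
        while sum(len(x) for x in states) < 200_000:
            states.append(np.full(dwell(1)[0], s))
            s = 1 - s
        seq = np.concatenate(states)
        res = ck_test(seq, lag=5, m=2, factors=(1, 2, 3, 4, 5), tolerance=0.05)
        assert not res.passed

    def test_factor_exceeding_length_flagged(self):
        seq = np.tile([0, 1], 30)
        res = ck_test(seq, lag=5, m=2, factors=(1, 3, 50))
        assert not res.valid[-1]


class TestTPT:
    def test_symmetric_path_chain_committor_half(self):
        T = np.array([[0.8, 0.2, 0.0], [0.1, 0.8, 0.1], [0.0, 0.2, 0.8]])
        model = estimate_transition_matrix((T * 1000).astype(int), reversible=True)
        res = tpt_analysis(model, [0], [2])
        assert res.forward_committor[1] == pytest.approx(0.5, abs=1e-12)
        assert res.forward_committor[0] == 0.0
        assert res.forward_committor[2] == 1.0

    def test_net_flux_antisymmetric_support(self):
        T = np.array([[0.7, 0.2, 0.1], [0.2, 0.6, 0.2], [0.1, 0.3, 0.6]])
        model = estimate_transition_matrix((T * 5000).astype(int), reversible=True)
        res = tpt_analysis(model, [0], [2])
        assert np.all(res.net_flux >= 0)
        assert np.all((res.net_flux * res.net_flux.T) < 1e-18)

    def test_birth_death_mfpt_matches_simulation(self, rng):
        p, q = 0.3, 0.2
        n = 5
        T = np.zeros((n, n))
        for i in range(n):
            if i > 0:
                T[i, i - 1] = q
            if i < n - 1:
                T[i, i + 1] = p
            T[i, i] = 1 - T[i].sum()
        model = estimate_transition_matrix((T * 10_000).astype(int), reversible=True)
        res = tpt_analysis(model, [0], [4])
        sim = simulate_first_passage(model.transition_matrix, 0, 4, 100_000, rng)
        assert res.mfpt == pytest.approx(sim.mean(), rel=0.02)

    def test_disjointness_required(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        model = estimate_transition_matrix((T * 100).astype(int), reversible=True)
        with pytest.raises(ValueError, match="disjoint"):
            tpt_analysis(model, [0], [0, 1])


class TestRepresentative:
    def test_duplicated_frame_wins(self, rng):
        # 8 near-copies of one conformation plus 2 genuinely distorted outliers
        # (internal distortion, not rigid motion, which RMSD would ignore)
        common = rng.standard_normal((6, 3)) * 5
        pool = np.array([common + 0.01 * rng.standard_normal((6, 3)) for _ in range(8)]
                        + [common + 4.0 * rng.standard_normal((6, 3)),
                           common + 4.0 * rng.standard_normal((6, 3))])
        rep = select_representative(pool)
        assert rep.frame_index < 8

    def test_two_frames_tie_returns_first(self, rng):
        pool = rng.standard_normal((2, 5, 3))
        rep = select_representative(pool)
        assert rep.frame_index == 0

    def test_identical_pool_degenerate_scale(self, rng):
        pool = np.tile(rng.standard_normal((5, 3)), (4, 1, 1))
        rep = select_representative(pool)
        assert rep.frame_index == 0 and rep.score == 1.0 and rep.d_scale == 0.0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            pool = rng.standard_normal((10, 5, 3)) * 3
            rep = select_representative(pool)
            idx, score = representative_bruteforce(pool, quaternion_rmsd)
            assert rep.frame_index == idx
            assert rep.score == pytest.approx(score, abs=1e-6)
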