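import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from boolpert.likelihood_hmm import (
    EmissionParameters,
    assign_states,
    data_log_likelihood,
    estimate_emission_parameters,
    optimize_states,
    read_tidy_table,
    sigma_floor,
    write_tidy_table,
    StateAssignment,
)
from boolpert.model_core import NodeRoster, SignalingNetwork
from boolpert.propagation import StateTrajectory
from boolpert.synthetic_data import (
    GeneratorSpec,
    default_emission,
    default_shortterm_design,
    example_truth_network,
    generate_dataset,
)

from conftest import make_dataset, random_roster


def single_protein_roster():
    return NodeRoster(("X", "S"), {"X": "protein", "S": "stimulus"})


def two_state_trajectory(roster, cond=frozenset({"S"})):
    """X off, then on (S clamped throughout)."""
    states = np.array([[0, 1], [1, 1]], dtype=np.int8)
    return StateTrajectory(cond, roster, states, "fixpoint")


def enumerate_monotone(M, T):
    return itertools.combinations_with_replacement(range(M), T)


def brute_force_assignment(trajs, data, emission):
    """Exhaustive oracle: scan every monotone sequence per condition."""
    pidx = [data.roster.index(p) for p in data.roster.proteins]
    out = []
    for c, traj in enumerate(trajs):
        T = data.design.n_times
        best, best_val = None, -np.inf
        for seq in enumerate_monotone(traj.n_states, T):
            val = 0.0
            for t, k in enumerate(seq):
                for p_i, p_row in enumerate(pidx):
                    cls = traj.states[k, p_row]
                    mu = emission.mu1[p_i] if cls else emission.mu0[p_i]
                    sd = emission.sd1[p_i] if cls else emission.sd0[p_i]
                    vals = data.values[p_i, c, t]
                    vals = vals[np.isfinite(vals)]
                    val += sstats.norm.logpdf(vals, mu, sd).sum()
            # lexicographically smallest winner within tolerance
            if best is None or val > best_val + 1e-9 * (1 + abs(best_val)):
                best, best_val = seq, val
        out.append(best)
    return out


class TestEstimateEmission:
    def test_two_by_two_split_recovers_class_means(self):
        roster = single_protein_roster()
        data = make_dataset(
            roster, [(frozenset({"S"}), frozenset())], (0.0, 1.0, 2.0, 3.0),
            np.array([1.0, 1.0, 3.0, 3.0]).reshape(1, 1, 4, 1),
        )
        gamma = np.array([0, 0, 1, 1], dtype=np.int8).reshape(1, 1, 4)
        assignment = StateAssignment(np.array([[0, 0, 1, 1]]), gamma)
        em = estimate_emission_parameters(data, assignment)
        assert em.mu0[0] == pytest.approx(1.0)
        assert em.mu1[0] == pytest.approx(3.0)
        floor = sigma_floor(data.values)
        assert em.sd0[0] == pytest.approx(floor)
        assert em.sd1[0] == pytest.approx(floor)

    def test_empty_class_falls_back_with_warning(self):
        roster = single_protein_roster()
        data = make_dataset(
            roster, [(frozenset({"S"}), frozenset())], (0.0, 1.0),
            np.array([2.0, 4.0]).reshape(1, 1, 2, 1),
        )
        gamma = np.ones((1, 1, 2), dtype=np.int8)  # everything active
        assignment = StateAssignment(np.array([[0, 0]]), gamma)
        with pytest.warns(UserWarning, match="empty emission class"):
            em = estimate_emission_parameters(data, assignment)
        assert em.mu0[0] < em.mu1[0]

    def test_matches_group_by_oracle_on_random_assignment(self):
        rng = np.random.default_rng(3)
        roster = random_roster(rng, n_proteins=3)
        P, C, T, R = 3, 2, 5, 3
        idx = np.sort(rng.integers(0, 2, size=(C, T)), axis=1)
        gamma = rng.integers(0, 2, size=(P, C, T)).astype(np.int8)
        # active cells shifted up so the class orientation (active mean
        # above passive) matches the labels
        values = rng.normal(10, 2, size=(P, C, T, R)) \
            + 8.0 * gamma[..., None]
        data = make_dataset(
            roster,
            [(frozenset({"s0"}), frozenset()),
             (frozenset({"s0"}), frozenset({"d0"}))],
            tuple(range(T)), values,
        )
        assignment = StateAssignment(idx, gamma)
        em = estimate_emission_parameters(data, assignment)
        for p in range(P):
            mask1 = np.repeat(gamma[p].astype(bool)[..., None], R, axis=2)
            v1 = values[p][mask1]
            v0 = values[p][~mask1]
            assert em.mu0[p] == pytest.approx(v0.mean())
            assert em.mu1[p] == pytest.approx(v1.mean())
            assert em.sd0[p] == pytest.approx(v0.std())
            assert em.sd1[p] == pytest.approx(v1.std())


class TestAssignStates:
    def test_single_state_trajectory_is_forced(self):
        roster = single_protein_roster()
        cond = frozenset({"S"})
        traj = StateTrajectory(cond, roster,
                              np.array([[0, 1]], dtype=np.int8), "fixpoint")
        data = make_dataset(roster, [(cond, frozenset())], (0.0, 1.0, 2.0),
                            np.array([9.0, 12.0, 15.0]).reshape(1, 1, 3, 1))
        em = EmissionParameters([10.0], [1.0], [12.0], [1.0])
        a = assign_states([traj], data, em)
        assert a.indices.tolist() == [[0, 0, 0]]

    def test_well_separated_switch_at_t3_of_5(self):
        roster = single_protein_roster()
        cond = frozenset({"S"})
        traj = two_state_trajectory(roster)
        vals = np.array([10.0, 10.0, 12.0, 12.0, 12.0]).reshape(1, 1, 5, 1)
        data = make_dataset(roster, [(cond, frozenset())],
                            (0.0, 1.0, 2.0, 3.0, 4.0), vals)
        em = EmissionParameters([10.0], [0.5], [12.0], [0.5])
        a = assign_states([traj], data, em)
        assert a.indices.tolist() == [[0, 0, 1, 1, 1]]

    @pytest.mark.parametrize("seed", range(30))
    def test_dp_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        roster = random_roster(rng, n_proteins=2)
        M = int(rng.integers(2, 5))
        T = int(rng.integers(2, 7))
        cond = frozenset({"s0"})
        states = np.zeros((M, len(roster)), dtype=np.int8)
        states[:, roster.index("s0")] = 1
        for k in range(1, M):
            states[k] = states[k - 1]
            flip = rng.integers(0, 2)
            states[k, flip] = 1 - states[k, flip]
        traj = StateTrajectory(cond, roster, states, "fixpoint")
        values = rng.normal(11, 1.5, size=(2, 1, T, 2))
        data = make_dataset(roster, [(cond, frozenset())], tuple(range(T)),
                            values)
        em = EmissionParameters([10.0, 10.0], [1.0, 1.0],
                                [12.0, 12.0], [1.0, 1.0])
        got = assign_states([traj], data, em)
        expected = brute_force_assignment([traj], data, em)
        assert got.indices.tolist() == [list(expected[0])]


class TestDataLogLikelihood:
    def test_single_cell_at_active_peak(self):
        roster = single_protein_roster()
        cond = frozenset({"S"})
        data = make_dataset(roster, [(cond, frozenset())], (0.0, 1.0),
                            np.array([12.0, 12.0]).reshape(1, 1, 2, 1))
        em = EmissionParameters([10.0], [1.0], [12.0], [1.0])
        gamma = np.ones((1, 1, 2), dtype=np.int8)
        a = StateAssignment(np.array([[0, 0]]), gamma)
        ll = data_log_likelihood(data, a, em)
        # two iid cells at the standard-normal peak: 2 * log(1/sqrt(2 pi))
        assert ll == pytest.approx(2 * np.log(1 / np.sqrt(2 * np.pi)))

    def test_matches_per_cell_oracle(self):
        rng = np.random.default_rng(11)
        roster = random_roster(rng, n_proteins=3)
        P, C, T, R = 3, 2, 4, 3
        values = rng.normal(11, 1, size=(P, C, T, R))
        values[1, 0, 2, 2] = np.nan  # a missing replicate
        data = make_dataset(
            roster,
            [(frozenset({"s0"}), frozenset()),
             (frozenset({"s0"}), frozenset({"d0"}))],
            tuple(range(T)), values,
        )
        em = EmissionParameters(rng.normal(10, 0.2, P), np.full(P, 0.8),
                                rng.normal(12, 0.2, P), np.full(P, 1.2))
        idx = np.sort(rng.integers(0, 2, size=(C, T)), axis=1)
        gamma = rng.integers(0, 2, size=(P, C, T)).astype(np.int8)
        a = StateAssignment(idx, gamma)
        oracle = 0.0
        for p in range(P):
            for c in range(C):
                for t in range(T):
                    mu = em.mu1[p] if gamma[p, c, t] else em.mu0[p]
                    sd = em.sd1[p] if gamma[p, c, t] else em.sd0[p]
                    v = values[p, c, t]
                    oracle += sstats.norm.logpdf(v[np.isfinite(v)], mu, sd).sum()
        assert data_log_likelihood(data, a, em) == pytest.approx(oracle)

    def test_replicate_permutation_invariance(self):
        rng = np.random.default_rng(5)
        roster = random_roster(rng, n_proteins=2)
        values = rng.normal(11, 1, size=(2, 1, 3, 4))
        cond = [(frozenset({"s0"}), frozenset())]
        data = make_dataset(roster, cond, (0.0, 1.0, 2.0), values)
        perm = values[:, :, :, rng.permutation(4)]
        data_p = make_dataset(roster, cond, (0.0, 1.0, 2.0), perm)
        em = EmissionParameters([10, 10], [1, 1], [12, 12], [1, 1])
        a = StateAssignment(np.zeros((1, 3), dtype=int),
                            np.zeros((2, 1, 3), dtype=np.int8))
        assert data_log_likelihood(data, a, em) == pytest.approx(
            data_log_likelihood(data_p, a, em))


class TestOptimizeStates:
    def test_recovers_generating_states_at_4_sigma(self, truth_net,
                                                   short_design):
        hits = []
        for seed in range(20):
            spec = GeneratorSpec(truth_net, short_design,
                                 default_emission(6), seed=seed)
            data, true_assign = generate_dataset(spec)
            res = optimize_states(truth_net, data)
            hits.append((res.assignment.gamma == true_assign.gamma).mean())
        assert np.mean(hits) >= 0.95

    def test_constant_data_returns_tie_break_assignment(self, cascade_net):
        roster = cascade_net.roster
        values = np.full((3, 1, 4, 2), 10.0)
        data = make_dataset(roster, [(frozenset({"S"}), frozenset())],
                            (0.0, 1.0, 2.0, 3.0), values)
        res = optimize_states(cascade_net, data)
        assert res.assignment.indices.tolist() == [[0, 0, 0, 0]]

    @pytest.mark.parametrize("seed", range(25))
    def test_round_trace_is_non_decreasing(self, seed):
        rng = np.random.default_rng(200 + seed)
        roster = random_roster(rng, n_proteins=3, n_stimuli=1, n_drugs=1)
        n = len(roster)
        adj = np.zeros((n, n), dtype=int)
        pmask = roster.perturbation_mask()
        for i in range(n):
            for j in range(n):
                if i != j and not pmask[j] and rng.random() < 0.4:
                    adj[i, j] = rng.choice([1, 1, -1])
        net = SignalingNetwork(roster, adj)
        values = rng.normal(10, 1, size=(3, 2, 5, 2)) \
            + rng.integers(0, 2, size=(3, 2, 5, 1)) * 2
        data = make_dataset(
            roster,
            [(frozenset({"s0"}), frozenset()),
             (frozenset({"s0"}), frozenset({"d0"}))],
            tuple(range(5)), values,
        )
        res = optimize_states(net, data)
        assert all(b >= a - 1e-9 for a, b in zip(res.trace, res.trace[1:]))


class TestTidyIO:
    def test_round_trip_preserves_values_and_design(self, planted_data,
                                                    tmp_path):
        data, _ = planted_data
        path = tmp_path / "data.tsv"
        write_tidy_table(data, path)
        back = read_tidy_table(path, data.roster)
        assert back.design.timepoints == data.design.timepoints
        assert back.design.n_conditions == data.design.n_conditions
        # align condition order via labels
        labels = data.design.condition_labels()
        back_labels = back.design.condition_labels()
        order = [back_labels.index(l) for l in labels]
        np.testing.assert_allclose(back.values[:, order], data.values)

    def test_missing_cell_reported(self, tmp_path):
        roster = single_protein_roster()
        path = tmp_path / "bad.tsv"
        path.write_text(
            "protein\tcondition\tstimuli\tdrugs\ttime\treplicate\tvalue\n"
            "X\tS|none\tS\t\t0\t1\t10.0\n"
            "X\tS|none\tS\t\t1\t1\t11.0\n"
            "X\tS|none\tS\t\t2\t1\t\n"  # missing value at t=2
        )
        with pytest.raises(ValueError, match="missing cells"):
            read_tidy_table(path, roster)
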