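import itertools

import numpy as np
import pytest

from boolpert.boolean_sim import (
    And,
    Not,
    Or,
    PerturbationScenario,
    RuleParseError,
    Var,
    edgetic_scan,
    exhaustive_steady_states,
    find_attractors,
    network_to_rules,
    parse_expression,
    parse_rules,
    simulate_drug_panel,
    synchronous_step,
    write_rules,
)
from boolpert.model_core import NodeRoster, SignalingNetwork
from boolpert.propagation import transition_step
from boolpert.synthetic_data import example_truth_network

from conftest import random_roster


def random_network(rng, roster, p_edge=0.35):
    n = len(roster)
    adj = np.zeros((n, n), dtype=int)
    pmask = roster.perturbation_mask()
    for i in range(n):
        for j in range(n):
            if i != j and not pmask[j] and rng.random() < p_edge:
                adj[i, j] = rng.choice([1, 1, -1])
    # indegree cap
    for j in range(n):
        parents = np.nonzero(adj[:, j])[0]
        if parents.size > 4:
            adj[rng.choice(parents, parents.size - 4, replace=False), j] = 0
    return SignalingNetwork(roster, adj)


class TestRuleConstruction:
    def test_activators_inhibitors_and_self_term(self):
        names = ("j", "a", "b", "c", "S")
        roles = dict.fromkeys(names, "protein")
        roles["S"] = "stimulus"
        roster = NodeRoster(names, roles)
        net = SignalingNetwork.from_edges(
            roster, [("a", "j", 1), ("b", "j", 1), ("c", "j", -1)])
        rules = network_to_rules(net, {"S"})
        assert str(rules.rules["j"]) == "(a | b | j) & !(c)"

    def test_isolated_node_holds_its_value(self, tiny_roster):
        net = SignalingNetwork.empty(tiny_roster)
        rules = network_to_rules(net, {"S"})
        assert str(rules.rules["A"]) == "A"

    def test_input_with_parents_rejected(self, cascade_net):
        with pytest.raises(ValueError, match="ingoing"):
            network_to_rules(cascade_net, {"S", "A"})


class TestParsing:
    def test_expression_grammar_and_precedence(self):
        e = parse_expression("A | B & !C")
        assert e == Or((Var("A"), And((Var("B"), Not(Var("C"))))))
        assert parse_expression("(EGF | A) & !(E)") == And(
            (Or((Var("EGF"), Var("A"))), Not(Var("E"))))

    def test_malformed_expression_raises(self):
        with pytest.raises(RuleParseError):
            parse_expression("A | | B")
        with pytest.raises(RuleParseError):
            parse_expression("(A")

    def test_unknown_literal_named_in_error(self, tiny_roster, tmp_path):
        path = tmp_path / "bad.rules"
        path.write_text("targets, factors\nA, (S | zzz)\n")
        with pytest.raises(RuleParseError, match="zzz"):
            parse_rules(path, tiny_roster)

    def test_round_trip_on_random_networks(self, tmp_path):
        rng = np.random.default_rng(0)
        for k in range(10):
            roster = random_roster(rng, n_proteins=5, n_stimuli=1, n_drugs=1)
            net = random_network(rng, roster)
            rules = network_to_rules(net, roster.perturbations)
            path = tmp_path / f"net{k}.rules"
            write_rules(rules, path)
            back = parse_rules(path, roster)
            assert back.rules == rules.rules
            assert back.fixed == rules.fixed


class TestSynchronousStep:
    def test_self_term_sustains_activity_unlike_propagation(self):
        # regression pinning the two semantics: once the activator turns
        # off, the reconstruction-time propagation drops the child while the
        # forward-simulation rule keeps it active via the self term
        names = ("A", "B", "S")
        roster = NodeRoster(names, {"A": "protein", "B": "protein",
                                    "S": "stimulus"})
        net = SignalingNetwork.from_edges(roster, [("A", "B", 1)])
        state = np.array([0, 1, 0])  # activator A off, B on
        prop_next = transition_step(net, state, set())
        assert prop_next[1] == 0  # no self term: B decays
        rules = network_to_rules(net, {"S"})
        sim_next = synchronous_step(rules, state, {"S": 0})
        assert sim_next[1] == 1  # self term: B sustains

    def test_chain_activation_under_stimulus(self, cascade_net):
        rules = network_to_rules(cascade_net, {"S"})
        state = np.array([0, 0, 0, 1])
        s1 = synchronous_step(rules, state, {"S": 1})
        assert list(s1) == [1, 0, 0, 1]

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_truth_table_oracle(self, seed):
        rng = np.random.default_rng(seed)
        roster = random_roster(rng, n_proteins=5, n_stimuli=1, n_drugs=0)
        net = random_network(rng, roster)
        rules = network_to_rules(net, roster.perturbations)
        for state in itertools.product((0, 1), repeat=len(roster)):
            state = np.array(state)
            got = synchronous_step(rules, state, {"s0": int(state[-1])})
            for j, node in enumerate(roster.names):
                if node in rules.fixed:
                    assert got[j] == state[j]
                    continue
                acts = net.parents(node, 1)
                inhs = net.parents(node, -1)
                pos = state[j] or any(
                    state[roster.index(a)] for a in acts)
                neg = any(state[roster.index(i)] for i in inhs)
                assert got[j] == int(bool(pos) and not neg)


class TestAttractors:
    def test_all_zero_rules_reach_zero_steady_state(self, tiny_roster):
        net = SignalingNetwork.empty(tiny_roster)
        rules = network_to_rules(net, {"S"})
        att = find_attractors(rules, PerturbationScenario({"S": 0}))
        assert att.is_steady and not att.states.any()

    def test_stimulated_cascade_closure(self, cascade_net):
        rules = network_to_rules(cascade_net, {"S"})
        att = find_attractors(rules, PerturbationScenario({"S": 1}))
        assert att.is_steady
        assert att.states[0].tolist() == [1, 1, 1, 1]

    def test_feedback_with_self_sustaining_inhibitor_damps(self):
        # A -> B, B -| A: B self-sustains once on, permanently silencing A,
        # so the self-term semantics give a steady state rather than the
        # oscillation the propagation semantics would produce
        names = ("A", "B", "S")
        roster = NodeRoster(names, {"A": "protein", "B": "protein",
                                    "S": "stimulus"})
        net = SignalingNetwork.from_edges(
            roster, [("S", "A", 1), ("A", "B", 1), ("B", "A", -1)])
        rules = network_to_rules(net, {"S"})
        att = find_attractors(rules, PerturbationScenario({"S": 1}))
        assert att.is_steady
        assert att.states[0].tolist() == [0, 1, 1]

    def test_mutual_inhibition_two_cycle(self):
        # stimulated mutual inhibition flips both nodes in lockstep: the
        # synchronous trajectory enters a 2-cycle, reported not as steady
        names = ("A", "B", "S")
        roster = NodeRoster(names, {"A": "protein", "B": "protein",
                                    "S": "stimulus"})
        net = SignalingNetwork.from_edges(
            roster, [("S", "A", 1), ("S", "B", 1),
                     ("A", "B", -1), ("B", "A", -1)])
        rules = network_to_rules(net, {"S"})
        att = find_attractors(rules, PerturbationScenario({"S": 1}))
        assert not att.is_steady
        assert len(att.states) == 2

    @pytest.mark.parametrize("seed", range(15))
    def test_steady_states_in_exhaustive_set_and_async_fixed(self, seed):
        rng = np.random.default_rng(300 + seed)
        roster = random_roster(rng, n_proteins=6, n_stimuli=1, n_drugs=1)
        net = random_network(rng, roster)
        rules = network_to_rules(net, roster.perturbations)
        fixed = {"s0": 1, "d0": int(rng.integers(0, 2))}
        att = find_attractors(rules, PerturbationScenario(fixed))
        for node, v in fixed.items():
            assert (att.states[:, roster.index(node)] == v).all()
        if att.is_steady:
            ss = exhaustive_steady_states(rules, fixed)
            assert tuple(int(x) for x in att.states[0]) in ss

    def test_identity_rules_make_every_state_fixed(self, tiny_roster):
        net = SignalingNetwork.empty(tiny_roster)
        rules = network_to_rules(net, {"S"})
        ss = exhaustive_steady_states(rules, {"S": 0})
        assert len(ss) == 2 ** 3  # three free protein nodes

    def test_exhaustive_rejects_oversized_state_space(self):
        rng = np.random.default_rng(0)
        roster = random_roster(rng, n_proteins=23, n_stimuli=1, n_drugs=0)
        rules = network_to_rules(SignalingNetwork.empty(roster),
                                 roster.perturbations)
        with pytest.raises(ValueError, match="free nodes"):
            exhaustive_steady_states(rules, {"s0": 1})


class TestDrugPanel:
    def test_three_drugs_give_eight_rows(self, truth_net):
        rules = network_to_rules(truth_net, truth_net.roster.perturbations)
        panel = simulate_drug_panel(rules, ["E", "P", "T"], ["EGF", "HRG"],
                                    ["K1", "O1"])
        assert len(panel) == 8
        assert panel[["E", "P", "T"]].drop_duplicates().shape[0] == 8

    def test_all_drugs_off_matches_stimulus_only_attractor(self, truth_net):
        roster = truth_net.roster
        rules = network_to_rules(truth_net, roster.perturbations)
        panel = simulate_drug_panel(rules, ["E", "P", "T"], ["EGF", "HRG"],
                                    list(roster.proteins))
        row = panel[(panel["E"] == 0) & (panel["P"] == 0)
                    & (panel["T"] == 0)].iloc[0]
        att = find_attractors(rules, PerturbationScenario(
            {"EGF": 1, "HRG": 1, "E": 0, "P": 0, "T": 0}))
        for p in roster.proteins:
            assert row[p] == att.node_value(p)

    def test_receptor_inhibitor_silences_downstream(self, truth_net):
        # E blocks R1, hence K1 and O1, in every row with E on
        rules = network_to_rules(truth_net, truth_net.roster.perturbations)
        panel = simulate_drug_panel(rules, ["E", "P", "T"], ["EGF", "HRG"],
                                    ["R1", "K1", "O1"])
        on_e = panel[panel["E"] == 1]
        assert (on_e[["R1", "K1", "O1"]] == 0).all().all()

    def test_unknown_readout_rejected(self, truth_net):
        rules = network_to_rules(truth_net, truth_net.roster.perturbations)
        with pytest.raises(KeyError):
            simulate_drug_panel(rules, ["E"], ["EGF"], ["nope"])


class TestEdgeticScan:
    def test_four_candidates_yield_15_removal_sets(self):
        # 4 singletons + 11 multi-edge combinations, plus a baseline block
        names = ("T1", "a", "b", "c", "d", "S", "D")
        roles = dict.fromkeys(names, "protein")
        roles.update({"S": "stimulus", "D": "drug"})
        roster = NodeRoster(names, roles)
        net = SignalingNetwork.from_edges(
            roster,
            [("a", "T1", 1), ("b", "T1", 1), ("c", "T1", 1), ("d", "T1", 1),
             ("S", "a", 1), ("S", "b", 1), ("S", "c", 1), ("S", "d", 1)])
        report = edgetic_scan(net, "T1", ["a", "b", "c", "d"], ["D"], ["S"])
        removals = [r for r in report["removed"].unique() if r]
        assert len(removals) == 15
        multi = [r for r in removals if "+" in r]
        assert len(multi) == 11
        assert len(report) == 16 * 2  # 2 drug rows per removal set

    def test_baseline_block_reproduces_intact_panel(self, truth_net):
        roster = truth_net.roster
        report = edgetic_scan(truth_net, "K1", ["R1"], ["E", "P", "T"],
                              ["EGF", "HRG"], readouts=["K1", "O1"])
        rules = network_to_rules(truth_net, roster.perturbations)
        panel = simulate_drug_panel(rules, ["E", "P", "T"], ["EGF", "HRG"],
                                    ["K1", "O1"])
        base = report[report.removed == ""].reset_index(drop=True)
        assert (base[["E", "P", "T", "K1", "O1"]].values
                == panel[["E", "P", "T", "K1", "O1"]].values).all()

    def test_removing_sustaining_edge_flips_target_off(self):
        # K1's only activator is R1; removing R1->K1 leaves K1 off even
        # without its inhibitor
        net = example_truth_network()
        report = edgetic_scan(net, "K1", ["R1"], ["E", "P", "T"],
                              ["EGF", "HRG"], readouts=["K1"])
        removed = report[report.removed == "R1"]
        assert (removed["K1"] == 0).all()

    def test_non_parent_candidate_rejected(self, truth_net):
        with pytest.raises(ValueError, match="not a parent"):
            edgetic_scan(truth_net, "K1", ["O2"], ["E"], ["EGF"])
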