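"""Deterministic Boolean effects propagation through a small cascade.

Builds a receptor->kinase->output chain with an inhibitor drug, clamps the
stimulus on, and prints the reachable system states in order.
"""

from boolpert import NodeRoster, SignalingNetwork, propagate_states

roster = NodeRoster(
    ("R", "K", "O", "EGF", "drugE"),
    {"R": "protein", "K": "protein", "O": "protein",
     "EGF": "stimulus", "drugE": "drug"},
)
net = SignalingNetwork.from_edges(
    roster,
    [("EGF", "R", 1), ("drugE", "R", -1), ("R", "K", 1), ("K", "O", 1)],
)

for condition in ({"EGF"}, {"EGF", "drugE"}):
    traj = propagate_states(net, condition)
    print(f"condition {sorted(condition)}: {traj.n_states} states,"
          f" terminal={traj.terminal}")
    for k, state in enumerate(traj.states):
        print(f"  step {k}: " + " ".join(
            f"{n}={v}" for n, v in zip(roster.names, state)))

# Under EGF alone, activity travels one layer per transition until the full
# cascade is on (a fixpoint).  Adding the receptor inhibitor clamps the
# system in its resting state: the drug blocks activation at the source.
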