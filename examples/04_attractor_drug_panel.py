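"""Boolean rules and steady-state attractors under drug combinations.

Converts a signed network to update rules, then simulates all eight on/off
combinations of the three drugs with both growth factors clamped on, and
prints the attractor value of each downstream readout.
"""

from boolpert import network_to_rules, simulate_drug_panel, write_rules
from boolpert.synthetic_data import example_truth_network

net = example_truth_network()
rules = network_to_rules(net, net.roster.perturbations)
print("update rules:")
for node in net.roster.proteins:
    print(f"  {node}, {rules.rules[node]}")

panel = simulate_drug_panel(rules, ["E", "P", "T"], ["EGF", "HRG"],
                            ["K1", "K2", "O1", "O2"])
print(panel.to_string(index=False))

# Each row is one treatment scenario (1 = drug present).  A 0 readout means
# the protein is inactive in the steady state the system settles into: the
# drug combination cuts every sustaining path to it.
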