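"""Edgetic analysis: which edge removals restore drug sensitivity?

Removes each subset of a target's incoming activation edges, re-simulates
the drug panel, and reports when the target can still be switched off.
Models edge-specific (edgetic) mutations rather than node knockouts.
"""

from boolpert import edgetic_scan
from boolpert.model_core import NodeRoster, SignalingNetwork

# K receives signal through the druggable receptor R and through a second,
# drug-independent branch F — a bypass that confers resistance.
roster = NodeRoster(
    ("R", "K", "F", "EGF", "drugE"),
    {"R": "protein", "K": "protein", "F": "protein",
     "EGF": "stimulus", "drugE": "drug"},
)
net = SignalingNetwork.from_edges(
    roster,
    [("EGF", "R", 1), ("drugE", "R", -1),
     ("EGF", "F", 1), ("R", "K", 1), ("F", "K", 1)],
)

report = edgetic_scan(net, "K", ["R", "F"], ["drugE"], ["EGF"],
                      readouts=["K"])
print(report[["removed", "drugE", "K", "K_inactive"]].to_string(index=False))

# In the intact network the drug fails to silence K: the bypass edge F->K
# keeps feeding it.  Removing F->K (alone or together with R->K) makes K
# drug-sensitive again, so that edge is the modelled resistance mechanism;
# removing only R->K changes nothing the drug had not already blocked.
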