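"""RPPA-like synthetic perturbation time courses from a known network.

The generator inverts the reconstruction model: it propagates Boolean
perturbation effects through a ground-truth signed network, maps the
reachable states onto the measurement time grid, and draws every intensity
from the protein's active- or passive-class Gaussian.  The shipped designs
mirror the study layout this package targets: a short-term panel of 11
phosphoproteins under 3 growth-factor contexts x 8 drug subsets (24
conditions, 10 time points over 0-60 min, 3 replicates, 5 when drug-free)
and a long-term panel of 21 proteins under a single growth-medium stimulus
(10 time points over 0-30 h).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .likelihood_hmm import (
    EmissionParameters,
    ExperimentDesign,
    PerturbationDataset,
    StateAssignment,
)
from .model_core import NodeRoster, SignalingNetwork
from .propagation import propagate_states

__all__ = [
    "GeneratorSpec",
    "generate_dataset",
    "default_shortterm_design",
    "default_longterm_design",
    "shortterm_roster",
    "longterm_roster",
    "example_truth_network",
    "default_emission",
]

SHORT_TIMEPOINTS_MIN = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 30.0, 40.0, 50.0, 60.0)
LONG_TIMEPOINTS_H = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 18.0, 24.0, 30.0)
DRUGS = ("E", "P", "T")  # erlotinib, pertuzumab, trastuzumab

_SHORT_PROTEINS = (
    "AKT", "ERBB1", "ERBB2", "ERBB3", "ERK12", "MEK12",
    "mTOR", "p70S6K", "PDK1", "PKCa", "PLCg",
)
_LONG_PROTEINS = (
    "AKT", "BAX", "cJUN", "cRAF", "CyclinB1", "CyclinD1", "ERBB1", "ERBB2",
    "ERBB3", "ERK12", "FOXO13a", "GSK3", "NFkB", "p38", "p53", "p70S6K",
    "PRAS", "PTEN", "RB", "RPS6", "TSC2",
)


def shortterm_roster() -> NodeRoster:
    """11 phosphoprotein targets plus EGF/HRG stimuli and the three drugs."""
    names = _SHORT_PROTEINS + ("EGF", "HRG") + DRUGS
    roles = {p: "protein" for p in _SHORT_PROTEINS}
    roles.update({"EGF": "stimulus", "HRG": "stimulus"})
    roles.update({d: "drug" for d in DRUGS})
    return NodeRoster(names, roles)


def longterm_roster() -> NodeRoster:
    """21 long-term targets plus the growth-medium stimulus S and the drugs."""
    names = _LONG_PROTEINS + ("S",) + DRUGS
    roles = {p: "protein" for p in _LONG_PROTEINS}
    roles["S"] = "stimulus"
    roles.update({d: "drug" for d in DRUGS})
    return NodeRoster(names, roles)


def _drug_subsets():
    out = []
    for k in range(len(DRUGS) + 1):
        out.extend(frozenset(c) for c in itertools.combinations(DRUGS, k))
    return out


def default_shortterm_design() -> ExperimentDesign:
    """3 stimulus contexts x 8 drug subsets = 24 conditions, 0-60 min.

    Drug-treated conditions carry 3 biological replicates, drug-free ones 5.
    """
    stimuli = (frozenset({"EGF"}), frozenset({"HRG"}), frozenset({"EGF", "HRG"}))
    conditions, reps = [], []
    for s in stimuli:
        for d in _drug_subsets():
            conditions.append((s, d))
            reps.append(5 if not d else 3)
    return ExperimentDesign(tuple(conditions), SHORT_TIMEPOINTS_MIN, "min",
                            tuple(reps))


def default_longterm_design() -> ExperimentDesign:
    """Growth-medium stimulus S; no drug, erlotinib alone, doubles, triple."""
    s = frozenset({"S"})
    drug_sets = (
        frozenset(), frozenset({"E"}),
        frozenset({"E", "P"}), frozenset({"E", "T"}), frozenset({"P", "T"}),
        frozenset({"E", "P", "T"}),
    )
    conditions = tuple((s, d) for d in drug_sets)
    return ExperimentDesign(conditions, LONG_TIMEPOINTS_H, "h",
                            (3,) * len(conditions))


def example_truth_network() -> SignalingNetwork:
    """Small planted ground truth used for recovery benchmarks.

    Two receptor-like proteins gated by stimuli and drugs feed a two-layer
    cascade, so every protein has a distinct on/off pattern across the
    24-condition short-term design and activation times are staggered.
    """
    proteins = ("R1", "R2", "K1", "K2", "O1", "O2")
    names = proteins + ("EGF", "HRG") + DRUGS
    roles = {p: "protein" for p in proteins}
    roles.update({"EGF": "stimulus", "HRG": "stimulus"})
    roles.update({d: "drug" for d in DRUGS})
    roster = NodeRoster(names, roles)
    edges = [
        ("EGF", "R1", 1), ("HRG", "R2", 1),
        ("E", "R1", -1), ("P", "R2", -1), ("T", "K1", -1),
        ("R1", "K1", 1), ("R2", "K2", 1),
        ("K1", "O1", 1), ("K2", "O2", 1),
    ]
    return SignalingNetwork.from_edges(roster, edges)


def default_emission(n_proteins: int, mu0: float = 10.0, mu1: float = 12.0,
                     sigma: float = 0.5) -> EmissionParameters:
    """Generating two-class Gaussians; defaults mimic well-separated
    log-intensities (separation (mu1-mu0)/sigma = 4)."""
    ones = np.ones(n_proteins)
    return EmissionParameters(mu0 * ones, sigma * ones, mu1 * ones, sigma * ones)


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything needed to draw a dataset: truth, design, noise, schedule.

    ``state_schedule`` is "even" (state k_t = ceil(t*M/T), the final state
    held) or "dwell" (random monotone switch times, seeded) for stressing
    the HMM alignment.
    """

    truth_net: SignalingNetwork
    design: ExperimentDesign
    emission: EmissionParameters
    state_schedule: str = "even"
    seed: int = 0

    def __post_init__(self):
        if self.state_schedule not in ("even", "dwell"):
            raise ValueError(f"unknown schedule {self.state_schedule!r}")
        for pset in self.design.perturbation_sets():
            unknown = pset - set(self.truth_net.roster.perturbations)
            if unknown:
                raise ValueError(
                    f"design references unknown perturbations {sorted(unknown)}"
                )


def _even_schedule(M: int, T: int) -> np.ndarray:
    t = np.arange(1, T + 1)
    return np.clip(np.ceil(t * M / T).astype(int), 1, M) - 1


def _dwell_schedule(M: int, T: int, rng) -> np.ndarray:
    if M == 1:
        return np.zeros(T, dtype=int)
    switches = np.sort(rng.choice(np.arange(1, T), size=min(M - 1, T - 1),
                                  replace=False))
    ks = np.zeros(T, dtype=int)
    for s in switches:
        ks[s:] += 1
    return np.clip(ks, 0, M - 1)


def generate_dataset(
    spec: GeneratorSpec,
) -> tuple[PerturbationDataset, StateAssignment]:
    """Draw a dataset plus the generating state assignment (reproducible)."""
    rng = np.random.default_rng(spec.seed)
    roster = spec.truth_net.roster
    design = spec.design
    proteins = roster.proteins
    pidx = np.array([roster.index(p) for p in proteins])
    P, C, T = len(proteins), design.n_conditions, design.n_times
    Rmax = max(design.replicates)

    indices = np.empty((C, T), dtype=int)
    gamma = np.empty((P, C, T), dtype=np.int8)
    for c, pset in enumerate(design.perturbation_sets()):
        traj = propagate_states(spec.truth_net, pset)
        M = traj.n_states
        ks = (_even_schedule(M, T) if spec.state_schedule == "even"
              else _dwell_schedule(M, T, rng))
        if np.any(np.diff(ks) < 0):
            raise ValueError("state schedule produced non-monotone indices")
        indices[c] = ks
        gamma[:, c, :] = traj.states[ks][:, pidx].T

    em = spec.emission
    mu = np.where(gamma.astype(bool), em.mu1[:, None, None], em.mu0[:, None, None])
    sd = np.where(gamma.astype(bool), em.sd1[:, None, None], em.sd0[:, None, None])
    values = rng.normal(mu[..., None], sd[..., None], size=(P, C, T, Rmax))
    for c, r in enumerate(design.replicates):
        values[:, c, :, r:] = np.nan

    data = PerturbationDataset(roster, design, values)
    return data, StateAssignment(indices, gamma)
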