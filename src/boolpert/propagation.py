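"""Deterministic Boolean effects propagation.

Given a signed network and a set of permanently active perturbations
(clamped stimulus/drug nodes), the reachable system states are computed by
synchronous updates from the all-inactive start: a node switches on iff at
least one activating parent is active and no inhibiting parent is active.
The resulting state sequence (the columns of the reachability matrix) is
what the HMM later aligns to the measured time points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .model_core import NodeRoster, SignalingNetwork

__all__ = ["StateTrajectory", "transition_step", "propagate_states",
           "write_trajectory"]


@dataclass(frozen=True)
class StateTrajectory:
    """Reachable system states of a network under one perturbation context.

    ``states`` has shape (M, N): row k is the binary node-state vector after
    k synchronous transitions from the all-inactive start.  ``terminal`` is
    "fixpoint" when the last state maps to itself, otherwise the index of
    the earlier state the sequence re-enters (a cycle).
    """

    condition: frozenset[str]
    roster: NodeRoster
    states: np.ndarray
    terminal: str | int

    def __post_init__(self):
        states = np.asarray(self.states, dtype=np.int8)
        states.setflags(write=False)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "condition", frozenset(self.condition))

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    @property
    def is_fixpoint(self) -> bool:
        return self.terminal == "fixpoint"


def _clamp_indices(roster: NodeRoster, clamped: Iterable[str]) -> np.ndarray:
    idx = []
    pert = set(roster.perturbations)
    for name in clamped:
        if name not in roster.roles:
            raise KeyError(f"unknown node {name!r}")
        if name not in pert:
            raise ValueError(f"node {name!r} is not a stimulus/drug node")
        idx.append(roster.index(name))
    return np.array(sorted(idx), dtype=int)


def transition_step(
    net: SignalingNetwork, state: np.ndarray, clamped: Iterable[str]
) -> np.ndarray:
    """One synchronous update of every node.

    A node with parents becomes active iff some activating parent is active
    and every inhibiting parent is inactive; a parentless, unclamped node
    holds its current value; clamped nodes stay 1.
    """
    state = np.asarray(state, dtype=np.int8)
    if state.shape != (len(net.roster),):
        raise ValueError("state length does not match roster")
    cidx = _clamp_indices(net.roster, clamped)
    adj = net.adjacency
    act = (adj == 1).T @ state > 0            # some activating parent on
    inh = (adj == -1).T @ state > 0           # some inhibiting parent on
    has_parent = np.count_nonzero(adj, axis=0) > 0
    nxt = np.where(has_parent, (act & ~inh), state.astype(bool))
    nxt = nxt.astype(np.int8)
    nxt[cidx] = 1
    return nxt


def propagate_states(
    net: SignalingNetwork, condition: Iterable[str]
) -> StateTrajectory:
    """All reachable system states under a fixed perturbation context.

    Starts from all proteins inactive with the condition's perturbation
    nodes clamped to 1 and iterates :func:`transition_step` until a state
    repeats.  M, the number of distinct states, is bounded by 2**N.
    """
    roster = net.roster
    cidx = _clamp_indices(roster, condition)
    state = np.zeros(len(roster), dtype=np.int8)
    state[cidx] = 1
    seen: dict[bytes, int] = {state.tobytes(): 0}
    states = [state]
    terminal: str | int = "fixpoint"
    while True:
        nxt = transition_step(net, states[-1], condition)
        key = nxt.tobytes()
        if key in seen:
            prev = seen[key]
            terminal = "fixpoint" if prev == len(states) - 1 else prev
            break
        seen[key] = len(states)
        states.append(nxt)
    return StateTrajectory(frozenset(condition), roster,
                           np.vstack(states), terminal)


def _propagate_many(adj: np.ndarray, clamp_indices: list[np.ndarray]
                    ) -> list[np.ndarray]:
    """Reachable-state matrices for several clamp sets at once (fast path).

    Steps all conditions jointly with vectorized updates; per condition the
    sequence ends at its first repeated state.  Used by the MCMC inner loop;
    semantics match :func:`propagate_states`.
    """
    n = adj.shape[0]
    C = len(clamp_indices)
    a_act = (adj == 1).astype(np.int8)
    a_inh = (adj == -1).astype(np.int8)
    has_parent = np.count_nonzero(adj, axis=0) > 0

    states = np.zeros((C, n), dtype=np.int8)
    for c, idx in enumerate(clamp_indices):
        states[c, idx] = 1
    seqs: list[list[np.ndarray]] = [[states[c].copy()] for c in range(C)]
    seen: list[set[bytes]] = [{states[c].tobytes()} for c in range(C)]
    done = np.zeros(C, dtype=bool)
    while not done.all():
        act = (states @ a_act) > 0
        inh = (states @ a_inh) > 0
        nxt = np.where(has_parent[None, :], act & ~inh, states.astype(bool))
        nxt = nxt.astype(np.int8)
        for c, idx in enumerate(clamp_indices):
            nxt[c, idx] = 1
        for c in range(C):
            if done[c]:
                continue
            key = nxt[c].tobytes()
            if key in seen[c]:
                done[c] = True
            else:
                seen[c].add(key)
                seqs[c].append(nxt[c].copy())
        states = nxt
    return [np.vstack(s) for s in seqs]


def write_trajectory(traj: StateTrajectory, path) -> None:
    """Dump a trajectory as a delimited table (one row per state)."""
    df = pd.DataFrame(traj.states, columns=traj.roster.names)
    df.insert(0, "step", np.arange(traj.n_states))
    with open(path, "w") as fh:
        fh.write(f"# condition: {','.join(sorted(traj.condition))}\n")
        fh.write(f"# terminal: {traj.terminal}\n")
        df.to_csv(fh, sep="\t", index=False)
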