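"""Domain types for signed signalling networks and the Laplace structure prior.

A signalling network is a signed directed graph over protein, stimulus and
drug nodes.  Adjacency entries take values in {-1, 0, 1}: ``adjacency[i, j]``
is +1 for an activating edge i -> j, -1 for an inhibiting edge, 0 for no
edge.  Stimulus and drug nodes model external perturbations and may only act
as sources.  The structure prior is a per-edge double-exponential (Laplace)
penalty on the deviation between a sampled edge value and a literature
belief, so that the log-prior of a whole network is the sum of independent
per-edge terms.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NodeRoster",
    "SignalingNetwork",
    "PriorSpec",
    "StructureConstraints",
    "Violation",
    "validate_network",
    "edge_prior_density",
    "network_log_prior",
    "read_roster",
    "write_roster",
    "read_edge_list",
    "write_edge_list",
    "read_adjacency",
    "write_adjacency",
]

ROLES = ("protein", "stimulus", "drug")


@dataclass(frozen=True)
class NodeRoster:
    """Ordered node names with a role (protein / stimulus / drug) for each."""

    names: tuple[str, ...]
    roles: Mapping[str, str]

    def __post_init__(self):
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "roles", dict(self.roles))
        if not names:
            raise ValueError("roster must contain at least one node")
        if len(set(names)) != len(names):
            raise ValueError("node names must be unique")
        missing = [n for n in names if n not in self.roles]
        if missing:
            raise ValueError(f"roles missing for nodes: {missing}")
        bad = {n: r for n, r in self.roles.items() if r not in ROLES}
        if bad:
            raise ValueError(f"unknown roles: {bad}")
        if not any(self.roles[n] == "protein" for n in names):
            raise ValueError("roster must contain at least one protein node")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown node {name!r}") from None

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if self.roles[n] == "protein")

    @property
    def perturbations(self) -> tuple[str, ...]:
        """Stimulus and drug nodes, i.e. the clampable inputs."""
        return tuple(n for n in self.names if self.roles[n] != "protein")

    def perturbation_mask(self) -> np.ndarray:
        return np.array([self.roles[n] != "protein" for n in self.names])


def _as_signed_matrix(adjacency, n: int) -> np.ndarray:
    adj = np.asarray(adjacency)
    if adj.shape != (n, n):
        raise ValueError(f"adjacency must be {n}x{n}, got {adj.shape}")
    if not np.isin(adj, (-1, 0, 1)).all():
        raise ValueError("adjacency entries must be in {-1, 0, 1}")
    return adj.astype(np.int8)


@dataclass(frozen=True)
class SignalingNetwork:
    """Signed directed graph: ``adjacency[i, j]`` is the edge i -> j."""

    roster: NodeRoster
    adjacency: np.ndarray

    def __post_init__(self):
        adj = _as_signed_matrix(self.adjacency, len(self.roster))
        adj.setflags(write=False)
        object.__setattr__(self, "adjacency", adj)

    @classmethod
    def empty(cls, roster: NodeRoster) -> "SignalingNetwork":
        n = len(roster)
        return cls(roster, np.zeros((n, n), dtype=np.int8))

    @classmethod
    def from_edges(
        cls, roster: NodeRoster, edges: Iterable[tuple[str, str, int]]
    ) -> "SignalingNetwork":
        n = len(roster)
        adj = np.zeros((n, n), dtype=np.int8)
        for src, dst, sign in edges:
            if sign not in (-1, 1):
                raise ValueError(f"edge sign must be +-1, got {sign}")
            adj[roster.index(src), roster.index(dst)] = sign
        return cls(roster, adj)

    def edges(self) -> list[tuple[str, str, int]]:
        out = []
        for i, j in zip(*np.nonzero(self.adjacency)):
            out.append((self.roster.names[i], self.roster.names[j],
                        int(self.adjacency[i, j])))
        return out

    def parents(self, node: str, sign: int | None = None) -> tuple[str, ...]:
        j = self.roster.index(node)
        col = self.adjacency[:, j]
        mask = col != 0 if sign is None else col == sign
        return tuple(np.asarray(self.roster.names)[mask])

    def replace_adjacency(self, adjacency) -> "SignalingNetwork":
        return SignalingNetwork(self.roster, adjacency)


@dataclass(frozen=True)
class StructureConstraints:
    """Structural pruning rules applied to every sampled network."""

    max_indegree: int = 4
    forbid_self_loops: bool = True
    perturbation_nodes_source_only: bool = True

    def __post_init__(self):
        if self.max_indegree < 1:
            raise ValueError("max_indegree must be >= 1")


@dataclass(frozen=True)
class Violation:
    rule: str
    nodes: tuple[str, ...]
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.rule}({', '.join(self.nodes)}): {self.detail}"


def validate_network(
    net: SignalingNetwork, constraints: StructureConstraints = StructureConstraints()
) -> list[Violation]:
    """Return one :class:`Violation` per broken structural rule (empty = valid)."""
    adj = net.adjacency
    names = net.roster.names
    out: list[Violation] = []
    if constraints.forbid_self_loops:
        for i in np.nonzero(np.diag(adj))[0]:
            out.append(Violation("self-loop", (names[i],), "self edges are forbidden"))
    if constraints.perturbation_nodes_source_only:
        pmask = net.roster.perturbation_mask()
        for j in np.nonzero(pmask)[0]:
            if np.any(adj[:, j] != 0):
                srcs = [names[i] for i in np.nonzero(adj[:, j])[0]]
                out.append(
                    Violation(
                        "perturbation-ingoing",
                        (names[j],),
                        f"perturbation node has ingoing edges from {srcs}",
                    )
                )
    indeg = np.count_nonzero(adj, axis=0)
    for j in np.nonzero(indeg > constraints.max_indegree)[0]:
        out.append(
            Violation(
                "indegree",
                (names[j],),
                f"indegree {indeg[j]} exceeds {constraints.max_indegree}",
            )
        )
    return out


@dataclass(frozen=True)
class PriorSpec:
    """Laplace structure prior: belief matrix B with scale lambda, exponent gamma.

    The per-edge density is (1/2λ)·exp(-|φ-b|^γ / λ); small λ pins the
    sampler to the belief, large λ flattens the prior.
    """

    roster: NodeRoster
    belief: np.ndarray
    lam: float = 0.0001
    gamma: float = 1.0

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        belief = np.asarray(self.belief, dtype=float)
        n = len(self.roster)
        if belief.shape != (n, n):
            raise ValueError(f"belief must be {n}x{n}, got {belief.shape}")
        if np.any(np.abs(belief) > 1):
            raise ValueError("belief entries must lie in [-1, 1]")
        belief.setflags(write=False)
        object.__setattr__(self, "belief", belief)

    @classmethod
    def from_network(
        cls, net: SignalingNetwork, lam: float = 0.0001, gamma: float = 1.0
    ) -> "PriorSpec":
        return cls(net.roster, net.adjacency.astype(float), lam, gamma)

    def as_network(self) -> SignalingNetwork:
        """Belief matrix as a network; requires integer-valued beliefs."""
        b = self.belief
        if not np.isin(b, (-1.0, 0.0, 1.0)).all():
            raise ValueError("belief has non-integer entries; no exact network form")
        return SignalingNetwork(self.roster, b.astype(np.int8))

    def free_pair_mask(self) -> np.ndarray:
        """Ordered pairs contributing to the prior: off-diagonal, target a protein."""
        n = len(self.roster)
        mask = ~np.eye(n, dtype=bool)
        mask[:, self.roster.perturbation_mask()] = False
        return mask


def edge_prior_density(phi: float, b: float, lam: float, gamma: float) -> float:
    """Laplace edge prior (1/2λ)·exp(-|φ-b|^γ/λ); maximal iff φ equals b."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    delta = abs(phi - b) ** gamma
    return float(np.exp(-delta / lam) / (2.0 * lam))


def network_log_prior(net: SignalingNetwork, prior: PriorSpec) -> float:
    """Sum of per-edge log Laplace densities over all free ordered pairs.

    Pairs whose target is a perturbation node (and the diagonal) are
    structurally fixed to zero and excluded; they would only add a constant.
    """
    if net.roster.names != prior.roster.names:
        raise ValueError("network and prior rosters differ")
    mask = prior.free_pair_mask()
    delta = np.abs(net.adjacency.astype(float) - prior.belief) ** prior.gamma
    logdens = -np.log(2.0 * prior.lam) - delta / prior.lam
    return float(logdens[mask].sum())


# ---------------------------------------------------------------------------
# file I/O: rosters, edge lists, dense adjacencies (all tab-delimited text)

def write_roster(roster: NodeRoster, path) -> None:
    pd.DataFrame(
        {"node": roster.names, "role": [roster.roles[n] for n in roster.names]}
    ).to_csv(path, sep="\t", index=False)


def read_roster(path) -> NodeRoster:
    df = pd.read_csv(path, sep="\t")
    return NodeRoster(tuple(df["node"]), dict(zip(df["node"], df["role"])))


def write_edge_list(net: SignalingNetwork, path) -> None:
    rows = net.edges()
    pd.DataFrame(rows, columns=["source", "target", "type"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path, roster: NodeRoster) -> SignalingNetwork:
    df = pd.read_csv(path, sep="\t")
    edges = [(r.source, r.target, int(r.type)) for r in df.itertuples()]
    return SignalingNetwork.from_edges(roster, edges)


def write_adjacency(net: SignalingNetwork, path) -> None:
    pd.DataFrame(
        net.adjacency, index=net.roster.names, columns=net.roster.names
    ).to_csv(path, sep="\t")


def read_adjacency(path, roster: NodeRoster) -> SignalingNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if tuple(df.index) != roster.names or tuple(df.columns) != roster.names:
        raise ValueError("adjacency header does not match roster order")
    return SignalingNetwork(roster, df.to_numpy())
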