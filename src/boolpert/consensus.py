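"""Consensus-network construction from independent MCMC chains.

Per chain and ordered node pair, the fractions of post-burn-in iterations
sampled as activation and as inhibition are the edge's confidence values.
A two-sided Wilcoxon rank-sum test compares the per-chain activation and
inhibition confidences; after Benjamini-Hochberg adjustment across all
pairs, significant pairs keep the edge type with the larger mean
confidence.  The test is embedded in leave-one-out cross-validation over
chains: an edge enters the final consensus only if it is retained with the
same type in every leave-one-out subset.  Finally, consensus edges absent
from the literature prior are greedily added to it in order of
significance, each kept only if the Boolean steady-state attractors fit the
observed end-of-time-course activity at least as well as before.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .boolean_sim import PerturbationScenario, find_attractors, network_to_rules
from .inhib_mcmc import ChainResult, _free_pairs
from .likelihood_hmm import EmissionParameters, PerturbationDataset
from .model_core import (
    NodeRoster,
    SignalingNetwork,
    StructureConstraints,
    validate_network,
)

__all__ = [
    "EdgeConfidenceTable",
    "ConsensusResult",
    "edge_confidences",
    "consensus_test",
    "loo_consensus",
    "greedy_augment",
    "attractor_fit_score",
    "observed_endpoint_from_data",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeConfidenceTable:
    """Per-chain activation/inhibition sampling fractions, shape (chains, N, N)."""

    roster: NodeRoster
    conf_act: np.ndarray
    conf_inh: np.ndarray

    @property
    def n_chains(self) -> int:
        return self.conf_act.shape[0]


@dataclass(frozen=True)
class ConsensusResult:
    """Cross-validated consensus edges plus the per-subset presence record."""

    edges: pd.DataFrame          # source, target, type, adj_p, mean confidences
    alpha: float
    presence: pd.DataFrame       # one row per (edge, loo-run) candidate


def edge_confidences(chains: Sequence[ChainResult]) -> EdgeConfidenceTable:
    """Sampling fractions count / n_samples per chain and edge type."""
    if len(chains) < 2:
        raise ValueError("need >= 2 chains")
    roster = chains[0].roster
    for ch in chains:
        if ch.roster.names != roster.names:
            raise ValueError("chains disagree on the roster")
        if ch.n_samples == 0:
            raise ValueError("chain with zero post-burn-in samples")
    conf_act = np.stack([ch.count_act / ch.n_samples for ch in chains])
    conf_inh = np.stack([ch.count_inh / ch.n_samples for ch in chains])
    return EdgeConfidenceTable(roster, conf_act, conf_inh)


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p, exact in the small-sample regime.

    Without ties the exact U distribution is used; with ties and <= 10 per
    group, a seeded permutation test (20,000 resamples) approximates the
    tie-respecting exact p; larger samples fall back to the tie-corrected
    normal approximation.
    """
    if np.all(x == y[0]) and np.all(y == y[0]):
        return 1.0  # all tied: the null holds exactly
    # canonical group order so the (Monte Carlo) p is symmetric in x and y
    if tuple(np.sort(y)) < tuple(np.sort(x)):
        x, y = y, x
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= 10 and y.size <= 10:
        if not has_ties:
            method = "exact"
        else:
            method = sstats.PermutationMethod(
                n_resamples=20000, rng=np.random.default_rng(0))
    else:
        method = "asymptotic"
    return float(
        sstats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def consensus_test(
    table: EdgeConfidenceTable,
    alpha: float = 0.05,
    constraints: StructureConstraints = StructureConstraints(),
) -> pd.DataFrame:
    """Wilcoxon + BH edge calls over all free ordered pairs.

    Returns one row per tested pair with columns source, target, raw_p,
    adj_p, mean_conf_act, mean_conf_inh and type in {1, -1, 0} (0 = no
    edge).  Significant pairs get the type with the larger mean confidence.
    """
    roster = table.roster
    pi, pj = _free_pairs(roster, constraints)
    raws = np.empty(pi.size)
    for k in range(pi.size):
        raws[k] = _rank_sum_p(table.conf_act[:, pi[k], pj[k]],
                              table.conf_inh[:, pi[k], pj[k]])
    adj_p = multipletests(raws, method="fdr_bh")[1]
    mean_act = table.conf_act[:, pi, pj].mean(axis=0)
    mean_inh = table.conf_inh[:, pi, pj].mean(axis=0)
    etype = np.where(adj_p <= alpha,
                     np.where(mean_act >= mean_inh, 1, -1), 0)
    names = np.asarray(roster.names)
    return pd.DataFrame({
        "source": names[pi], "target": names[pj],
        "raw_p": raws, "adj_p": adj_p,
        "mean_conf_act": mean_act, "mean_conf_inh": mean_inh,
        "type": etype,
    })


def loo_consensus(
    chains: Sequence[ChainResult],
    alpha: float = 0.05,
    constraints: StructureConstraints = StructureConstraints(),
) -> ConsensusResult:
    """Leave-one-chain-out cross-validated consensus.

    An edge is retained iff it is called significant with the same type in
    every leave-one-out subset; type flips between subsets drop the edge.
    """
    if len(chains) < 3:
        raise ValueError("need >= 3 chains for leave-one-out consensus")
    runs = []
    for left_out in range(len(chains)):
        subset = [ch for k, ch in enumerate(chains) if k != left_out]
        res = consensus_test(edge_confidences(subset), alpha, constraints)
        res.insert(0, "left_out", left_out)
        runs.append(res)
    presence = pd.concat(runs, ignore_index=True)

    sig = presence[presence["type"] != 0]
    kept_rows = []
    for (src, dst), grp in sig.groupby(["source", "target"], sort=False):
        if len(grp) < len(chains):
            continue  # missing from some run
        types = grp["type"].unique()
        if types.size > 1:
            logger.info("edge %s->%s dropped: type flips between runs", src, dst)
            continue
        kept_rows.append({
            "source": src, "target": dst, "type": int(types[0]),
            "adj_p": float(grp["adj_p"].max()),
            "mean_conf_act": float(grp["mean_conf_act"].mean()),
            "mean_conf_inh": float(grp["mean_conf_inh"].mean()),
        })
    edges = pd.DataFrame(
        kept_rows, columns=["source", "target", "type", "adj_p",
                            "mean_conf_act", "mean_conf_inh"]
    )
    return ConsensusResult(edges, alpha, presence)


# ---------------------------------------------------------------------------
# attractor fit and greedy augmentation

def observed_endpoint_from_data(
    data: PerturbationDataset, emission: EmissionParameters
) -> dict[tuple[str, int], int]:
    """Binary end-of-time-course activity per (protein, condition index).

    A protein counts as active in a condition iff its final-time mean
    intensity lies above the midpoint of the optimized class means.
    """
    mid = (emission.mu0 + emission.mu1) / 2.0
    endpoint = np.nanmean(data.values[:, :, -1, :], axis=2)  # (P, C)
    out = {}
    for p_idx, prot in enumerate(data.roster.proteins):
        for c in range(data.design.n_conditions):
            out[(prot, c)] = int(endpoint[p_idx, c] > mid[p_idx])
    return out


def attractor_fit_score(
    net: SignalingNetwork,
    data: PerturbationDataset,
    observed_endpoint: Mapping[tuple[str, int], int],
) -> float:
    """Fraction of (protein, condition) cells whose steady-state attractor
    value matches the observed endpoint; cycling nodes only match if every
    cycle state agrees."""
    inputs = list(net.roster.perturbations)
    rules = network_to_rules(net, inputs)
    matches = 0
    for c, pset in enumerate(data.design.perturbation_sets()):
        fixed = {nd: (1 if nd in pset else 0) for nd in inputs}
        att = find_attractors(rules, PerturbationScenario(fixed))
        for prot in data.roster.proteins:
            vals = set(int(v) for v in att.states[:, net.roster.index(prot)])
            if len(vals) == 1 and vals.pop() == observed_endpoint[(prot, c)]:
                matches += 1
    return matches / (len(data.roster.proteins) * data.design.n_conditions)


def greedy_augment(
    prior_net: SignalingNetwork,
    consensus: ConsensusResult,
    data: PerturbationDataset,
    observed_endpoint: Mapping[tuple[str, int], int],
    constraints: StructureConstraints = StructureConstraints(),
    allow_deletions: bool = False,
) -> SignalingNetwork:
    """Add consensus edges to the prior network in order of significance.

    Candidates (consensus edges absent from the prior) are sorted by
    adjusted p ascending, ties by larger mean confidence then
    lexicographically; each is kept iff the attractor-fit score does not
    drop and the structural constraints still hold.  With
    ``allow_deletions`` prior edges the consensus assigns type 0 with
    adjusted p <= alpha are also tried for removal under the same rule.
    """
    roster = prior_net.roster
    edges = consensus.edges
    cand = []
    for r in edges.itertuples():
        cur = prior_net.adjacency[roster.index(r.source), roster.index(r.target)]
        if r.type != 0 and cur != r.type:
            conf = max(r.mean_conf_act, r.mean_conf_inh)
            cand.append((r.adj_p, -conf, r.source, r.target, int(r.type)))
    cand.sort()

    net = prior_net
    score = attractor_fit_score(net, data, observed_endpoint)
    for adj_p, _negconf, src, dst, etype in cand:
        trial = net.adjacency.copy()
        trial[roster.index(src), roster.index(dst)] = etype
        trial_net = net.replace_adjacency(trial)
        if validate_network(trial_net, constraints):
            logger.info("candidate %s->%s skipped: violates constraints", src, dst)
            continue
        trial_score = attractor_fit_score(trial_net, data, observed_endpoint)
        if trial_score >= score:
            net, score = trial_net, trial_score

    if allow_deletions:
        dele = consensus.presence
        # prior edges the consensus consistently calls absent
        for src, dst, sign in prior_net.edges():
            rows = dele[(dele.source == src) & (dele.target == dst)]
            if len(rows) and (rows["type"] == 0).all():
                trial = net.adjacency.copy()
                trial[roster.index(src), roster.index(dst)] = 0
                trial_net = net.replace_adjacency(trial)
                trial_score = attractor_fit_score(trial_net, data,
                                                  observed_endpoint)
                if trial_score >= score:
                    net, score = trial_net, trial_score
    return net
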