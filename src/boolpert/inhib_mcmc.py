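"""Metropolis-Hastings structure sampling over signed networks.

The sampler proposes single-edge moves that set one free ordered pair to a
different value in {-1, 0, 1} (activation and inhibition edges are sampled
directly), subject to the structural constraints.  Proposals are uniform
over the valid-move set, and because that set's size differs between the
current and the candidate network near constraint boundaries, the exact
Hastings correction |moves(current)| / |moves(candidate)| is applied.

The target density is the product of the HMM data likelihood (the state
alignment is re-optimized per candidate network from its deterministic
initialization, so the likelihood is a pure function of the structure and
can be cached) and the Laplace structure prior.  Multiple independent
chains with derived seeds feed the consensus step; convergence is monitored
with the classic Gelman-Rubin potential scale reduction factor on the
post-burn-in log-posterior traces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .likelihood_hmm import (
    PerturbationDataset,
    _median_split_emission,
    _optimize_with_trajectories,
)
from .model_core import (
    NodeRoster,
    PriorSpec,
    SignalingNetwork,
    StructureConstraints,
    validate_network,
)
from .propagation import _propagate_many

__all__ = [
    "MCMCConfig",
    "ChainResult",
    "GelmanResult",
    "propose_move",
    "run_chain",
    "run_chains",
    "gelman_rubin",
    "random_network",
    "write_chain_results",
    "read_chain_results",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; the defaults are the full-scale run (50,000
    iterations, half burn-in, ten chains)."""

    prior: PriorSpec
    iterations: int = 50000
    burn_in: int = 25000
    chains: int = 10
    seed: int = 0
    constraints: StructureConstraints = field(default_factory=StructureConstraints)
    max_opt_rounds: int = 5
    thin: int = 0  # stored-sample stride; 0 picks ~200 samples
    swap_weight: float = 0.2  # fraction of parent-swap proposals
    anneal_temp0: float = 1.0  # burn-in start temperature (1 = no tempering)
    greedy_init_steps: int = 25  # steepest-ascent mode-finding steps (0 = off)

    def __post_init__(self):
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("need 0 <= burn_in < iterations")
        if self.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")


@dataclass
class ChainResult:
    """Sampling record of one chain.

    ``count_act[i, j]`` / ``count_inh[i, j]`` count post-burn-in iterations
    in which edge i -> j was an activation / inhibition (the current state
    is re-counted on rejection).
    """

    roster: NodeRoster
    count_act: np.ndarray
    count_inh: np.ndarray
    n_samples: int
    log_posterior_trace: np.ndarray
    final_network: SignalingNetwork
    acceptance_rate: float
    seed: int
    status: str = "ok"
    thinned_iterations: np.ndarray | None = None
    thinned_samples: np.ndarray | None = None  # (K, N, N) post-burn-in states


# ---------------------------------------------------------------------------
# proposals

def _free_pairs(roster: NodeRoster, constraints: StructureConstraints):
    n = len(roster)
    mask = np.ones((n, n), dtype=bool)
    if constraints.forbid_self_loops:
        mask &= ~np.eye(n, dtype=bool)
    if constraints.perturbation_nodes_source_only:
        mask[:, roster.perturbation_mask()] = False
    return np.nonzero(mask)


def _count_moves(adj, pi, pj, indeg, max_indeg) -> int:
    cur = adj[pi, pj]
    blocked = (cur == 0) & (indeg[pj] >= max_indeg)
    return int(2 * pi.size - 2 * np.count_nonzero(blocked))


_ALT = {0: (1, -1), 1: (0, -1), -1: (0, 1)}


def _draw_move(adj, pi, pj, indeg, max_indeg, rng):
    """Uniform draw from the valid single-edge move set (by rejection)."""
    npairs = pi.size
    for _ in range(100000):
        r = int(rng.integers(2 * npairs))
        k, alt = divmod(r, 2)
        i, j = int(pi[k]), int(pj[k])
        cur = int(adj[i, j])
        new = _ALT[cur][alt]
        if cur == 0 and new != 0 and indeg[j] >= max_indeg:
            continue
        return i, j, new
    raise RuntimeError("no valid move found; constraints degenerate")


def _swap_state_counts(adj, pi, pj):
    """Per-target eligible-parent bookkeeping for the parent-swap kernel."""
    targets = np.unique(pj)
    eligible = []
    for j in targets:
        rows = pi[pj == j]
        deg = int(np.count_nonzero(adj[rows, j]))
        nfree = rows.size - deg
        if deg >= 1 and nfree >= 1:
            eligible.append((int(j), deg, nfree))
    return eligible


def _draw_swap(adj, pi, pj, rng):
    """Parent swap: move one ingoing edge of a target to a new source.

    Returns (p, q, j, new_sign, n_eligible_targets) or None when no target
    has both a parent and a free source.  The move keeps the indegree of j
    unchanged, so constraints are preserved by construction.
    """
    eligible = _swap_state_counts(adj, pi, pj)
    if not eligible:
        return None
    j, deg, nfree = eligible[int(rng.integers(len(eligible)))]
    rows = pi[pj == j]
    parents = rows[adj[rows, j] != 0]
    free = rows[adj[rows, j] == 0]
    p = int(parents[int(rng.integers(parents.size))])
    q = int(free[int(rng.integers(free.size))])
    sign = 1 if rng.random() < 0.5 else -1
    return p, q, j, sign, len(eligible)


def propose_move(
    net: SignalingNetwork,
    constraints: StructureConstraints,
    rng: np.random.Generator,
) -> tuple[SignalingNetwork, float, float]:
    """One uniform single-edge modification plus its proposal probabilities.

    Returns (candidate, q_forward, q_backward) where each q is
    1 / |valid moves| in the respective state, for the Hastings ratio.
    """
    pi, pj = _free_pairs(net.roster, constraints)
    adj = net.adjacency
    indeg = np.count_nonzero(adj, axis=0)
    n_fwd = _count_moves(adj, pi, pj, indeg, constraints.max_indegree)
    if n_fwd == 0:
        raise RuntimeError("no valid moves; constraints degenerate")
    i, j, new = _draw_move(adj, pi, pj, indeg, constraints.max_indegree, rng)
    cand = adj.copy()
    cand[i, j] = new
    indeg_c = indeg.copy()
    indeg_c[j] = np.count_nonzero(cand[:, j])
    n_back = _count_moves(cand, pi, pj, indeg_c, constraints.max_indegree)
    return net.replace_adjacency(cand), 1.0 / n_fwd, 1.0 / n_back


# ---------------------------------------------------------------------------
# likelihood evaluation (cached per structure)

class _PosteriorEvaluator:
    """Data log-likelihood as a pure, cached function of the adjacency."""

    def __init__(self, data: PerturbationDataset | None, max_opt_rounds: int):
        self.data = data
        self.max_opt_rounds = max_opt_rounds
        self.cache: dict[bytes, float] = {}
        if data is not None:
            self.stats = data.suff_stats()
            self.init_emission = _median_split_emission(data)
            roster = data.roster
            self.clamp_indices = [
                np.array(sorted(roster.index(p) for p in pset), dtype=int)
                for pset in data.design.perturbation_sets()
            ]

    def loglik(self, adj: np.ndarray) -> float:
        if self.data is None:
            return 0.0
        key = adj.tobytes()
        hit = self.cache.get(key)
        if hit is not None:
            return hit
        state_arrays = _propagate_many(adj, self.clamp_indices)
        res = _optimize_with_trajectories(
            state_arrays, self.data, self.max_opt_rounds,
            self.init_emission, stats=self.stats,
        )
        ll = res.log_likelihood
        if len(self.cache) > 300000:
            self.cache.clear()
        self.cache[key] = ll
        return ll


# ---------------------------------------------------------------------------
# chains

def _steepest_ascent(adj, evaluator, belief, lam, gam, pi, pj, max_indeg,
                     max_steps):
    """Deterministic best-improvement hill climb on the log posterior.

    Scans the full single-edge and parent-swap neighborhood each step and
    takes the largest improvement; used as mode-finding initialization
    before sampling (the evaluator cache makes successive scans cheap).
    """
    def log_prior_term(a, i, j):
        return -abs(a[i, j] - belief[i, j]) ** gam / lam

    cur_post = evaluator.loglik(adj)
    cur_post += sum(log_prior_term(adj, int(pi[k]), int(pj[k]))
                    for k in range(pi.size))
    for _ in range(max_steps):
        best_gain, best_adj = 1e-9, None
        for k in range(pi.size):
            i, j = int(pi[k]), int(pj[k])
            cur = int(adj[i, j])
            for new in (v for v in (-1, 0, 1) if v != cur):
                cand = adj.copy()
                cand[i, j] = new
                if np.count_nonzero(cand[:, j]) > max_indeg:
                    continue
                gain = (evaluator.loglik(cand) - evaluator.loglik(adj)
                        + log_prior_term(cand, i, j) - log_prior_term(adj, i, j))
                if gain > best_gain:
                    best_gain, best_adj = gain, cand
        for j in np.unique(pj):
            rows = pi[pj == j]
            parents = rows[adj[rows, j] != 0]
            free = rows[adj[rows, j] == 0]
            for p in parents:
                for q in free:
                    for sign in (1, -1):
                        cand = adj.copy()
                        cand[p, j] = 0
                        cand[q, j] = sign
                        gain = (
                            evaluator.loglik(cand) - evaluator.loglik(adj)
                            + log_prior_term(cand, p, j) - log_prior_term(adj, p, j)
                            + log_prior_term(cand, q, j) - log_prior_term(adj, q, j)
                        )
                        if gain > best_gain:
                            best_gain, best_adj = gain, cand
        if best_adj is None:
            break
        adj = best_adj
    return adj


def run_chain(
    data: PerturbationDataset | None,
    start: SignalingNetwork,
    config: MCMCConfig,
    seed: int | None = None,
    _evaluator: _PosteriorEvaluator | None = None,
) -> ChainResult:
    """One Metropolis-Hastings chain; byte-reproducible given the seed.

    ``data=None`` runs a prior-only chain (flat likelihood), used for
    sampler diagnostics.  ``_evaluator`` lets multiple chains share the
    structure-likelihood cache (the likelihood is a pure function of the
    structure, so sharing does not couple the chains).
    """
    if validate_network(start, config.constraints):
        raise ValueError("start network violates the structural constraints")
    prior = config.prior
    if start.roster.names != prior.roster.names:
        raise ValueError("start network and prior rosters differ")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    evaluator = _evaluator or _PosteriorEvaluator(data, config.max_opt_rounds)

    roster = start.roster
    n = len(roster)
    pi, pj = _free_pairs(roster, config.constraints)
    max_indeg = config.constraints.max_indegree
    belief = prior.belief
    lam, gam = prior.lam, prior.gamma

    adj = start.adjacency.copy()
    if data is not None and config.greedy_init_steps > 0:
        # mode-finding initialization: a deterministic hill climb from the
        # empty network locates the dominant posterior mode (cheap when the
        # evaluator cache is shared across chains); each chain then starts
        # from that mode or its own start, whichever scores higher
        climbed = _steepest_ascent(
            np.zeros_like(adj), evaluator, belief, lam, gam, pi, pj,
            config.constraints.max_indegree, config.greedy_init_steps)

        def _post(a):
            return evaluator.loglik(a) - float(
                (np.abs(a[pi, pj] - belief[pi, pj]) ** gam).sum()) / lam

        if _post(climbed) > _post(adj):
            adj = climbed.copy()
    indeg = np.count_nonzero(adj, axis=0)
    ll = evaluator.loglik(adj)
    free_mask = np.zeros((n, n), dtype=bool)
    free_mask[pi, pj] = True
    lp = float(
        (-np.log(2 * lam) - np.abs(adj - belief) ** gam / lam)[free_mask].sum()
    )

    count_act = np.zeros((n, n), dtype=np.int64)
    count_inh = np.zeros((n, n), dtype=np.int64)
    trace = np.empty(config.iterations)
    n_post = config.iterations - config.burn_in
    thin = config.thin or max(1, n_post // 200)
    thin_iters, thin_samples = [], []
    accepted = 0

    for it in range(config.iterations):
        # tempered burn-in: the posterior difference is scaled by a
        # temperature that decays geometrically from anneal_temp0 to 1 over
        # the burn-in, letting chains cross likelihood barriers early; all
        # retained (post-burn-in) samples are drawn untempered
        if config.anneal_temp0 > 1.0 and it < config.burn_in:
            inv_temp = config.anneal_temp0 ** (-(1.0 - it / config.burn_in))
        else:
            inv_temp = 1.0
        # mixture kernel: uniform single-edge moves plus indegree-preserving
        # parent swaps (the swap's Hastings ratio is exactly 1: the swapped
        # target keeps its parent/free-source counts)
        use_swap = config.swap_weight > 0 and rng.random() < config.swap_weight
        if use_swap:
            draw = _draw_swap(adj, pi, pj, rng)
            if draw is not None:
                p, q, j, sign, _ = draw
                old_p = int(adj[p, j])
                dprior = (
                    abs(old_p - belief[p, j]) ** gam - abs(belief[p, j]) ** gam
                    + abs(belief[q, j]) ** gam - abs(sign - belief[q, j]) ** gam
                ) / lam
                adj[p, j] = 0
                adj[q, j] = sign
                ll_new = evaluator.loglik(adj)
                delta = ((ll_new - ll) + dprior) * inv_temp
                if not np.isfinite(delta):
                    raise FloatingPointError("non-finite posterior difference")
                if math.log(rng.random()) < delta:
                    ll = ll_new
                    lp += dprior
                    accepted += 1
                else:
                    adj[p, j] = old_p
                    adj[q, j] = 0
        else:
            n_fwd = _count_moves(adj, pi, pj, indeg, max_indeg)
            i, j, new = _draw_move(adj, pi, pj, indeg, max_indeg, rng)
            old = int(adj[i, j])
            dprior = (abs(old - belief[i, j]) ** gam
                      - abs(new - belief[i, j]) ** gam) / lam
            adj[i, j] = new
            indeg[j] += (new != 0) - (old != 0)
            n_back = _count_moves(adj, pi, pj, indeg, max_indeg)
            ll_new = evaluator.loglik(adj)
            delta = ((ll_new - ll) + dprior) * inv_temp \
                + math.log(n_fwd) - math.log(n_back)
            if not np.isfinite(delta):
                raise FloatingPointError("non-finite posterior difference")
            if math.log(rng.random()) < delta:
                ll = ll_new
                lp += dprior
                accepted += 1
            else:
                adj[i, j] = old
                indeg[j] += (old != 0) - (new != 0)
        trace[it] = ll + lp
        if it >= config.burn_in:
            count_act += adj == 1
            count_inh += adj == -1
            if (it - config.burn_in) % thin == 0:
                thin_iters.append(it)
                thin_samples.append(adj.copy())

    return ChainResult(
        roster=roster,
        count_act=count_act,
        count_inh=count_inh,
        n_samples=n_post,
        log_posterior_trace=trace,
        final_network=SignalingNetwork(roster, adj.copy()),
        acceptance_rate=accepted / config.iterations,
        seed=seed,
        thinned_iterations=np.array(thin_iters),
        thinned_samples=np.stack(thin_samples) if thin_samples else None,
    )


def random_network(
    roster: NodeRoster,
    constraints: StructureConstraints,
    rng: np.random.Generator,
    probs: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> SignalingNetwork:
    """Sparse random constraint-satisfying network (start-state diversity).

    Each free pair is set to 0/+1/-1 with the given probabilities, then
    columns over the indegree cap drop random excess parents.
    """
    n = len(roster)
    adj = np.zeros((n, n), dtype=np.int8)
    pi, pj = _free_pairs(roster, constraints)
    vals = rng.choice(np.array([0, 1, -1], dtype=np.int8), size=pi.size, p=probs)
    adj[pi, pj] = vals
    for j in range(n):
        parents = np.nonzero(adj[:, j])[0]
        excess = parents.size - constraints.max_indegree
        if excess > 0:
            drop = rng.choice(parents, size=excess, replace=False)
            adj[drop, j] = 0
    return SignalingNetwork(roster, adj)


def default_starts(
    roster: NodeRoster, config: MCMCConfig, rng: np.random.Generator
) -> list[SignalingNetwork]:
    """One empty network plus chains-1 random constraint-satisfying ones."""
    starts = [SignalingNetwork.empty(roster)]
    for _ in range(config.chains - 1):
        starts.append(random_network(roster, config.constraints, rng))
    return starts


def run_chains(
    data: PerturbationDataset | None,
    config: MCMCConfig,
    starts: Sequence[SignalingNetwork] | None = None,
) -> list[ChainResult]:
    """Independent chains with per-chain seeds derived from the base seed."""
    ss = np.random.SeedSequence(config.seed)
    start_rng = np.random.default_rng(ss.spawn(1)[0])
    roster = config.prior.roster
    if starts is None:
        starts = default_starts(roster, config, start_rng)
    if len(starts) != config.chains:
        raise ValueError("need one start network per chain")
    chain_seeds = [int(s.generate_state(1, np.uint32)[0]) for s in
                   np.random.SeedSequence(config.seed + 1).spawn(config.chains)]
    evaluator = _PosteriorEvaluator(data, config.max_opt_rounds)
    results = []
    for start, seed in zip(starts, chain_seeds):
        try:
            results.append(run_chain(data, start, config, seed=seed,
                                     _evaluator=evaluator))
        except (FloatingPointError, RuntimeError) as exc:  # partial results
            warnings.warn(f"chain with seed {seed} aborted: {exc}")
            results.append(
                ChainResult(
                    roster=roster,
                    count_act=np.zeros_like(start.adjacency, dtype=np.int64),
                    count_inh=np.zeros_like(start.adjacency, dtype=np.int64),
                    n_samples=0,
                    log_posterior_trace=np.array([]),
                    final_network=start,
                    acceptance_rate=float("nan"),
                    seed=seed,
                    status=f"aborted: {exc}",
                )
            )
    return results


# ---------------------------------------------------------------------------
# convergence

@dataclass(frozen=True)
class GelmanResult:
    psrf: float
    converged: bool
    degenerate: bool = False


def gelman_rubin(traces: Sequence[np.ndarray], threshold: float = 1.1
                 ) -> GelmanResult:
    """Classic potential scale reduction factor on per-chain traces.

    PSRF = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B the between-chain variance of the chain means.
    """
    arr = np.asarray(traces, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 equal-length traces")
    m, n = arr.shape
    if n < 10:
        raise ValueError("traces too short for the diagnostic")
    W = arr.var(axis=1, ddof=1).mean()
    B = n * arr.mean(axis=1).var(ddof=1)
    if W == 0:
        return GelmanResult(1.0, True, degenerate=True)
    var_hat = (n - 1) / n * W + B / n
    psrf = float(np.sqrt(var_hat / W))
    return GelmanResult(psrf, psrf < threshold)


# ---------------------------------------------------------------------------
# persistence (plain delimited text plus a YAML manifest)

def write_chain_results(results: Sequence[ChainResult], config: MCMCConfig,
                        outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    roster = results[0].roster
    files = []
    for k, res in enumerate(results):
        name = f"chain_{k:02d}"
        rows = []
        for i, src in enumerate(roster.names):
            for j, dst in enumerate(roster.names):
                if i == j:
                    continue
                rows.append((src, dst, int(res.count_act[i, j]),
                             int(res.count_inh[i, j]), res.n_samples))
        pd.DataFrame(
            rows, columns=["source", "target", "n_act", "n_inh", "n_samples"]
        ).to_csv(outdir / f"{name}_edges.tsv", sep="\t", index=False)
        stride = max(1, res.log_posterior_trace.size // 1000)
        tr = res.log_posterior_trace[::stride]
        pd.DataFrame({
            "iteration": np.arange(res.log_posterior_trace.size)[::stride],
            "log_posterior": tr,
        }).to_csv(outdir / f"{name}_trace.tsv", sep="\t", index=False)
        files.append({"chain": k, "seed": res.seed, "status": res.status,
                      "acceptance_rate": None if np.isnan(res.acceptance_rate)
                      else float(res.acceptance_rate)})
    manifest = {
        "nodes": list(roster.names),
        "roles": {n: roster.roles[n] for n in roster.names},
        "config": {
            "iterations": config.iterations,
            "burn_in": config.burn_in,
            "chains": config.chains,
            "seed": config.seed,
            "lambda": config.prior.lam,
            "gamma": config.prior.gamma,
            "max_indegree": config.constraints.max_indegree,
        },
        "chains": files,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_chain_results(outdir, roster: NodeRoster) -> list[ChainResult]:
    """Rebuild the consensus-relevant parts (edge counts) of saved chains."""
    outdir = Path(outdir)
    with open(outdir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    n = len(roster)
    results = []
    for entry in manifest["chains"]:
        k = entry["chain"]
        df = pd.read_csv(outdir / f"chain_{k:02d}_edges.tsv", sep="\t")
        count_act = np.zeros((n, n), dtype=np.int64)
        count_inh = np.zeros((n, n), dtype=np.int64)
        n_samples = 0
        for r in df.itertuples():
            i, j = roster.index(r.source), roster.index(r.target)
            count_act[i, j] = r.n_act
            count_inh[i, j] = r.n_inh
            n_samples = int(r.n_samples)
        tr = pd.read_csv(outdir / f"chain_{k:02d}_trace.tsv", sep="\t")
        results.append(
            ChainResult(
                roster=roster, count_act=count_act, count_inh=count_inh,
                n_samples=n_samples,
                log_posterior_trace=tr["log_posterior"].to_numpy(),
                final_network=SignalingNetwork.empty(roster),
                acceptance_rate=entry.get("acceptance_rate") or float("nan"),
                seed=entry["seed"], status=entry.get("status", "ok"),
            )
        )
    return results
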