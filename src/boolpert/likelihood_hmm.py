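"""Gaussian-HMM alignment of Boolean trajectories to measured time courses.

Each protein's measurements are modelled as draws from one of two Gaussians
(active / passive class).  For a candidate network, the reachable Boolean
states of every perturbation condition (the trajectory) form the HMM's state
inventory; a monotone dynamic program picks, per condition, the state index
sequence over time that maximizes the summed Gaussian emission
log-densities.  Emission parameters are the per-class empirical mean and
standard deviation, re-estimated by coordinate ascent.

The data likelihood of a network is the summed log-density of every
intensity cell under its assigned class, which is the quantity the
structure MCMC scores against the prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .model_core import NodeRoster, SignalingNetwork
from .propagation import StateTrajectory, propagate_states

__all__ = [
    "ExperimentDesign",
    "PerturbationDataset",
    "EmissionParameters",
    "StateAssignment",
    "estimate_emission_parameters",
    "assign_states",
    "data_log_likelihood",
    "optimize_states",
    "read_tidy_table",
    "write_tidy_table",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ExperimentDesign:
    """Perturbation conditions, common time grid and replicate counts.

    Each condition is a pair (stimuli, drugs) of perturbation-node name
    sets; ``replicates[c]`` is the replicate count of condition c at every
    time point.
    """

    conditions: tuple[tuple[frozenset[str], frozenset[str]], ...]
    timepoints: tuple[float, ...]
    time_unit: str
    replicates: tuple[int, ...]

    def __post_init__(self):
        conds = tuple(
            (frozenset(s), frozenset(d)) for s, d in self.conditions
        )
        object.__setattr__(self, "conditions", conds)
        object.__setattr__(self, "timepoints", tuple(float(t) for t in self.timepoints))
        object.__setattr__(self, "replicates", tuple(int(r) for r in self.replicates))
        if len(self.timepoints) < 2:
            raise ValueError("need at least two time points")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if len(set(conds)) != len(conds):
            raise ValueError("conditions must be unique")
        if len(self.replicates) != len(conds):
            raise ValueError("one replicate count per condition required")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_times(self) -> int:
        return len(self.timepoints)

    def perturbation_sets(self) -> list[frozenset[str]]:
        """Active perturbation nodes (stimuli plus drugs) per condition."""
        return [s | d for s, d in self.conditions]

    def condition_labels(self) -> list[str]:
        out = []
        for s, d in self.conditions:
            stim = "+".join(sorted(s)) or "none"
            drug = "+".join(sorted(d)) or "none"
            out.append(f"{stim}|{drug}")
        return out


@dataclass(frozen=True)
class PerturbationDataset:
    """Intensity tensor (protein, condition, time, replicate), NaN-padded.

    ``values`` has shape (P, C, T, Rmax) where P runs over the roster's
    protein nodes in roster order; missing replicates are NaN.
    """

    roster: NodeRoster
    design: ExperimentDesign
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        P = len(self.roster.proteins)
        C, T = self.design.n_conditions, self.design.n_times
        if vals.ndim != 4 or vals.shape[:3] != (P, C, T):
            raise ValueError(
                f"values must have shape ({P}, {C}, {T}, Rmax), got {vals.shape}"
            )
        if np.isinf(vals).any():
            raise ValueError("intensities must be finite")
        counts = np.isfinite(vals).sum(axis=3)
        if (counts < 1).any():
            raise ValueError("every (protein, condition, time) needs >=1 replicate")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    def suff_stats(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-cell replicate count, sum and sum of squares, shape (P, C, T)."""
        finite = np.isfinite(self.values)
        n = finite.sum(axis=3).astype(float)
        s1 = np.nansum(self.values, axis=3)
        s2 = np.nansum(self.values**2, axis=3)
        return n, s1, s2


@dataclass(frozen=True)
class EmissionParameters:
    """Two-class Gaussian parameters per protein (passive=0, active=1)."""

    mu0: np.ndarray
    sd0: np.ndarray
    mu1: np.ndarray
    sd1: np.ndarray

    def __post_init__(self):
        for name in ("mu0", "sd0", "mu1", "sd1"):
            arr = np.asarray(getattr(self, name), dtype=float)
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        if (self.sd0 <= 0).any() or (self.sd1 <= 0).any():
            raise ValueError("standard deviations must be positive")


@dataclass(frozen=True)
class StateAssignment:
    """Per-condition monotone state-index sequences and implied classes.

    ``indices[c, t]`` indexes into condition c's trajectory; ``gamma`` is
    the implied binary class per (protein, condition, time), shared across
    replicates.
    """

    indices: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        gam = np.asarray(self.gamma, dtype=np.int8)
        if np.any(np.diff(idx, axis=1) < 0):
            raise ValueError("state indices must be non-decreasing over time")
        idx.setflags(write=False)
        gam.setflags(write=False)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "gamma", gam)


def sigma_floor(values: np.ndarray) -> float:
    """Scale-aware lower bound on emission standard deviations."""
    vrange = float(np.nanmax(values) - np.nanmin(values))
    return max(1e-6 * vrange, 1e-12)


# ---------------------------------------------------------------------------
# emission parameter estimation

def _estimate_from_stats(n, s1, s2, gamma, floor):
    """Class-wise MLE mean/sd from per-cell sufficient statistics."""
    g = gamma.astype(float)
    n1 = (n * g).sum(axis=(1, 2))
    n0 = (n * (1.0 - g)).sum(axis=(1, 2))
    s1_1 = (s1 * g).sum(axis=(1, 2))
    s1_0 = (s1 * (1.0 - g)).sum(axis=(1, 2))
    s2_1 = (s2 * g).sum(axis=(1, 2))
    s2_0 = (s2 * (1.0 - g)).sum(axis=(1, 2))

    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = s1_0 / n0
        mu1 = s1_1 / n1
        var0 = s2_0 / n0 - mu0**2
        var1 = s2_1 / n1 - mu1**2
    sd0 = np.sqrt(np.clip(var0, 0.0, None))
    sd1 = np.sqrt(np.clip(var1, 0.0, None))

    # identifiability: the active class carries the larger mean.  Where a
    # labelling inverts the order, project both means onto the pooled mean
    # (the order-constrained estimate), which removes any advantage of
    # intensity-inverted state patterns.
    with np.errstate(invalid="ignore", divide="ignore"):
        viol = (n0 > 0) & (n1 > 0) & (mu1 < mu0)
        if viol.any():
            pooled = (s1_0 + s1_1) / (n0 + n1)
            v0 = s2_0 / n0 - 2 * pooled * s1_0 / n0 + pooled**2
            v1 = s2_1 / n1 - 2 * pooled * s1_1 / n1 + pooled**2
            mu0 = np.where(viol, pooled, mu0)
            mu1 = np.where(viol, pooled, mu1)
            sd0 = np.where(viol, np.sqrt(np.clip(v0, 0.0, None)), sd0)
            sd1 = np.where(viol, np.sqrt(np.clip(v1, 0.0, None)), sd1)

    # degenerate labelling: one class empty for some protein -> borrow the
    # other class's sd and push the mean one pooled sd away
    empty0 = n0 == 0
    empty1 = n1 == 0
    if empty0.any() or empty1.any():
        warnings.warn("empty emission class for some protein; using fallback")
        pooled = np.where(empty0, sd1, sd0)
        pooled = np.maximum(pooled, floor)
        mu0 = np.where(empty0, mu1 - pooled, mu0)
        sd0 = np.where(empty0, sd1, sd0)
        mu1 = np.where(empty1, mu0 + pooled, mu1)
        sd1 = np.where(empty1, sd0, sd1)
    sd0 = np.maximum(sd0, floor)
    sd1 = np.maximum(sd1, floor)
    return EmissionParameters(mu0, sd0, mu1, sd1)


def estimate_emission_parameters(
    data: PerturbationDataset, assignment: StateAssignment
) -> EmissionParameters:
    """Empirical per-class mean/sd over all cells with that class label.

    Uses the maximum-likelihood (population) standard deviation so that the
    coordinate-ascent likelihood never decreases at this step; sds are
    floored at a scale-aware epsilon.
    """
    n, s1, s2 = data.suff_stats()
    return _estimate_from_stats(n, s1, s2, assignment.gamma, sigma_floor(data.values))


def _median_split_emission(data: PerturbationDataset) -> EmissionParameters:
    """Deterministic initialization: per-protein split at the median."""
    floor = sigma_floor(data.values)
    P = data.n_proteins
    mu0 = np.empty(P); sd0 = np.empty(P); mu1 = np.empty(P); sd1 = np.empty(P)
    for i in range(P):
        v = data.values[i][np.isfinite(data.values[i])]
        med = np.median(v)
        lo, hi = v[v <= med], v[v > med]
        if hi.size == 0:  # constant data
            lo, hi = v, v
        mu0[i], sd0[i] = lo.mean(), max(lo.std(), floor)
        mu1[i], sd1[i] = hi.mean(), max(hi.std(), floor)
    return EmissionParameters(mu0, sd0, mu1, sd1)


# ---------------------------------------------------------------------------
# state assignment (monotone DP)

def _cell_class_loglik(n, s1, s2, emission):
    """Summed-over-replicates Gaussian log-density per cell and class.

    Returns (L0, L1), each shape (P, C, T), using the identity
    sum_r log N(d_r; mu, sd) = -n/2 log(2 pi sd^2) - (S2 - 2 mu S1 + n mu^2)/(2 sd^2).
    """
    out = []
    for mu, sd in ((emission.mu0, emission.sd0), (emission.mu1, emission.sd1)):
        mu = mu[:, None, None]
        var = (sd**2)[:, None, None]
        quad = s2 - 2.0 * mu * s1 + n * mu**2
        out.append(-0.5 * n * (_LOG_2PI + np.log(var)) - quad / (2.0 * var))
    return out[0], out[1]


def _dp_monotone(E: np.ndarray) -> np.ndarray:
    """Best monotone non-decreasing state sequence for an (M, T) score grid.

    Returns the lexicographically smallest sequence among (tolerance-tied)
    maximizers of sum_t E[k_t, t] subject to k_1 <= ... <= k_T.
    """
    return _dp_monotone_batch(E[None, :, :])[0]


@njit(cache=True)
def _dp_kernel(E: np.ndarray, Ms: np.ndarray):
    """Monotone DP over a padded (C, M, T) score tensor.

    Returns the (C, T) index matrix (lexicographically smallest optimum per
    condition, ties within a small relative tolerance) and the per-condition
    optimal score.
    """
    C, M, T = E.shape
    ks = np.zeros((C, T), dtype=np.int64)
    vals = np.zeros(C)
    S = np.empty((M, T))
    for c in range(C):
        m = Ms[c]
        for k in range(m):
            S[k, T - 1] = E[c, k, T - 1]
        for t in range(T - 2, -1, -1):
            smax = -1e300
            for k in range(m - 1, -1, -1):
                if S[k, t + 1] > smax:
                    smax = S[k, t + 1]
                S[k, t] = E[c, k, t] + smax
        lo = 0
        for t in range(T):
            mx = -1e300
            for k in range(lo, m):
                if S[k, t] > mx:
                    mx = S[k, t]
            if t == 0:
                vals[c] = mx
            tol = 1e-9 * (1.0 + abs(mx))
            for k in range(lo, m):
                if S[k, t] >= mx - tol:
                    lo = k
                    break
            ks[c, t] = lo
    return ks, vals


def _dp_monotone_batch(E: np.ndarray) -> np.ndarray:
    """Monotone DP over a (C, M, T) score tensor -> (C, T) indices."""
    C, M, T = E.shape
    Ms = np.full(C, M, dtype=np.int64)
    ks, _ = _dp_kernel(np.ascontiguousarray(E, dtype=np.float64), Ms)
    return ks


def assign_states(
    trajectories: Sequence[StateTrajectory] | Mapping[int, StateTrajectory],
    data: PerturbationDataset,
    emission: EmissionParameters,
) -> StateAssignment:
    """Monotone maximum-emission state sequence per condition.

    ``trajectories`` is ordered like the design's conditions.  Ties break
    toward the smaller state index.
    """
    if isinstance(trajectories, Mapping):
        trajectories = [trajectories[c] for c in range(data.design.n_conditions)]
    n, s1, s2 = data.suff_stats()
    L0, L1 = _cell_class_loglik(n, s1, s2, emission)
    pidx = np.array([data.roster.index(p) for p in data.roster.proteins])
    return _assign_from_logliks([t.states for t in trajectories], pidx, data, L0, L1)


def _assign_from_logliks(state_arrays, pidx, data, L0, L1):
    """DP assignment from per-condition raw state matrices (fast path).

    The per-condition emission grids are padded to a common state count and
    the monotone DP runs batched over all conditions at once.
    """
    C, T = data.design.n_conditions, data.design.n_times
    P = data.n_proteins
    Ms = np.array([s.shape[0] for s in state_arrays])
    Mmax = int(Ms.max())
    G = np.zeros((C, Mmax, P))
    for c, states in enumerate(state_arrays):
        G[c, : Ms[c]] = states[:, pidx]
    # E[c,k,t] = sum_p (G L1 + (1-G) L0) = G @ (L1-L0) + sum_p L0
    E = G @ (L1 - L0).transpose(1, 0, 2)
    E += L0.sum(axis=0)[:, None, :]
    pad = np.arange(Mmax)[None, :] >= Ms[:, None]
    E[pad] = -np.inf
    indices = _dp_monotone_batch(E)
    gamma = np.empty((P, C, T), dtype=np.int8)
    for c, states in enumerate(state_arrays):
        gamma[:, c, :] = states[indices[c]][:, pidx].T
    return StateAssignment(indices, gamma)


def data_log_likelihood(
    data: PerturbationDataset,
    assignment: StateAssignment,
    emission: EmissionParameters,
) -> float:
    """Summed Gaussian log-density of every intensity cell under its class."""
    n, s1, s2 = data.suff_stats()
    L0, L1 = _cell_class_loglik(n, s1, s2, emission)
    g = assignment.gamma
    return float((g * L1 + (1 - g) * L0).sum())


# ---------------------------------------------------------------------------
# coordinate ascent

@dataclass
class OptimizeResult:
    assignment: StateAssignment
    emission: EmissionParameters
    log_likelihood: float
    trace: list[float] = field(default_factory=list)
    converged: bool = True


def optimize_states(
    net: SignalingNetwork,
    data: PerturbationDataset,
    max_rounds: int = 10,
    init_emission: EmissionParameters | None = None,
) -> OptimizeResult:
    """Alternate state assignment and emission re-estimation until stable.

    Starts from a per-protein median split (or a supplied warm-start
    emission) and returns the best assignment/parameters seen; the reported
    per-round likelihood trace is non-decreasing because the loop stops at
    the first non-improving round.
    """
    psets = data.design.perturbation_sets()
    trajectories = [propagate_states(net, ps) for ps in psets]
    return _optimize_with_trajectories(
        [t.states for t in trajectories], data, max_rounds, init_emission
    )


def _optimize_with_trajectories(state_arrays, data, max_rounds, init_emission,
                                stats=None):
    n, s1, s2 = stats if stats is not None else data.suff_stats()
    floor = sigma_floor(data.values)
    pidx = np.array([data.roster.index(p) for p in data.roster.proteins])
    emission = (init_emission if init_emission is not None
                else _median_split_emission(data))

    C, T = data.design.n_conditions, data.design.n_times
    P = data.n_proteins
    Ms = np.array([s.shape[0] for s in state_arrays], dtype=np.int64)
    Mmax = int(Ms.max())
    G = np.zeros((C, Mmax, P))
    for c, states in enumerate(state_arrays):
        G[c, : Ms[c]] = states[:, pidx]

    best = None
    trace: list[float] = []
    prev_ks = None
    converged = False
    for _ in range(max_rounds):
        # the DP's optimal score equals the data log-likelihood of the
        # returned assignment under the current emission parameters
        L0, L1 = _cell_class_loglik(n, s1, s2, emission)
        E = G @ (L1 - L0).transpose(1, 0, 2)
        E += L0.sum(axis=0)[:, None, :]
        ks, vals = _dp_kernel(E, Ms)
        ll = float(vals.sum())
        gamma = np.empty((P, C, T), dtype=np.int8)
        for c, states in enumerate(state_arrays):
            gamma[:, c, :] = states[ks[c]][:, pidx].T
        if best is not None and ll < best.log_likelihood:
            break  # sd floor can break exact ascent; keep the best round
        best = OptimizeResult(StateAssignment(ks, gamma), emission, ll)
        trace.append(ll)
        if prev_ks is not None and np.array_equal(prev_ks, ks):
            converged = True
            break
        prev_ks = ks
        emission = _estimate_from_stats(n, s1, s2, gamma, floor)
    best.trace = trace
    best.converged = converged or len(trace) < max_rounds
    return best


# ---------------------------------------------------------------------------
# tidy-table I/O

_TIDY_COLUMNS = ["protein", "condition", "stimuli", "drugs", "time",
                 "replicate", "value"]


def write_tidy_table(data: PerturbationDataset, path) -> None:
    labels = data.design.condition_labels()
    rows = []
    for ci, (s, d) in enumerate(data.design.conditions):
        stim = "+".join(sorted(s))
        drug = "+".join(sorted(d))
        for pi, prot in enumerate(data.roster.proteins):
            for ti, t in enumerate(data.design.timepoints):
                for r in range(data.values.shape[3]):
                    v = data.values[pi, ci, ti, r]
                    if np.isfinite(v):
                        rows.append((prot, labels[ci], stim, drug, t, r + 1, v))
    pd.DataFrame(rows, columns=_TIDY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tidy_table(path, roster: NodeRoster, time_unit: str = "min"
                    ) -> PerturbationDataset:
    """Read a tidy intensity table and validate design completeness."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     na_values=[""], dtype={"stimuli": str, "drugs": str})
    missing_cols = set(_TIDY_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"tidy table missing columns: {sorted(missing_cols)}")

    def _split(s):
        s = "" if pd.isna(s) else str(s)
        return frozenset(x for x in s.split("+") if x)

    cond_df = df[["condition", "stimuli", "drugs"]].drop_duplicates("condition")
    conditions = []
    for r in cond_df.itertuples():
        conditions.append((_split(r.stimuli), _split(r.drugs)))
    timepoints = tuple(sorted(df["time"].unique()))
    labels = list(cond_df["condition"])
    reps = tuple(
        int(df[df["condition"] == lab]["replicate"].max()) for lab in labels
    )
    design = ExperimentDesign(tuple(conditions), timepoints, time_unit, reps)

    proteins = roster.proteins
    unknown = set(df["protein"]) - set(proteins)
    if unknown:
        raise ValueError(f"unknown proteins in table: {sorted(unknown)}")
    P, C, T = len(proteins), len(conditions), len(timepoints)
    Rmax = max(reps)
    values = np.full((P, C, T, Rmax), np.nan)
    pmap = {p: i for i, p in enumerate(proteins)}
    cmap = {lab: i for i, lab in enumerate(labels)}
    tmap = {t: i for i, t in enumerate(timepoints)}
    for r in df.itertuples():
        values[pmap[r.protein], cmap[r.condition], tmap[r.time],
               int(r.replicate) - 1] = r.value

    incomplete = np.isfinite(values).sum(axis=3) < 1
    if incomplete.any():
        pi, ci, ti = map(lambda a: a[0], np.nonzero(incomplete))
        raise ValueError(
            "missing cells, e.g. protein "
            f"{proteins[pi]!r} condition {labels[ci]!r} time {timepoints[ti]}"
        )
    return PerturbationDataset(roster, design, values)
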