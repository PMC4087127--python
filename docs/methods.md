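# Methods

## Model

A signalling network is a signed directed graph over protein, stimulus and
drug nodes: `adjacency[i, j] ∈ {−1, 0, 1}` encodes inhibition, absence or
activation of the edge i → j. Perturbations (stimuli and drugs) are nodes
like any other but may only act as sources. Sampled structures obey three
constraints throughout: no self-loops, indegree at most 4, and no edges
into perturbation nodes.

**Effects propagation.** Given a network and a set of clamped (permanently
active) perturbations, system dynamics are Boolean and deterministic: from
the all-inactive start, a node with parents becomes active iff at least one
activating parent is active and no inhibiting parent is; parentless nodes
hold their value; all nodes update synchronously. Iterating until a state
repeats yields the reachable state sequence Γ (at most 2^N states; in
practice a handful). The update order within a transition is a modelling
choice — synchronous updating is used because Γ serves only as a state
inventory, not as a timing model.

**Likelihood.** Each protein i has passive and active Gaussian intensity
classes, `N(μ_i0, σ_i0)` and `N(μ_i1, σ_i1)`. For a candidate network, each
condition's measured time points are aligned to its trajectory by a
monotone dynamic program: the state index sequence k_1 ≤ … ≤ k_T maximizing
the summed emission log-densities, ties broken toward the smaller index
(lexicographically smallest optimum; a relative tolerance of 1e-9 treats
numerically equal scores as ties). Monotone progression reflects forward
signal propagation from the resting start and makes the program exact in
O(M·T) per condition. HMM transition weights are uniform over allowed moves
(stay or advance), so only emissions drive the alignment; replicates share
the state of their (protein, time) cell.

Emission parameters are the per-class empirical means and maximum-
likelihood (population) standard deviations of all cells assigned to the
class — the MLE choice makes each re-estimation step a true ascent of the
likelihood. Standard deviations are floored at
`max(1e-6 × intensity range, 1e-12)`. Two safeguards handle degenerate
labelings: (1) *orientation* — the active class must not have the smaller
mean; where a labeling inverts the order, both class means are projected
onto the pooled mean (the order-constrained estimate), which removes any
likelihood advantage of intensity-inverted state patterns and resolves a
label-switching unidentifiability that otherwise fragments the posterior;
(2) *empty classes* — a protein with all cells in one class reuses the
other class's spread with the mean pushed one pooled standard deviation
away, keeping the likelihood finite while penalizing the labeling.

The alignment and the emission parameters are optimized by coordinate
ascent from a deterministic per-protein median-split initialization, until
the assignment stabilizes (at most 5 rounds inside the sampler; the best
round is returned, so the reported trace is non-decreasing even when the
standard-deviation floor perturbs exact ascent). Because the
initialization is deterministic, the data log-likelihood is a pure function
of the network structure and is memoized across the MCMC run.

## Structure sampling

The sampler targets `P(Φ | D) ∝ P(D | Φ) · P(Φ | B, λ, γ)` with the
per-edge Laplace prior `(1/2λ) exp(−|φ_ij − b_ij|^γ / λ)` multiplied over
all free ordered pairs (pairs into perturbation nodes are structurally zero
and contribute only a constant, so they are excluded). Defaults follow the
full-scale setting: λ = 0.0001 (a prior this tight effectively pins edges
to the belief unless the data strongly disagree), γ = 1, 50,000 iterations
with the first half as burn-in, ten chains (one started from the empty
network, nine from sparse random constraint-satisfying networks drawn with
edge probabilities 0.8/0.1/0.1 for 0/+1/−1 and repaired to the indegree
cap).

Proposals mix two reversible kernels:

* **Single-edge moves** (default 80%): pick uniformly among all valid
  modifications that set one free pair to a different value in {−1, 0, 1}.
  Because the valid-move count differs between current and candidate state
  near the indegree boundary, the exact Hastings factor
  |moves(current)| / |moves(candidate)| is applied.
* **Parent swaps** (default 20%): move one incoming edge of a target to a
  new source, keeping the sign free and the indegree unchanged. The
  swapped target retains its parent and free-source counts, so the
  proposal is exactly symmetric (Hastings ratio 1). Swaps let the sampler
  exchange a misattributed parent in one step instead of through a
  low-probability two-step valley.

**Mode-finding initialization.** Posterior landscapes of near-noiseless
Boolean likelihoods are extremely peaked: single-move acceptance ratios
span hundreds of log-units, and plain Metropolis–Hastings behaves like a
randomized hill climb that can wedge into local optima. Each chain
therefore first runs a deterministic steepest-ascent climb (full
single-move and swap neighborhood, best improvement, at most 25 steps) from
the empty network, and starts sampling from that mode or from its own
start network, whichever scores higher. This is initialization only — the
post-burn-in samples come from the untempered kernel and their stationary
distribution is unchanged. An optional geometric burn-in tempering
schedule (`anneal_temp0`) exists but is off by default; in testing it
mixed worse than mode-finding at these scales. All chains in a run share
the structure-likelihood memo table, which is sound because the likelihood
is a pure function of the structure.

Edge confidences are the per-chain fractions of post-burn-in iterations in
which a pair was sampled as activation resp. inhibition (the current state
is re-counted when a proposal is rejected). The "total number of sampled
edges" normalizer is interpreted per edge as the post-burn-in iteration
count, giving fractions in [0, 1] comparable across chains. Convergence is
monitored with the classic Gelman–Rubin PSRF on the post-burn-in
log-posterior traces (threshold 1.1).

## Consensus and augmentation

For every free pair, the ten per-chain activation confidences are compared
with the ten inhibition confidences by a two-sided Wilcoxon rank-sum test:
exact (U distribution) without ties, a seeded 20,000-resample permutation
test with ties at n ≤ 10 per group (ties at confidence 0 are the norm), and
the tie-corrected normal approximation for larger samples. P-values are
Benjamini–Hochberg adjusted across pairs; significant pairs (α = 0.05) take
the type with the larger mean confidence. The test is embedded in
leave-one-chain-out cross-validation: an edge enters the consensus only if
called with the same type in every subset.

Consensus edges absent from the prior network are then greedily added in
order of adjusted p (ties: larger mean confidence, then lexicographic).
Each candidate is kept iff the constraints still hold and the
*attractor-fit score* — the fraction of (protein, condition) cells whose
Boolean steady-state value matches the observed endpoint — does not
decrease. The observed endpoint discretizes each protein's final-time mean
intensity per condition at the midpoint of its optimized class means.
Cycling attractors count as matches only when every cycle state agrees.
Prior-edge deletions are reported but applied only under an explicit
`allow_deletions` flag, since the default workflow treats the literature
network as trustworthy.

## Forward simulation

Rule conversion gives every non-input node the update expression
`(act_1 | … | act_A | self) & !(inh_1 | … | inh_I)`; with no inhibitors
the negation clause is dropped and an isolated node keeps its value (the
self term is retained even with no activators). Note the deliberate
semantic difference from reconstruction-time propagation: the self term
makes activity self-sustaining in forward simulation, whereas propagation
lets a child decay when its activators switch off; a regression test pins
both behaviours. Attractor search iterates the synchronous update from the
scenario start (inputs clamped, free nodes 0) until a state repeats;
steady states (cycles of length 1) are additionally verified to be fixed
points under asynchronous single-node updates. Limit cycles are reported
as results, not errors. An exhaustive fixed-point enumerator (≤ 22 free
nodes, vectorized over the full state space) serves as the independent
oracle in tests. Drug panels clamp all stimuli to 1 and enumerate all
2^|drugs| input vectors; edgetic scans delete every non-empty subset of a
target's candidate incoming edges (k singletons plus 2^k − k − 1
combinations) and re-simulate the panel, with a baseline block included.

## Statistics layer

Fast-Green-style normalization divides each spot by its total-protein
correction factor (stain / median stain) and rescales the corrected values
so their median equals the raw-signal median; restoring the *native*
median is one of several readings of "multiplied by the median value" and
is the one implemented. The drug-effect test models intensity on
continuous time, treatment group and their interaction (categorical time
is available as an option); continuous time matches the parallel-shift
logic — equal slopes with different intercepts should not open the gate.
Only when the interaction is significant (p < 0.05) is the one-sided
rank-sum test for lower treated intensities at the final time point run,
exact at the small replicate counts in scope (3 treated vs 5 untreated;
with 3 vs 3 the smallest achievable exact p is 0.05 and no verdict can
pass the strict threshold). No multiplicity adjustment is applied across
proteins or treatments in this layer — verdicts are per-test decisions.
Kendall association uses tau-b with tie correction and exact p-values for
small untied samples; constant series yield a flagged, undefined result.

## Synthetic data

The generator inverts the reconstruction model: propagate the truth
network per condition, map the M trajectory states to the T time points —
the default "even" schedule `k_t = ceil(t·M/T)` spreads phases uniformly
and holds the final state; a seeded "dwell" schedule with random monotone
switch times stresses the alignment — and draw every replicate from its
class Gaussian. Default generating parameters are μ0 = 10, μ1 = 12
(arbitrary intensity units), σ = 0.5, i.e. a class separation of 4σ,
mimicking well-separated log-intensities. The shipped designs mirror the
reference layout: short-term, 3 stimulus contexts (EGF, HRG, both) × 8
drug subsets of {E, P, T} = 24 conditions, time points 0–60 min, 3
replicates (5 drug-free), an 11-protein panel; long-term, a single
growth-medium stimulus S with no drug / erlotinib alone / double / triple
combinations, time points 0–30 h, 3 replicates, a 21-protein panel.

The planted benchmark network has 6 proteins: two stimulus-gated receptors
(each blocked by one drug), a two-layer cascade below them, and a kinase
inhibited by the third drug — every protein has a distinct on/off pattern
across the 24 conditions and staggered activation times, which is what
makes the structure identifiable from the data alone. Recovery is scored
by majority vote on the mean per-chain confidences (an edge is called when
its mean activation or inhibition confidence exceeds 0.5). The
significance-based consensus machinery is not used for scoring at 3
chains because the exact rank-sum test cannot reach α = 0.05 with 3
observations per group (minimum two-sided p = 0.1); it operates at the
full 10-chain design.

What the generator does *not* emulate: heteroscedastic and multiplicative
RPPA noise, spatial slide artifacts, antibody cross-reactivity, and
partial protein activation. Passing recovery benchmarks therefore shows
the inference machinery is correct under its own model assumptions, not
that those assumptions hold for any particular real dataset.

## Scaled-down test settings

The test suite and the acceptance script use desk-scale problem sizes: 3
chains × 5,000 iterations on the 6-protein planted network (10 simulated
datasets), 5,000 prior-only iterations for the concentration check, 10^5
flat-posterior iterations on 3 nodes for the uniformity check, 1,000
simulations for the drug-test error rates, and 100–200 random instances
for the oracle-agreement checks. These sizes were chosen as the smallest
at which the corresponding quantities are stable from run to run.

## Known limitations

* Likelihood plateaus: networks whose trajectories produce identical
  state-to-time alignments are indistinguishable; the sampler reports all
  of them with shared confidence mass rather than picking one.
* The mode-finding initialization biases early post-burn-in samples toward
  the dominant mode; with strongly multimodal posteriors and short chains
  the confidence fractions underrepresent minor modes.
* The exact-cache design assumes the likelihood is deterministic per
  structure; stochastic likelihood approximations would require clearing
  the cache.
* Asynchronous dynamics are implemented as fixed-point verification, not
  as a full asynchronous attractor landscape.
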