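# Methods

## The model

A gene regulatory network over N genes is inferred many times from resampled
data, giving a bootstrap ensemble of N_g directed networks.  Each directed
network is symmetrized (an undirected edge {n, m} exists iff m→n, n→m, or
both were inferred) and self-regulations are dropped — the hierarchy model
is defined on simple undirected graphs, and inferred auto-regulations mostly
reflect transcript degradation rather than interesting structure.

The shared structure of the ensemble is summarized by a hierarchical random
graph H(D, θ): a rooted binary dendrogram D with the N genes at its leaves
and a probability θ_i at each of its N − 1 internal nodes.  Under the model
each unordered gene pair {u, v} is an edge independently with probability
θ at the pair's lowest common ancestor (LCA).  The ensemble log-likelihood
is

    log L(D, θ) = Σ_j Σ_i [ E_ij log θ_i + (L_i R_i − E_ij) log(1 − θ_i) ],

where E_ij counts the edges of ensemble member j whose endpoints have
internal node i as their LCA, and L_i, R_i are the leaf counts of node i's
two subtrees.  For fixed D the maximizing θ is closed-form,
θ_i = Σ_j E_ij / (N_g L_i R_i), so the only free object is the tree.  We use
the convention 0·log 0 := 0 (the standard MLE limit), which makes a
perfectly consistent ensemble attain log-likelihood exactly 0.  The
likelihood is evaluated from the aggregated counts E_i = Σ_j E_ij —
algebraically identical to the double sum, O(N²) instead of O(N²·N_g).

## Searching tree space

The (2N−3)!! leaf-labeled rooted binary shapes are searched by simulated
annealing.  A proposal selects an internal node s uniformly; writing the
configuration below s as (A, (B, C)) — A one child's subtree, B and C the
grandchild subtrees under the other, internal, child — the Exchange
operator swaps A with B or C, and the Rotate operator regroups to ((A, B), C)
or ((A, C), B).  On unordered trees the two operators generate the same
neighborhood (the rooted nearest-neighbor-interchange moves); both are kept
and chosen with equal probability, and breadth-first closure of the move set
reaches all 15 shapes at N = 4 and all 105 at N = 5 (tested).  A node whose
children are both leaves admits no move; such proposals count against the
per-temperature budget and a fresh node is drawn on the next iteration.

The cooling loop is: start from a random tree (built by sequential uniform
branch insertion — the initial distribution is immaterial since annealing
forgets it), reset the current tree to the best-so-far at the start of every
temperature epoch, make N_max proposals per epoch with Metropolis acceptance
min{1, exp(−(Obj_c − Obj_t)/T)}, replace the best tree only on strict
improvement, and cool geometrically T ← γT until T ≤ T_end.  Defaults are
T_start = 1000, T_end = 0.1, N_max = 1000·N, γ = 0.99.  The per-epoch
restart from the best tree is unusual for simulated annealing but is a
deliberate part of this method's definition; `restart_from_best=False` disables it for
experimentation.

Each proposal only changes the statistics of s and its internal child (the
move redistributes LCAs among pairs crossing A, B, C; everything above s
keeps its leaf set), so the annealer keeps per-node leafsets, pair counts
and likelihood contributions cached and re-evaluates exactly two nodes per
proposal, with an undo snapshot for rejections.  A full-recompute mode
(`incremental=False`) exists and is tested to agree with the cached path to
1e-9 along random move/revert walks.  For N ≤ 8 an exhaustive enumerator
provides the global optimum and the tie set as a test oracle.

## Confidence values

Bootstrap confidences p^B(n, m) — the fraction of ensemble networks
containing regulation m→n — are directed and lie on the grid {k/N_g}.
Hierarchy confidences p^H(n, m) = θ at the LCA of n and m are direction
blind.  The final confidence is p = η·p^B + (1 − η)·p^H with default
η = 1 − 1/N_g.  At that default the hierarchy is strictly a tie-breaker:
whenever two regulations differ by at least two grid steps in p^B, the
mixture cannot reverse them (η·2/N_g > (1 − η)·1 for N_g ≥ 3; tested
exhaustively for N_g ∈ {10, 100}).  Self-regulations carry their p^B value
only and are excluded from ranking and evaluation.  Residual ties in the
mixture are broken deterministically by p^B, then regulator label, then
target label — a repo convention, since no rule is implied by the model.

## Synthetic data

The generator emulates a standard in-silico protocol.  Dynamics follow the
S-system

    dX_n/dt = α_n Π_m X_m^{g_{n,m}} − β_n Π_m X_m^{h_{n,m}},

with α = β = 1, h the identity (first-order auto-degradation), and, for
every regulation m→n of the target topology, g_{n,m} drawn uniformly from
[−1, −0.5] ∪ [0.5, 1] (independent uniform sign).  Each experiment set
starts from X0 ~ U[0, 2]^N and is observed at 11 timepoints 0.4 apart;
100 sets by default, so each gene contributes K = 100 × 11 = 1100
measurements.  Measurement noise is multiplicative Gaussian with sd 10% of
the signal (the common convention for "10% Gaussian noise"; an
`absolute_noise` flag provides the additive alternative), floored at 1e-6 so
downstream log transforms stay finite.

Numerical details: integration is adaptive explicit Runge-Kutta (RK45,
rtol 1e-8, atol 1e-10); the power law is singular at 0, so initial states
with any coordinate below 1e-3 are redrawn; random kinetic orders can
produce finite-time blow-up from some initial corners, and such initial
states are likewise redrawn (up to 20 times, after which the model is
reported unstable rather than silently patched).  With everything decoupled
(g = 0) the system is dX/dt = 1 − X with closed form
X(t) = 1 + (X0 − 1)e^{−t}, which the solver matches to 1e-6 (tested).

Because published benchmark topologies are external downloads, the test
topology generator produces random modular networks (genes split into
blocks, regulation probability 0.3 within and 0.05 between blocks) as a
small-scale stand-in with the block structure that makes hierarchy
detection meaningful.  What the generator does *not* emulate: intrinsic
(process) noise, transcription/translation delays, unobserved regulators,
and realistic degree distributions of curated networks — passing tests
demonstrate the machinery and the direction of the effect, not performance
on real expression data.

## Ensemble inference baseline

This confidence-combination approach was developed around a bootstrap
linear-programming-machine method (BS-LPM) defined elsewhere; it is not
re-implemented here.  The pluggable inference registry ships
`baseline_bootstrap_regression`: each bootstrap replicate resamples whole
experiment sets with replacement (preserving within-set dynamics), estimates
derivatives by central differences (one-sided at the ends), and regresses
each gene's derivative on the log-transformed expression of all unmasked
candidate regulators; a regulation enters the replicate's network when its
standardized coefficient magnitude exceeds a threshold (default 0.2, chosen
so a planted strong single regulator on noise-free data is recovered in
≥ 95% of replicates while the reverse edge stays rare).  The log transform
linearizes the power-law production term near steady state; it is a
heuristic.  Hard prior knowledge enters as forbidden/forced edge masks
enforced on every network.  Results from this baseline are not comparable
to published numbers produced with the original inference method.

## Evaluation

Evaluation is directed and ignores self-regulations on both sides.  The
recall-precision curve has one point per distinct confidence value
(threshold sweep; a tie block enters as a whole), with precision defined as
1 when nothing is predicted.  AURPC integrates the best precision achieved
at each recall by the trapezoidal rule over recall, extends the curve at
constant precision from the smallest achieved recall down to 0, and adds
nothing beyond the largest achieved recall.  The confusion counting is
cross-checked against scikit-learn's precision-recall curve points to 1e-6
under this same integration convention; absolute AURPC values under other
conventions (e.g. step interpolation) differ slightly, so comparisons
should stay within one convention.

## Problem sizes used in the shipped experiments

The test suite and the acceptance script run the method at reduced scale,
chosen as the smallest sizes at which each property is meaningful: annealer
vs exhaustive oracle on N ∈ {5, 6, 7}, N_g = 20 with the reduced schedule
(T 10 → 0.1, γ = 0.9, 200·N proposals per epoch); planted-θ recovery on a
balanced 16-leaf tree with θ ∈ {0.05, 0.9} by depth and N_g = 100; the
end-to-end comparison on 10-gene modular networks with 20 time-series sets
and N_g = 50.  At these sizes the hierarchy's improvement over
bootstrap-only ranking is small (order 1e-3 in mean AURPC) and
seed-dependent in sign for any single small batch of trials, consistent
with the method being a tie-breaker by construction at η = 1 − 1/N_g.

## Known limitations

- The annealer returns a single optimum; it does not average over models,
  so plateaus with many tied optima yield an arbitrary member of the tie set.
- p^H is direction blind; the method cannot by itself orient a regulation.
- When no two regulations share a bootstrap probability, the mixture at the
  default η changes nothing — the hierarchy only re-ranks ties.
- The baseline inference stage is a deliberately simple stand-in; its
  absolute accuracy bounds what the end-to-end numbers can show.
- Exhaustive search is limited to N ≤ 8 ((2N−3)!! growth).
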