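# Methods

This note records the models, the numerical choices, and the reasoning
behind the open design decisions, in the order the pipeline uses them.

## The dating model

Dating operates on a fixed rooted topology whose internal nodes carry ages
`t` in My before present (tips at 0).  The posterior combines four terms.

**Birth–death node-age prior.**  Conditioned on the root age `T` and the
tip count, the non-root speciation times of a completely sampled
birth–death tree are i.i.d. with density `p1(t)/F(T)` on (0, T), where
`p1(t) = r² e^{−rt}/(λ − μ e^{−rt})²`, `r = λ − μ`, and `F` is p1's
antiderivative; the critical case λ = μ reduces to
`p1(t) = 1/(1+λt)²`, `F(t) = t/(1+λt)` and is dispatched analytically.
The root age is uniform on (0, `root_max`]; the default ceiling is
2000 My, the deepest bound the study system admits.  λ and μ receive
vague exponential hyperpriors (mean 0.1/My) and are sampled; the method's
external reference tool applies its birth–death prior with unstated
defaults, so sampling them is the neutral choice.

**Soft-bound calibrations.**  A two-sided bound distributes mass
(1 − p_L − p_U) uniformly on [min, max] and p_L, p_U (default 2.5% each)
into exponential tails whose rate is fixed by density continuity at each
bound.  A minimum-only bound places (1 − p_L) in an exponential component
above the bound (scale default min/2 — diffuse relative to typical
posterior widths, proper, and integrable) and p_L = 5% below.  Tail mass 0
degenerates to a hard bound.  The per-side 2.5% reading of the two-sided
convention was adopted; the alternative "2.5% total" reading appears once
in looser prose and contradicts the parenthetical that defines the scheme.
Calibration densities multiply the tree prior without renormalisation
(the standard practical treatment).

**Relaxed-clock priors.**  One rate per branch, indexed by child node.
LN: child log-rate ~ Normal(parent log-rate, σ²Δt), with Δt the child
branch's own duration and root-adjacent branches anchored at the base
rate ν.  CIR: exact transition density (noncentral-χ², evaluated through
the exponentially scaled Bessel function; a moment-matched Gaussian
replaces it in the near-deterministic regime where the Bessel underflows),
stationary Gamma(2θν/σ², σ²/2θ) at the root, with the stationarity
condition 2θν/σ² > 1 enforced.  UGAM: i.i.d. Gamma(mean ν, variance σ²).
WN: independent Gamma with variance σ²/Δt.  All four collapse to the
strict clock as σ² → 0.

**Branch-length observation model.**  The data likelihood is *not* a full
phylogenetic likelihood over alignments — the upstream tree and branch
lengths are consumed as inputs, and the dating mathematics (priors,
clocks, calibrations, summaries) is the implementable content.  Two
modes: Poisson, `count_b ~ Pois(rate_b · Δt_b · sites)` (exact for
synthetic data and used throughout the recovery suites), and a normal
approximation for real branch-length trees, `length_b ~ N(rate_b · Δt_b,
SE²)` with SE defaulting to √(length/sites), floored at 1e-6.

## The sampler

Metropolis-within-Gibbs with per-term caching; each move touches only the
posterior terms it can change, and a from-scratch recomputation is the
correctness oracle in the tests.  Moves per sweep:

* node-age slide: uniform proposal inside the open window
  (max child age, parent age) — symmetric because the window does not
  depend on the node's own value;
* compensated node-age slide: the same window proposal with the adjacent
  branch rates rescaled to keep every rate×duration product fixed, so the
  likelihood is invariant; the Jacobian is the product of old/new duration
  ratios.  This move traverses the age–rate ridge on which plain
  single-age updates stall;
* per-branch rate: multiplicative log-uniform step (width 0.6);
* hyperparameters (ν, σ², θ, λ, μ): multiplicative steps (width 0.3)
  against exponential hyperpriors;
* every 10th sweep, a whole-tree scale move multiplying all ages by c and
  dividing all rates by c (Jacobian `(n_int − n_branch)·log c`).

Initial ages are built bottom-up with exponential gaps scaled to the
calibration depths, then clamped into calibration windows; with soft
bounds any order-valid configuration has finite posterior, and a bounded
search (200 attempts) raises if hard bounds are mutually infeasible.
Chains are deterministic given a seed (one `numpy` Generator per chain,
seeded by (seed, chain index)).  Burn-in discards the first 20% of
retained draws by default, matching the source protocol's ~20%.

Convergence is reported as rank-normalized split R-hat and bulk ESS
(Geyer initial monotone sequence), with pass thresholds R-hat < 1.1 and
ESS > 100 for every node age.  The 95% HPD is the shortest contiguous
window containing ⌈0.95 n⌉ sorted draws; intervals are stored
(lower, upper) and printed older-bound-first.

**Fossil cross-validation** is leave-one-out: re-date without calibration
i, report `D_i` = posterior mean age at i's node minus i's interval
midpoint (its minimum when one-sided), plus D_i² and ΣD_i².  The source
describes its procedure only by citation; this standard squared-deviation
design is used; its numbers are a property of this implementation and
are not compared against any externally published table.

## Trait models

Mk likelihoods use Felsenstein pruning with per-node rescaling; transition
matrices come from an eigendecomposition of Q batched over branch
durations, falling back to scaling-and-squaring `expm` when the eigenbasis
is ill-conditioned (condition number > 1e8).  Missing tips ("?")
contribute all-ones partials.  The root prior defaults to the fitted
model's stationary distribution, with uniform, FitzJohn-conditional, and
explicit-vector options; the source names no choice, and the explicit
vector exists because the packaged fixture is volvocine-only — the
unicellular, isogamous outgroups that anchor the root on the full
phylogeny are off-tree, so fixture analyses pin the root to the known
ancestral condition instead (the parsimony routines accept the analogous
`root_state`).

`fit_mk` maximises over log-rates with L-BFGS-B, rates bounded to
[1e-9, 1e3] /My, starting from a parsimony-informed rate (min changes /
total tree duration) plus seeded random restarts (5 by default).  A
single-observed-state character is flagged degenerate rather than fitted.
Model comparison is by Akaike weights, `w_m ∝ exp(−Δ_m/2)`.

Stochastic mapping samples node states top-down from their joint
conditionals, then fills each branch with an endpoint-conditioned path by
uniformization: jump count n drawn from `Pois(Ωt)·(Rⁿ)_{ab}/P_{ab}(t)`
with Ω = 1.05·max|q_ii| and R = I + Q/Ω, jump states bridge-sampled
against powers of R, jump times as uniform order statistics, and virtual
(self) jumps collapsed.  The jump-count cap is a generous Poisson upper
tail (mean + 20√mean + 50); sampling failure names the offending branch.

Parsimony: Fitch counting (binary trees; polytomies resolved arbitrarily
with a warning, tie-broken by state order for the single reported
labeling — the count itself is order-independent), and Sankoff DP under
arbitrary non-negative cost matrices with ∞ encoding irreversibility.
Ordered characters use the chain-path metric as the cost matrix (a 0→2
step on one branch costs 0→1 plus 1→2).  A second additive DP minimises
the number of non-derived→derived transitions *within* the set of
minimum-cost labelings, giving the "minimum origins across all optima"
statistic used for the trait-origin counts.

## The fixture

The fixture transcribes the study system at genus/species resolution:
28 tips, topology per the published phylogeny (Goniaceae monophyletic;
*Vitreochlamys ordinata* sister to the Tetrabaenaceae; the
*Chlamydomonas* lineage sister to Goniaceae + Volvocaceae; Volvocaceae =
(section *Volvox*, (PVC, (*Yamagishiella*, EVP)))), with the reported CIR
posterior mean ages at the anchor nodes (TGV crown 298; splits 267/274;
crowns 89/247/228; *Gonium*–*Astrephomene* 220; the *T. socialis* strain
pair 51) and interpolated ages elsewhere, chosen only to respect
parent > child.  The EVP clade includes the paraphyletic *Eudorina*
lineages that separate the somatic-cell origins; without them a
genus-collapsed tree would let parsimony merge the *Pleodorina
thompsonii* and *Volvox*+*P. japonica* gains into one.  Trait codings come
from main-text statements only; anything not stated in that main text is "?", and every cell carries a provenance entry.
The calibration table's anchor tip pairs are representative members of
each calibrated clade (the source names clades, not tips); the choices
are recorded in the table itself.

## Synthetic data and what passing tests show

Generators are seeded, return their ground truth, and default to the
recovery-suite scale: 20 tips, 1000 sites, 3 two-sided calibrations of
width 10% of the root age placed at the root plus two random internal
nodes, birth 0.02/My, death 0.01/My, base rate 1e-3 subst/site/My, and
variance scales giving a rate coefficient of variation near 0.5 (UGAM
σ² = 2.5e-7; WN σ² = 1.25e-5; LN σ² = 5e-4 /My; CIR σ² = 2e-5 with
θ = 0.05/My).  The birth–death simulator conditions on the tip count with
the present placed between the n-th birth and the next event, and on both
root lineages surviving.

The coverage experiment (20 replicates per clock model, chain lengths
4000–8000 sweeps chosen per model to reach adequate ESS) checks that 95%
HPDs cover true node ages for ≥90% of nodes.  The generator emulates the
count-based observation model exactly, so passing demonstrates the
correctness and calibration of the priors, the sampler, and the
summaries — not robustness to alignment-level misspecification, rate
heterogeneity across sites, topology error, or fossil misassignment,
none of which the synthetic data contain.  Likewise the identity screen's
simulated sequence pairs are gap-free, so they validate scoring and
conventions, not gap-placement behaviour on real ITS-2.

## Known limitations

* No full alignment likelihood; dating quality on real data inherits the
  normal approximation for branch lengths.
* No Bayesian MCMC over Mk parameters: ancestral states use ML +
  stochastic mapping (the ML/simmap route commonly paired with a
  Bayesian-MCMC alternative); the MCMC-based route's settings are not
  reproduced, and
  characters where the two tools disagreed will follow the simmap answer.
* Published percent-identity figures for the ITS-2 comparisons depend on
  an unstated aligner and column convention; the screen therefore exposes
  the convention as a flag rather than claiming those exact values.
* The cross-model non-overlap report flags HPD disjointness only; it is a
  screen for outlier clock models, not a model-selection statistic.
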