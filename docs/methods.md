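# Methods

This note documents the models, estimators, priors and numerical choices
behind `phylogeo`, and what the synthetic-data experiments do and do not
establish.

## Substitution models and likelihoods

Nucleotide models are the reversible JC/HKY/GTR family. The rate matrix is
built as Q_ij = s_ij π_j (s symmetric), scaled so the expected substitution
rate at stationarity is 1; branch lengths are therefore expected
substitutions per site. Transition probabilities use the eigendecomposition
of the symmetrized matrix D^{1/2} Q D^{-1/2} (real spectrum guaranteed for
reversible Q); rows are clipped at zero and renormalized against
floating-point noise.

Among-site rate variation uses the discrete-Γ approximation with
mean-per-equal-probability-bin category rates (k = 4 by default),
renormalized to average exactly 1. +I adds an invariant category of rate 0
with weight p_inv; the mixture is a (k+1)-component rate mixture and the
variable categories are *not* rescaled by 1/(1 − p_inv) — the overall mean
rate under +I is (1 − p_inv), which is absorbed by the branch-length
scale during inference. Likelihoods are computed by Felsenstein pruning
with per-node, per-site rescaling; gaps and `?` integrate over all states;
IUPAC ambiguity codes become partial likelihoods (never resolved randomly).

Morphology uses the symmetric Mk model with uniform stationary frequencies.
Because matrices that only record variable characters are ascertained, the
"variable" correction divides each character's likelihood by
1 − Σ_s P(constant pattern s), with the rate mixture applied inside both
numerator and correction. Characters are grouped by their observed state
count and each group gets its own Mk state space (a binary character is
Mk with r = 2 even inside a matrix that elsewhere shows four states); the
Γ shape parameter is shared across groups. This grouping matters: scoring
binary characters under a pooled r = 4 alphabet suppresses the rate-
variation signal that the Mk-vs-Mk+Γ Bayes factor is meant to detect.

Parsimony lengths use Hartigan's generalization of the Fitch pass, which
is exact on polytomies and treats missing/ambiguous cells as state-set
unions (verified against exhaustive ancestral-labeling enumeration).

## Per-partition model selection

BIC = −2 max lnL + K ln(n_sites) on a fixed reference tree, with
K ∈ {JC: 0, HKY: 4, GTR: 8} plus 1 each for +I and +Γ. All candidates share
one free tree-length scale (not counted in K, identical role in every
candidate). Candidates are fitted in nesting order and larger models are
warm-started from the best nested fit, which makes max lnL monotone under
nesting in practice as well as in theory. Partition merging/search is out
of scope; the scheme is an input.

## MCMC

One Metropolis update per generation per chain: NNI on a uniformly chosen
internal edge (implemented by rerooting at the edge's parent and swapping
uniformly chosen child subtrees — symmetric), branch-length multipliers
(Hastings ratio m), and model-parameter moves (multipliers for κ and α,
reflected windows for p_inv, Dirichlet proposals with concentration 300
for frequencies and GTR exchangeabilities). Default weights:
topology 0.35, branch lengths 0.35, parameters 0.30.

Priors: branch lengths iid Exponential(10); topology uniform over the
constraint-satisfying set; frequencies and GTR rates Dirichlet(1,…);
ln κ ~ Normal(1, 1.25); Γ shape ~ Exponential(1); p_inv ~ Uniform(0,1).
These mirror widely used Bayesian-phylogenetics defaults and are stated
here rather than hidden.

Hard constraints are enforced by proposal rejection, which is equivalent
to a prior with zero mass outside the constraint-satisfying set. Start
trees come from neighbor joining on JC-corrected p-distances when that
tree satisfies the constraints, otherwise from a random
constraint-respecting resolution; a user-supplied start tree that violates
the constraints is an error, not a silent repair.

Metropolis coupling runs 1 cold + (n_chains − 1) heated chains per run with
heat 1/(1 + 0.1 c) and adjacent-pair swap proposals every 10 generations;
"two hot and two cold chains" is realized as 2 independent runs × (1 cold +
1 heated). Convergence is monitored by the average standard deviation of
split frequencies (SDSF) between runs' cold chains, over splits reaching
frequency ≥ 0.10 in any run; the conventional 0.01 comfort threshold is a
config default, not an enforced stopping rule. The consensus is the greedy
("all-compatible" / extended majority rule) consensus: splits added in
decreasing frequency while compatible, node supports = split frequencies,
branch lengths = means over trees containing the split.

## Stepping-stone marginal likelihoods

The sampler walks from the posterior (β = 1) to the prior (β = 0) along
β_j = (j/K)^(1/0.3) (Beta(0.3, 1) quantile spacing), K = 50 steps by
default. Each interval's normalizing-constant ratio is estimated from the
samples at its *lower* power with the max-factored identity
log r̂ = log mean exp(d (lnL_i − max)) + d·max, d = β_upper − β_lower > 0;
the contributions telescope to log p(X). Each step's chain continues from
the previous step's final state, so every step is the next step's burn-in;
the initial posterior-power run is pure burn-in. Estimating ratios from the
upper power instead (a harmonic-mean-flavored variant) showed a clear
finite-sample bias on a quadrature-checkable fixture and is not used. The
Monte-Carlo SE is a circular block bootstrap (blocks of n/10) within steps,
combined across steps.

Bayes factors are reported as 2Δln (Kass–Raftery scale: <2 none, 2–6
positive, 6–10 strong, >10 very strong) with Δln also available, since
published "BF scores" are ambiguous between the two conventions.

## Stochastic mapping and homoplasy

For each character: pruning partials upward, joint node states sampled
root-to-tips, then endpoint-conditioned branch histories by uniformization
(Ω = 1.05 max|q_ii|; the jump count is drawn from its exact conditional
distribution, the jump chain is filled in backward-forward, and virtual
jumps are discarded). Rate uncertainty uses a per-character rate scaler
with a Gamma(1.25, mean 1) prior integrated over a 21-point log-spaced
grid posterior; a Γ category can additionally be mixed in per draw.

CI = m/s with m = (observed distinct states − 1) — the parsimony minimum
for an unordered character — and s the posterior-mean mapped change count;
CI is clipped at 1 against Monte-Carlo noise, HI = 1 − CI, and constant
characters are reported not-applicable and excluded from aggregation.
Dwell times are mean per-state occupancy fractions of total tree length.
Region shares divide each gonopod region's summed HI by the total over
coxa + prefemur + tibiotarsus; a CI-based aggregation is available by flag
because both conventions exist in the literature and they can disagree.

## Geography

Species centroids are normalized mean unit vectors on the sphere (robust
at the antimeridian; an exactly antipodal cloud is an error). Distances
are haversine on R = 6371.0088 km; a flat-Euclidean metric is available
for sensitivity analysis. Ecoregion assignment is point-in-polygon with a
deterministic lexicographic tie-break on boundaries and a logged
nearest-polygon fallback for centroids outside the map. The ecoregion
distance tree is neighbor joining (Q-criterion, lowest-index tie-break,
negative branch estimates clamped to zero with the deficit moved to the
sibling edge) over region centroids; species enter the downstream Bayes
factor test only through one monophyly constraint per region with ≥ 2
species — disjoint by construction, hence always a compatible set.

Range areas are convex hulls of the locality cloud, measured after a
spherical Lambert azimuthal equal-area projection centred on the species
centroid (exact for the sphere model; no external projection library is
required). Convex hulls overestimate ranges with concave or disjunct
distributions — a known, accepted bias. Endemism classes: MRE < 1,000 km²
⊂ SRE < 10,000 km² (strict thresholds), with MRE species counted as
SRE-qualifying in summaries.

## Synthetic data: what it emulates, what it does not

Defaults mirror the study system the package emulates: 90 taxa, a
3,975-bp six-partition supermatrix, 68 morphological characters (46
binary / 22 multistate, 40 gonopodal), and Appalachian-scale geography
(origin 37.5° N, 81° W; dispersal σ = 100 km). Tests and the acceptance
analyses use smaller explicit sizes (6–12 taxa, 60–1,500 sites, 6–68
characters) chosen so each check exercises the full pathway at desk scale.

Convergent evolution is created structurally: a fraction ρ of characters
evolves on a single shared decoy tree (a relabelled independent Yule
draw), so convergent characters carry coherent synapomorphies for a wrong
topology — the known-truth analogue of concerted gonopod convergence, and
the reason mean HI must rise monotonically with ρ. Geography is Brownian
dispersal along the tree (step SD σ√t), with a noise parameter that
redraws tip positions uniformly; noise = 0 gives Mantel-positive
isolation-by-distance, noise = 1 destroys it.

The generator does not emulate alignment error, saturation-induced model
misfit beyond what the models allow, gene-tree discordance, range shapes
beyond point clouds, or uneven sampling effort. Passing tests therefore
demonstrate the correctness and calibration of the machinery, not that any
real dataset satisfies the models' assumptions.

Two deliberate test-design choices: topology-recovery checks condition on
the generating tree having internal branches ≥ 0.05 expected substitutions
(shorter splits are not identifiable from finite alignments, so recovery
there measures luck, not the sampler), and the "low-rate homoplasy ≈ 0"
construction check maps at the known generating rate (with a free rate the
prior dominates a single character's weak likelihood and inflates HI).

## Numerical choices and degenerate inputs

Likelihood underflow is prevented by per-site partial rescaling. t = 0
branches give exact identity matrices. Mkv returns −∞ when the variable
correction would divide by zero. The uniformization series is truncated
when terms fall below 1e−14 of the accumulated mass (capped at 500 jumps).
Grid posteriors guard zero weights; Dirichlet proposals floor components
at 1e−6. All random streams derive deterministically from user seeds
(tuple-seeded `numpy` generators), making every simulation and sampler
run bit-reproducible.

## Known limitations

- Per-partition branch-length multipliers are supported in the state but
  not sampled by default; partitions share branch lengths.
- Topology proposals are NNI only (no SPR), adequate at the tested sizes
  but slow-mixing for large trees.
- The stepping-stone SE underestimates when within-step autocorrelation is
  severe; the `ss_thin` knob trades compute for accuracy.
- BIC optimization uses quasi-Newton local search with warm starts — not a
  global optimizer — and flags non-convergence rather than hiding it.
- The mapping-rate grid posterior is a deliberate simplification of fuller
  prior-marginalization schemes for mapping rates; its grid bounds and
  resolution are exposed as arguments rather than tuned internally.
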