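# Methods

## Model

A haploid population of fixed size N occupies the nodes of a simple,
undirected, connected graph; edges are the routes along which offspring
replace neighbours. Two ecotypes — a resident wild type and an invading
mutant — are distinguished on two axes:

* **Intrinsic fitness**: wild type 1, mutant 1 + s. This is the
  frequency-independent component (growth rate in monoculture or under
  saturating resources).
* **Metabolic strategy**: an allocation vector over two substitutable
  resources. In the symmetric parameterisation the wild type allocates
  (1 − α, α) and the mutant (α, 1 − α): the mutant swaps which resource it
  prefers while keeping the same budget. α = 0.5 means identical
  generalists; α = 1 fully separated specialists. Allocations enter only
  through ratios, so the model is invariant to rescaling all α's by a
  constant and to the reflection α ↔ 1 − α; the range [0.5, 1] is
  therefore exhaustive.

Resource i is supplied at constant rate S_i (default 0.5) and consumed at
per-enzyme rate μ(c_i) (default linear, μ(c) = c; degradation neglected).
With n mutants present, the steady state balances supply against total
consumption, c\*_i = S_i / (n_wt α_wt,i + n_mut α_mut,i). Ecological
fitness is r̃_σ = Σ_i v_i α_σi μ(c\*_i) (resource values v_i = 1 by
default) and overall fitness multiplies in the intrinsic part,
f̃_σ = s_σ r̃_σ. Only the relative mutant fitness
f_mut(n) = f̃_mut / f̃_wt matters for the dynamics.

For the symmetric two-resource case this relative fitness has the closed
form f_mut(x) = (1 + s)(1 − w)/(1 + w) with w = (2α − 1)²(2x − 1) at
mutant frequency x, which gives the interior equilibrium (root of
f_mut = 1)

x\* = 1/2 + (1/2)(2α − 1)⁻² · s/(2 + s).

The printed rendering of this expression in the source material is
typographically ambiguous, so the implementation treats the numerical root
of f_mut(x) = 1 as authoritative and the closed form as a cross-checked
convenience; the two agree to 1e−6 across the tested grid. The equilibrium
is unstable only against drift: the two absorbing states are loss (n = 0)
and fixation (n = N).

**Update rule.** Discrete-time Moran with Birth–death (Bd) updating: one
mutant starts on a uniformly chosen node; each step samples a reproducer
across all N nodes proportional to overall fitness, and the offspring
replaces a uniformly chosen neighbour of the parent. With well-mixed
resources fitness depends only on the total mutant count, which is what
makes both the compiled simulator and the exact reductions tractable.

## Exact solvers

Every chain used here is *skip-free* in the mutant count — a replacement
changes the count by at most one and the configuration only changes when
the count does. Absorption probabilities are computed by a first-passage
recursion over count levels,

R_n = (I − B_n R_{n−1})⁻¹ A_n,

where A_n/B_n are the up/down blocks of the embedded jump chain
(self-loops renormalised away) and R_n[i, j] is the probability of first
reaching level n + 1 in state j before loss, starting from level-n state
i. Fixation is the start distribution pushed through ∏ R_n; establishment
is the (defective) hitting distribution on level m = ⌈N x\*⌉; conditional
fixation is the hitting-weighted fixation from level m. The identity
P_fix = P_est · P_cfix then holds by construction (strong Markov property
at the first passage of m), and tests assert it to 1e−12.

* **Well-mixed** (complete graph): one state per level; the recursion
  reduces to the classical product formula with step ratios 1/f_mut(n),
  evaluated in log space with logsumexp because strong niche separation
  produces barrier products spanning hundreds of orders of magnitude.
* **Star**: two states per level (hub occupant × mutant leaf count), 2N
  states in total.
* **PA star** (i fully connected core nodes, N − i leaves attached to all
  cores): levels hold (core mutants, leaf mutants) pairs,
  (i + 1)(N − i + 1) states; i = 1 is the star and i = N − 1 the complete
  graph, both verified to 1e−10.
* **Brute force**: the full 2^N occupancy chain, solved sparsely and
  refused above N = 14. It is the ground-truth oracle for every
  structured solver on small graphs.

**Numerical note (why multiprecision).** Above the interior equilibrium the
matrix I − B_n R_{n−1} has a spectral gap equal to the probability of
crossing the lower potential barrier, which is exponentially small in the
barrier height and underflows double precision for strong niche
separation — float64 produces catastrophically wrong (even negative)
probabilities from N ≈ 50, α ≳ 0.9, while every *true* intermediate
quantity of the recursion is a well-behaved probability. The structured
solvers therefore run under mpmath with working precision set adaptively to
30 digits plus the total log₁₀-fitness barrier Σ|log₁₀ f_mut(n)|. A star
solve at N = 50 costs ~10 ms, so exact crossing sweeps stay interactive.
Correctness checks include the brute-force oracle and a type-exchange
symmetry: at s = 0 the model is invariant under swapping the ecotypes, so
the two level-N/2 fixation probabilities must sum to exactly 1 — a
property double precision visibly violates and the multiprecision solver
holds.

## Monte-Carlo engine

The well-mixed-resource simulator is a numba kernel: mutant/wild-type node
sets as swap lists (O(1) type-uniform sampling), fitness from the
precomputed f_mut(n) table, and an inline xorshift64\* generator seeded per
replicate through splitmix64 from a numpy SeedSequence expansion of the
master seed — replicate r is identical regardless of batching. Star-like
amplifiers need ~N³ steps per fixing trajectory, which is why per-step cost
(~40 ns) matters. Safety cap 10 N³ steps; truncated runs are excluded from
estimates and reported separately rather than silently folded in.
Establishment is the first passage of the count to ⌈N x\*⌉ (conservative
integer crossing; the continuum result does not specify rounding), matching
the exact solvers' definition, so Monte-Carlo and exact decompositions are
directly comparable. Probabilities carry binomial standard errors; times
are reported in Moran steps (one birth–death event) with sample standard
errors — divide by N for a generations view.

## Diffusible resources

To relax the well-mixed-resource assumption, each node j holds its own
concentrations: resource i is produced at rate S at every node, consumed at
rate α_ij set by the occupant, and diffuses along edges with constant D.
The per-resource steady state solves (D L + diag(α_i)) c\*_i = S_i with L
the combinatorial graph Laplacian; per-node fitness is
f_j = s_j Σ_i v_i α_ij c\*_ij. The simulator re-solves the equilibrium
after every replacement — the consumption diagonal changes at exactly one
node, so the kernel tracks the inverse by a Sherman–Morrison rank-1 update,
re-factorising every 64 updates to keep roundoff below the 1e−9 steady-
state residual tolerance (the update is tested against from-scratch solves
at 1e−8). For uniform occupancy the constant vector is an exact solution
(c = S/α, any D); as D → ∞ the field flattens onto the well-mixed values,
and the D = 100 simulation reproduces the well-mixed fixation probability
on an amplifier within Monte-Carlo error.

## Amplification factor

Estimated empirically: run the constant-selection process (α = 0.5, probe
advantage s_probe) on the graph, estimate the fixation probability Φ, and
solve Φ = (1 − (1+s)^−a) / (1 − (1+s)^−aN) for a by bracketed root
finding on (10⁻³, 20]. Default s_probe = 0.005 (CLI); the acceptance runs
use 0.01 for a stronger signal at 10⁵ replicates — both sit in the
near-linear response region. A weak-selection linearised estimator
a ≈ 2(Φ − 1/N)/s_probe is available for comparison.

## Approximations and validity

* **Weak ecological selection** (N·⅔(2α−1)² ≪ 1): the frequency
  dependence collapses into a constant effective coefficient
  s_e = s + ⅔(2α−1)² — the selection felt at frequency 1/3 — and
  P_fix ≈ 1/N + ½ a_Bd s_e. Tested against the exact chain at <10%
  relative error wherever |N s_e| < 0.3.
* **Strong ecological selection** (establishment-failure ratio
  [(2α−1)⁻² − 1 + 2/N] / [(2α−1)⁻² + 1 − 2/N] ≪ 1): establishment is
  s-independent, P_est ≈ 1 − 1/r_inv (well-mixed) or 1 − 1/r_inv² (star),
  with r_inv the lone-mutant ecological fitness; conditional fixation is
  α-independent, P_cfix ≈ (1 − (1+a_Bd s)^−N)/(1 − (1+a_Bd s)^−2N).
  Tested at <2%/<5% against the exact chain for N = 500,
  α ∈ [0.8, 0.95], |s| ≤ 0.01. At α = 0.7 the validity ratio is ≈ 0.73 —
  not a strong regime — and the measured errors grow to ~4%/6%, so the
  test grid starts at 0.8.
* **Linear interpolation**: P_fix(a_Bd) through the two exactly solvable
  endpoints (well-mixed at a_Bd = 1, star at ≈2).

Regime thresholds default to weak < 0.3 and strong < 0.05; the source
asymptotics say only "≪ 1", and these defaults reproduce the reference
regimes (α ≈ 0.53 weak at N = 100; α ≥ 0.99 strong at N = 500). Every
approximation returns its validity-condition value alongside the clipped
probability; the CLI warns outside the regime instead of refusing, since
the curves remain informative there.

## Synthetic graphs and what they stand for

Generators follow the standard constructions (k-regular, Erdős–Rényi,
Watts–Strogatz, complete bipartite, two-cluster random geometric with the
smallest connecting radius, degree-exponent preferential attachment, PA
stars, detour graphs, modified stars). Two points were genuinely open and
resolved as follows: the two-cluster geometric sampler reads the stated
N(0, 0.25) as mean/variance (sd = 0.5), with the variance exposed as a
parameter; detour and modified-star edge choices are uniform over eligible
edges. Degree-preserving randomization uses connectivity-checked double
edge swaps — a simpler stand-in for dk-series annealing that preserves the
degree sequence exactly but explores the rewiring space less
systematically. `random_ductal_tree` grows duct-like trees (long corridors
punctuated by side branches, branching probability ~0.3); these emulate
the *topology class* of imaged ductal networks — tree-like, low mean
degree, suppressor-leaning — but not their measured branch-length or
degree statistics, so conclusions about real ductal architectures should
be drawn from the family-level trends, not from any single synthetic tree.

## Problem sizes and design choices

The exact crossing sweeps run the star at N = 50 (the scale of the
role-reversal analysis). Monte-Carlo checks use 10⁵ replicates at N = 100
for the isothermal ratio and the star amplification factor (star
amplification at N = 100: exact value 1.960 vs the large-N limit 2; the
[1.7, 2.3] check is insensitive to this). The diffusible-resource
equivalence check runs at N = 20 with 5×10³ replicates, since every
diffusible replacement carries an O(N²) inverse update; the D ≥ 100
equivalence it asserts is scale-free. The D ≈ 1 boundary shift of the
amplified-deleterious limit (to Ns ≈ −0.6) needs ~10⁶ diffusible
replicates per grid point and is left to cluster-scale runs via the same
API.

## Known limitations

Two resources and two ecotypes (generalized allocation vectors are
supported, but no cross-feeding, degradation, or evolving strategies);
Birth–death updating only; no mutation during spread; exact solvers beyond
the symmetric reductions are limited to N ≤ 14 brute force; diffusible
mode requires the linear consumption law and dense Laplacian solves.
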