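# Methods

## Problem setting

Panels of immunological (or other) biomarkers are measured repeatedly at
fixed visits V1, V2, … before each treatment cycle, together with one
binary endpoint (toxicity, death, progression) observed after the last
visit. The goal is to rank biomarker-at-visit variables by a *lower bound*
on their causal effect on the endpoint, using observational data only.
The pipeline is: constraint-based structure learning → effect bounding on
the learned equivalence class (IDA) → stability selection across
subsamples.

## Structure learning

**PC-stable.** Starting from the complete undirected graph, edges are
removed level-wise: at conditioning-set size L the candidate separating
sets for a pair are the size-L subsets of the adjacency sets *frozen at
the start of the level*, which makes the result independent of variable
order. Pairs whose partial correlation passes the Fisher-z test at level
α are disconnected and the separating set recorded. Unshielded triples
a–b–c with b outside the recorded separating set of (a, c) become
colliders a→b←c, and Meek's rules R1–R3 are applied to a fixpoint.

**COPC-stable** adds chronological background knowledge:

1. the initial graph is complete but every cross-visit edge is
   pre-directed from the earlier visit to the later one (and every edge
   into the endpoint points at it);
2. candidate separating sets for a pair measured at visits t and t* never
   contain a variable measured strictly after max(t, t*) — the future
   cannot separate the past; this also makes COPC run strictly fewer CI
   tests than PC on the same data;
3. surviving cross-visit edges keep their chronological direction
   (a *partially directed skeleton*); collider orientation and Meek
   closure act only on the remaining within-visit undirected edges and
   treat the tier-directed edges as fixed background.

By construction the output CPDAG contains no arrow from a later to an
earlier visit and no undirected cross-visit edge; `classify_edges` counts
such "non-chronological" edges and the COPC path asserts the count is 0.

On finite data the constraint set can be internally inconsistent. The
orientation phases therefore never crash: an orientation that would
reverse a background edge or close a directed cycle is skipped with a
warning, and a pair proposed as a collider in both directions is left
undirected. Collider proposals are collected graph-wide and applied in
one batch, which keeps the phase order-independent.

**Separating-set search order.** Candidate sets are enumerated in
lexicographic order of the sorted frozen adjacency list, first from the
side of the lower-named endpoint; the first separating set found removes
the edge. This matches common reference implementations and makes runs
deterministic.

## Conditional-independence testing

Under joint normality, X ⟂ Y | S iff the partial correlation ρ_{XY·S}
vanishes. The sample correlation matrix is computed once per dataset (or
per subsample) and every partial correlation derives from it (closed-form
recursion at |S| ≤ 1, precision of the submatrix otherwise). The test
statistic is √(n − |S| − 3)·|atanh r| against the standard normal,
two-sided; the edge survives iff p ≤ α. α defaults to 0.02 (the
application value); larger α gives denser graphs.

The binary endpoint is included in the Fisher-z machinery as a 0/1
numeric column. This is a pragmatic approximation: the endpoint's
conditional mean is logistic, hence nonlinear, so partial correlations
involving it are only approximately zero under conditional independence.
A likelihood-ratio alternative (`outcome_test="logistic-lrt"`) fits
logistic regressions with and without the tested covariate and refers
2Δll to χ²₁; it is the statistically cleaner choice for endpoint pairs
but is slower and was not observed to change results materially at desk
scale, so the numeric approximation stays the default.

Missing values are rejected at load time with a pointer to impute
upstream; imputation itself is out of scope.

## Effect estimation

**Firth-penalized logistic regression.** Repeated measures are strongly
collinear and subsamples small, so ML logistic fits can diverge under
separation. The Jeffreys penalty ½·log det I(β) removes the first-order
bias and guarantees finite estimates; fitting is Newton iteration on the
hat-value-modified score with step-halving on penalized-likelihood
decrease. Inner tolerances (score 1e-9, step 1e-10, ≤ 100 iterations) are
tighter than the 1e-6 convergence contract so that closed-form cases
(intercept-only: logit of the half-corrected success proportion) are
reproduced to ~1e-8.

**Local IDA.** The CPDAG identifies the truth only up to Markov
equivalence, so each covariate X gets a multiset Θ_X of adjusted effects,
one per *locally valid* parent set: pa(X) ∪ S over subsets S of X's
undirected neighbours such that directing S→X creates no new collider at
X (every member of S adjacent to every other member and to every directed
parent). The reported bound is β_X = min |θ|, and the ambiguity â is the
number of distinct θ values at tolerance 1e-8 (â = 1 means the effect is
unambiguous; counting distinct values rather than multiset size is what
makes that reading exact). Two effect scales are available:

- `log-odds` (default): the Firth coefficient of X in a regression of the
  endpoint on X and the adjustment set;
- `risk-difference`: g-formula standardization of a one-unit increase of
  X from its mean, using the same fit.

The exact effect scale used in the original application could not be
pinned down; both candidates are first-class and the scale is always
explicit in the API and CLI. Only parents are ever adjusted for;
descendants never enter an adjustment set.

## Stability selection (CStaR) and PCER

The learner + IDA is repeated on B subsamples drawn without replacement
(default m = ⌊n/2⌋; the application protocol m = 30, B = 300 is available
through flags). Per run, covariates are ranked by β; across runs Π̂ is
the fraction of runs in which a covariate lands in the top q
(default q = ⌈0.1·p⌉, always reported). For Π̂ > ½ the per-comparison
error rate is bounded by q²/(p²(2Π̂ − 1)), else the bound is infinite.
Selection keeps covariates with PCER ≤ 0.5% by default. The reported
"median effect" is the median across runs of the per-run lower bound.
Top-q ties are broken by (bound descending, name ascending); runs that
fail are logged, excluded, and the effective B is reported. All
randomness flows from one `numpy` SeedSequence, so a fixed seed gives
byte-identical outputs.

Per-run CPDAGs are aggregated into a summary graph: an adjacency is drawn
iff present in ≥ 20% of runs, with thickness proportional to its
frequency; a direction is drawn only when its count strictly exceeds the
opposite direction plus undirected occurrences combined.

## Synthetic benchmark

The generator emulates the application's panel structure, not any real
biology:

- **Nodes**: p biomarkers × n_visits visits plus one endpoint in the final
  tier. Default p = 9, n_visits = 4 — 36 covariates + endpoint, the size
  of the smallest application panel.
- **Graph**: every tier-respecting ordered pair is a candidate edge
  (within-visit pairs ordered by biomarker index, so the graph is acyclic
  by construction), included independently with probability 0.1; the
  same-biomarker consecutive-visit chain edges are always present. Weights
  are uniform on [0.5, 1.5] in magnitude with random sign.
- **Data**: linear structural equations; the noise of one biomarker
  across visits is multivariate normal with AR(1) covariance
  ρ^|Δvisit|·σ² (ρ = 0.6 within the studied 0.5–0.7 range, σ² = 1),
  independent across biomarkers — this is what creates the collinearity
  of repeated measures the method must survive.
- **Endpoint**: Bernoulli with logistic link on its parents; the
  intercept is set to the negative empirical mean of the linear
  predictor, giving ≈ 50% prevalence.

What the generator does **not** emulate: non-Gaussian marginals,
missingness, unbalanced visit schedules, latent confounding, or dynamic
(visit-invariant) structure. A green benchmark therefore establishes
correctness of the algorithms under the stated linear-Gaussian tiered
world, not performance on real immunomonitoring data.

`run_scenario` draws per-replicate DAGs (or one fixed DAG), fits both
learners, and scores them against the true comparison graph — the CPDAG
of the covariate sub-DAG with the endpoint edges appended as directed
(the endpoint is measured last, so its edges are chronologically
identified). Sensitivity/specificity are confusion rates over unordered
node pairs (adjacency presence); SHD counts extra plus missing
adjacencies (a `full` variant additionally counts mark mismatches).
Reports carry both sd and standard error over replicates. Effect accuracy
is the MSE of IDA lower bounds against large-sample "true" effects:
per covariate, the same estimator applied to one seeded Monte-Carlo draw
(default 2·10⁵) with adjustment on the true parents.

At this desk scale the benchmark reproduces the qualitative orderings:
COPC-stable has higher sensitivity and lower SHD than PC-stable in every
grid cell, specificities stay ≥ 0.95, and COPC output never contains a
non-chronological edge.

## Numerical and degenerate-input choices

- Partial correlations are clipped to [−1, 1]; a singular correlation
  submatrix raises an error naming the conditioning set (collinearity
  signal). Conditioning sets are capped at n − 4 so the z test always has
  positive degrees of freedom.
- |r| = 1 yields p = 0 (dependent) with a warning rather than an error.
- Rank-deficient design matrices are rejected with the minimal set of
  dependent columns named.
- Specificity/sensitivity with an empty denominator (no true negatives /
  positives) are defined as 1 (vacuous truth).
- Duplicate variable@visit labels are rejected at load time; the outcome
  tier is forced strictly above all covariate tiers.

## Known limitations

- The Gaussian CI test applied to the binary endpoint is an
  approximation (see above); at large n it can retain a few extra
  endpoint edges.
- PC-type algorithms degrade on dense graphs; the benchmark's error
  cascade at small panels is visible as reduced specificity when the
  node-pair pool is small.
- No latent-variable machinery (FCI/PAG), no chain graphs, no
  time-series/dynamic constraints across visits, no imputation.
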