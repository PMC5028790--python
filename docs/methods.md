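# Methods

This note records the models implemented in `domcert`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want written
down.

## Dominance inference

**Win/loss matrix.** Every dyadic aggressive event is a win for the
actor, regardless of whether a submission was recorded; all severity
categories are retained by default (severity is parsed and kept but not
weighted). The matrix has a zero diagonal and its total equals the
number of retained events.

**Pathway evidence.** Indirect evidence for the pair (i, j) is the set
of directed *simple* paths i→…→j in the binarized win graph (an edge
exists iff at least one win was observed). Lengths 2 and 3 are counted
exactly by inclusion–exclusion on powers of the adjacency matrix
(subtracting walks that revisit the start or end node); longer lengths,
available via `max_path_len`, use an exhaustive depth-first search.
Length-1 "counts" are the raw direct win counts — direct evidence
scales with the number of observations, while for paths only existence
matters. Default maximum length is 3.

**Transitivity.** A dyad is *decided* when one animal holds strictly
more wins; triads with three decided dyads are classified cyclic
(A>B>C>A) or transitive, and t is the transitive proportion. Tied
dyads exclude their triads rather than being oriented arbitrarily.
With no closed triads t is undefined and treated as the uninformative
0.5 downstream.

**Imputed-win weighting.** A path of length ℓ ≥ 2 contributes
g(t, ℓ) = β·(2t−1)₊^(ℓ−1) imputed wins, with β = 0.5. The form is a
reference choice satisfying the constraints the method requires: the
weight grows with transitivity, decays with path length, vanishes at
t ≤ 0.5 (an untransitive network carries no usable indirect
information), and stays below 1 so a single direct win always outweighs
a single imputed win. The original percolation software's internal
weighting is not published; this g is the package's own documented
stand-in, and β is configurable (`indirect_beta`).

**Dominance probability.** DP_ij = P(X > ½) with
X ~ Beta(w̃_ij + 1, w̃_ji + 1) on the combined (direct + imputed) win
evidence. The add-one prior is the uniform Beta(1, 1): with no evidence
at all DP = ½ exactly, and DP_ij + DP_ji = 1 holds identically.
Certainty is c_ij = max(DP, 1−DP) and per-animal dominance certainty
DC_i is the arithmetic mean of c_ij over j ≠ i.

**Rank order.** The cost of an ordering is Σ (1 − DP_ij) over pairs
placed i-above-j, so a fully consistent probability matrix is minimised
exactly at its true order and strong contradicted placements are
expensive. Search is simulated annealing over adjacent transpositions
(the move's cost change is DP_ab − DP_ba), geometric cooling from
T = 0.5 to 10⁻⁴ over 200·N² proposals, warm-started from the
row-mean-DP order, followed by a greedy adjacent-swap polish; exact
ties resolve toward the initial id order, making the result
deterministic for a given seed (default 0). For N ≤ 8 the tests verify
the result against exhaustive permutation search. Ordinal ranks are
reported as the proportion of groupmates outranked,
r = (N − ordinal)/(N − 1).

**Certainty categories.** Per group, sorted DC values are regressed on
their empirical quantile with a continuous two-breakpoint piecewise
linear model; breakpoints are found by a coarse-to-fine grid search on
the quantile axis (deterministic, no local-minimum risk, equivalent to
iterative-linearization fits on well-behaved data) and mapped through
the fitted curve to the DC scale. Categories are group-specific because
DC distributions differ across groups. A constant DC vector yields a
single "moderate" category with a warning.

**Node-removal sensitivity.** Because network metrics share edges
across nodes, the package can delete named animals one at a time,
rerun the whole dominance chain, and report Pearson and Spearman
correlations between original and recomputed DC over the retained
animals.

## Health-outcome models

Ten hypotheses relate outcomes to sex, age class (3 / 4–5 / 6–12 /
13+ years; adults 6–12 the referent, males the referent sex), rank,
DC and their interactions, up to the full sex × rank × DC structure.
H6, H7a and H7b include the DC main effect alongside their
interactions, matching the fitted-model structure of the motivating
analysis (its hypothesis-table shorthand omits it). Controls: blood
outcomes carry sample-processing order; CRP additionally carries IL-6;
diarrhea-bout models carry a log observation-days offset. Families:
negative binomial (NB2, Var = μ + αμ²) with log link for IL-6, TNF-α
and bout counts; gamma with log link for CRP. Biomarker preprocessing
assigns 1 to cytokine values strictly below the 1.6 pg/mL assay floor
(exactly 1.6 is kept) and flags, but retains, CRP > 10.

**Estimation.** Each model is a GLMM with a scalar Gaussian group
(cage) intercept, fit by Laplace approximation: the scalar-per-group
random effect makes the inner problem a damped 1-D Newton iteration,
and the outer marginal likelihood is maximised by BFGS with a
Nelder-Mead fallback — fully deterministic. Dispersion and σ_b are
estimated on the log scale; as σ_b → 0 the marginal likelihood
converges to the ordinary GLM likelihood (verified against the
statsmodels GLM fit in the tests). Standard errors come from a
finite-difference observed-information matrix; when the σ_b direction
is flat (common with 3 groups) the fixed-effect block is extracted by
Schur complement with a pseudo-inverse. The parameter count for
information criteria is fixed effects + 1 dispersion + 1
random-intercept variance, and
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1).

**Selection.** ΔAICc from the best model, model likelihood
L = exp(−ΔAICc/2), Akaike weights w = L/ΣL, evidence ratio
w_best/w. If the best weight is ≥ 0.90 the candidate set is that
single model; otherwise all models with ΔAICc ≤ 5 except the null —
a null model can sit inside the window purely on its parsimony
penalty while offering nothing to interpret, and excluding it matches
the motivating analysis's reported candidate sets.

**Effect sizes.** On the log link, the effective slope of a predictor
is its main-effect coefficient plus each interaction coefficient
evaluated at supplied moderator values; the fold change for a shift Δ
is exp(slope·Δ), reported as an "x times increase/decrease" with the
reciprocal taken below 1. Reciprocity (fold(Δ)·fold(−Δ) = 1) holds by
construction.

## Synthetic studies

The generator emulates three outdoor breeding groups of ~120 rhesus
macaques observed for six weeks:

- **Hierarchy.** Latent scores equally spaced so that the
  Bradley–Terry win probability between rank-adjacent animals is 0.80
  (a steep, despotic hierarchy); win probabilities for all pairs follow
  the logistic of the score difference.
- **Ambiguity.** Each dyad's win probability is flattened toward ½ by
  a factor peaking (0.98) mid-hierarchy with a Gaussian profile
  (width 0.30 of the rank range) and decaying slowly with rank
  distance. This makes mid-ranked relationships genuinely undecided and
  produces, by construction, the U-shaped certainty–rank curve.
- **Contact process.** Dyads are sampled with exponential rank-distance
  decay (scale 0.35·N) times lognormal dyad propensity noise (σ = 0.8),
  with 0.80 events per dyad overall. Realized sparsity: ~43% of dyads
  interacting at ~1.85 events per interacting dyad, and >95% of decided
  triads transitive — the empirical regime. These four contact
  parameters were calibrated once against those regime statistics and
  then frozen.
- **Outcomes.** Log-linear models in true rank and true certainty with
  a group random intercept (SD 0.25): NB (α = 0.5) for IL-6/TNF-α with
  the published best-model coefficient values as generating defaults,
  gamma (shape 2) for CRP, and a per-observation-day Bernoulli
  liquid-stool process (logistic in DC and rank) aggregated by the
  bout-counting rule itself, so the bout definition is exercised by the
  generator. Twice-weekly checks over six weeks with 3% of days
  unobserved.

**What passing tests do and do not show.** The generator draws events
independently given the hierarchy; it has no temporal rank dynamics,
no kin structure, no observer error, and its ambiguity is a smooth
function of rank position rather than emergent social process. Order
recovery (Spearman ≈ 0.99) and the regime statistics therefore
validate the inference machinery in a well-specified world, not
performance on real colony data. A measured limitation worth knowing:
with <2 observations per interacting dyad, *animal-level certainty* is
only weakly identified from one observation window — estimated DC
correlates ~0.5 with the generating truth, and its spread is
compressed. Rank, by contrast, is recovered almost perfectly. For this
reason the end-to-end model-selection check fits the hypothesis set on
the study's retained generating covariates (the outcome simulator
accepts true or estimated covariates): it validates that the AICc
machinery detects the rank × certainty interaction at the configured
effect sizes, while certainty-estimation fidelity is assessed
separately by the U-shape and sensitivity checks. Regressions of
health outcomes on *estimated* DC from a single sparse window should be
expected to be strongly attenuation-biased — in simulation and in the
field.

## Numerical notes and degenerate inputs

- DP complementarity holds to < 10⁻¹² by construction
  (regularized-incomplete-beta symmetry).
- Zero-evidence dyads: DP = ½, certainty ½.
- No closed triads: transitivity undefined → imputed weights 0.
- Annealing: 200·N² proposals; ~1 s at N = 120. Restarts (off by
  default, used for small exhaustive-checked problems) draw from the
  same seeded generator.
- Segmented fit: breakpoints constrained to quantiles [0.02, 0.98]
  with a minimum gap of 0.05; coarse 40-point grid then a 21-point
  local refinement.
- GLMM: gamma family requires strictly positive outcomes; diarrhea
  models require positive observation days; fits with < 2 groups are
  rejected.
- Problem sizes in the tests: three groups of 118–124 for the regime
  checks, 20 regenerated studies for order recovery, 50 simulations at
  n = 250 for mixed-model coverage, N ≤ 8 for the exhaustive oracles.

## Known limitations

- The imputed-win weight g and the Beta prior are documented stand-ins
  for an unpublished reference weighting; absolute DC values are
  therefore not comparable across packages (here they concentrate
  higher in [0.5, 1] than published colony values), though orderings
  and the U-shape are.
- Whether repeated direct interactions should saturate (diminishing
  returns) is unresolved; the implementation lets direct evidence
  accumulate linearly.
- The hypothesis set and candidate-set rule are fixed by design;
  model-averaged coefficients are out of scope.
- Sensitivity correlations are computed on DC; the choice of which
  network measure to use for removal checks is a judgement call.
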