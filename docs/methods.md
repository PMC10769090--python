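# Methods

## Metabolic-scaling community model

**Web generation.** Communities of `S = 35` species (the default; any
`S ≥ 2` is supported) receive a random predation structure from the classic
niche model: niche values `n_i ~ U(0,1)`, feeding ranges `r_i = x_i n_i`
with `x_i ~ Beta(1, 1/(2C) − 1)` so the expected connectance equals the
target, and range centres `c_i ~ U(r_i/2, n_i)`. The target connectance is
tied to richness, `C = S^-0.65`. The smallest-niche species is forced basal,
cannibalistic self-links are stripped, and draws are rejected until the web
has no isolated species, at least one basal species, every consumer
reachable from a basal species, and realized connectance within ±20 % of the
target (a bounded retry loop; the Monte-Carlo mean over many webs lands
within ~1 % of the target).

**Trophic levels and masses.** Prey-averaged trophic levels solve the
linear system `TL_i = 1 + mean(TL of prey)`; basal species have `TL = 1`.
The system is nonsingular because every consumer is grounded in a basal
species. Masses follow `M_i = M0 · Q^(TL_i − 1 + ε_i)` with `Q = 10^3`
(the mean mass ratio between adjacent levels), `M0 = 1` in arbitrary units,
and `ε_i ~ N(0, 1)`. The resulting within-community median predator-prey
mass ratio typically falls in 10–10⁴.

**Transfer efficiency and the scaling coefficient.**
`TE_i = TE_max · M_i^-0.03 / max_j(M_j^-0.03)` declines weakly with mass
and attains its ceiling `TE_max` at the smallest species. Each species'
biomass scales as `B_i ∝ M_i^{k_i}` with the energetic-equivalence baseline
`k = 0.25` for basal species and, for a consumer with `n_j` prey,
`k_i = 0.25 + (1/n_j) Σ_j t_ji / log(PPMR_ji)`, where `t_ji = log(TE_i)`
when the predator outweighs its prey and `log(1 − TE_i)` when the prey is
heavier — the sign convention that keeps higher efficiency pushing `k`
upward on both sides of `PPMR = 1`. Links with `PPMR = 1` exactly are
excluded from the average (the log-ratio is undefined; a probability-zero
event under continuous masses), and a consumer whose every link has
`PPMR = 1` is an error. The proportionality constant in `B_i = M_i^{k_i}`
is set to 1; the fitted slope is invariant to it.

**Community slope.** `k_c` is the ordinary least-squares slope of
`log10 B` on `log10 M` (base-invariant since both axes share the base).
The fit is computed directly in log space, `log10 B_i = k_i · log10 M_i`,
which is exact and avoids floating-point under/overflow of `M^k` when a
near-unit PPMR inflates `k_i`. Plain (unweighted) least squares is used.
With the correction disabled (all `k_i = 0.25`) the fit returns 0.25 to
machine precision; with every linked predator heavier than its prey, every
correction term is negative, so `k_i ≤ 0.25` with equality only for basal
species.

**Harvest.** A fraction (default 40 %) of species is drawn without
replacement with selection probability proportional to mass, and each
harvested species is assigned a removal level `r_i ~ U[0.3, 1]`. The model
only constrains harvest to reduce both abundance and mean body mass; we
operationalize it with a truncated-lognormal individual-size model:
individual masses are lognormal with mean `M_i` and log-scale s.d.
`sigma_intra` (default 0.5, natural log), and harvest removes the heaviest
`r_i` fraction of individuals. The closed forms are, with
`z = Φ⁻¹(1 − r)`: surviving biomass fraction `Φ(z − σ)` (lognormal partial
expectation), surviving number fraction `1 − r`, and surviving mean-mass
ratio `Φ(z − σ)/(1 − r)`. Setting `sigma_intra = 0` recovers pure abundance
removal (mean mass unchanged). The closed forms are verified against
numerical quadrature of the lognormal density to 10⁻⁶. The harvested slope
`k_c^h` is refit on all species using post-harvest masses and biomasses.

**Experiment.** For each `TE_max ∈ {0.1, 0.3, 0.5, 0.7}`, `n_reps`
replicate communities are simulated and harvested (a single root seed
spawns independent per-replicate streams). The default replicate count for
the full study is 1000; the packaged tests and examples run 200 per level,
which is ample to resolve the two qualitative contrasts of interest —
median `k_c` rising with `TE_max`, and harvested medians below protected
medians at every level.

## Survey-table metrics

Long-format survey tables (site, year, survey, species, mass, abundance,
biomass) are aggregated by site-year: species biomass is summed across
surveys within a year (conserving total biomass; whether the original
yearly aggregation summed or averaged is not determinable, and the slope
is unchanged by a common factor), mean mass is abundance-weighted, and
observations are retained when surveyed at least twice that year with at
least five species (both thresholds inclusive). Per community we compute
the empirical slope `k_c^e` (OLS of log biomass on log mass), the
community-weighted mean body mass (abundance-weighted), and Spearman's
rank correlation between body mass and trophic level (undefined — NaN —
for constant inputs). Thermal stress anomalies count weeks in which SST
exceeds the maximum weekly climatological SST by strictly more than 1 °C
(a week at exactly +1.0 °C does not count). Median binarization maps
values strictly above the median to 1 and everything else — including
ties at the median — to 0, so at most half the entries become 1.
Rarefaction resamples surveys without replacement at each effort level and
averages pooled richness; two-sample Kolmogorov–Smirnov comparisons use
the asymptotic p-value at α = 0.05.

## Causal toolkit

**G² test.** Conditional independence of two binary variables given a set
S is tested with the stratified log-likelihood-ratio statistic
`G² = 2 Σ O ln(O/E)` summed over the 2×2 tables of every nonempty
configuration of S, with expected counts from within-stratum margins.
Zero-observation cells contribute nothing. Degrees of freedom are
`(2−1)(2−1)` per nonempty stratum — empty strata are skipped, the common
sparse-table correction. Independence is rejected at p < α with α = 0.05
and no multiple-testing correction, matching standard practice for this
discovery procedure. At n = 2000 the test's type-I error calibrates to
α within Monte-Carlo error.

**Discovery.** The skeleton search is exhaustive: an edge X—Y is removed
iff some conditioning subset of the remaining variables (scanned in
increasing cardinality, deterministic column order) renders the pair
independent; the first separating set is recorded. This is feasible for
the five-variable site problem (the intended regime, p ≲ 8). Colliders
X→Z←Y are oriented for nonadjacent X, Y with common neighbor Z exactly
when Z is outside the recorded separating set — the deterministic sepset
formulation of the collider rule. Orientation conflicts are resolved in
favor of the earlier triple in lexicographic order and recorded on the
graph. Only orientation rule R1 (orient b—c into b→c when a→b exists and
a, c are nonadjacent) is applied, to a fixpoint; it is the only rule the
five-variable protection graph needs, and an application that would create
a directed cycle raises.

**d-separation and Rule 2.** d-separation uses the linear-time
reachability ("Bayes-ball") formulation with collider opening via
descendants; it is cross-checked in the tests against an independent
brute-force path-enumeration oracle, exhaustively on all labeled DAGs
with up to 4 nodes and on a seeded sample of 5-node DAGs with every
(pair, conditioning subset) query. The do-calculus Rule 2 check deletes
arrows into X and out of Z and returns the d-separation verdict of
(Y ⫫ Z | X ∪ W); with X = W = ∅ it licenses replacing P(Y | do(Z)) by the
observational P(Y | Z).

**Genuine cause.** The three-step criterion is evaluated on all routes:
step (i) X dependent on Y given the full context; step (ii) a candidate
Z dependent on X given the remaining context plus the outcome (the
conditioning set includes the outcome variable by design of the
criterion's tabulation), with a witness W satisfying Z ⫫ W marginally and
W dependent on X; step (iii) Z dependent on Y given the remaining context
but independent once X joins the conditioning set. Three context
variables yield six routes; the report records every sub-test's G², df
and p, each route's verdict, and the count of passing routes (more routes,
stronger support). The ACE is the observational success-probability
contrast between treatment arms, valid as an interventional quantity when
Rule 2 holds for the discovered graph.

## Synthetic generators and what they do (not) emulate

**Site-table SCM.** Human, TSA and Coral are independent Bernoulli(0.5)
draws; MPA follows an additive conditional probability table
`P(MPA=1 | h,t,c) = 0.08 + 0.28h + 0.30t + 0.26c`, chosen faithful (no
cancelling pathways) with each driver leaving a distinct, strong marginal
footprint; the latent structure score is `1.14·MPA + N(0,1)`, binarized
strictly above the *sample* median for the data and above the *population*
median (the mixture-CDF root) for the ground truth — the mismatch is
O(n^-1/2) and vanishes at the default n = 10⁴. The effect size 1.14 makes
the closed-form interventional ACE ≈ 0.431, a convenient reference scale
for the protection effect; it is a modeling choice, not an empirical
claim. With these defaults the discovery pipeline recovers the generating
graph (four edges, three colliders, MPA→Structure) in ≥95 % of seeds at
n = 10⁴. A degenerate CPT (every row 0 or 1) is rejected as unfaithful.

Real site tables differ in ways the SCM deliberately ignores: spatial
autocorrelation between nearby sites, temporal dependence across years,
measurement error in the drivers, and any latent confounding. Passing
tests therefore demonstrate correctness of the machinery under
faithfulness and causal sufficiency, not robustness of empirical
conclusions to their violation.

**Survey tables.** Per-site species masses are log-uniform over a
configurable range and `log10 B = k · log10 M + intercept + N(0, σ²)` with
a prescribed slope per site; every species appears in two surveys with
equal biomass shares so the effort filter retains all sites and
aggregation reproduces the configured totals exactly. Noiseless tables
recover the prescribed slope to machine precision; noisy slopes are
unbiased. The generator does not emulate abundance-mass covariance,
zero-inflation, or detection error.

**SST series.** Deterministic: 0.5 °C below the climatological maximum
except in designated weeks sitting a configurable margin above it, giving
exact control of the thermal-stress-anomaly count including the strict
1 °C boundary.

## Numerical and design notes

- Single root seed everywhere; `numpy.random.SeedSequence.spawn` gives
  independent per-replicate streams, and all generators are bit-for-bit
  reproducible from their seed.
- Regression slopes use base-10 logs on both axes (base-invariant).
- `round(harvest_fraction · S)` species are harvested (14 of 35 at the
  40 % default), clamped to [1, S].
- Removal levels are clipped away from 1 by 10⁻¹² before the truncated
  lognormal quantile to avoid a degenerate survivor set.
- The acceptance script runs the two desk-scale reference computations
  (the EEH baseline slope and the predator-heavier bound) at S = 35 and
  500 replicate communities respectively.
- Known limitations: no population dynamics or temperature dependence in
  the simulator; the causal toolkit assumes binary variables, no latent
  confounders (no FCI-style search) and implements only rule R1 of the
  orientation rules; the exhaustive skeleton search is exponential in the
  variable count and intended for small variable sets.
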