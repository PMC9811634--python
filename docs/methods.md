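# Methods

This note documents the statistical procedures implemented in
`reefcontests`, the choices that were genuinely open, and what the synthetic
data can and cannot establish.

## Data model and inclusion rules

An encounter is one observed interaction within 1 m between a focal fish and
a congeneric partner: region, reef, period (`before`/`after` the resource
loss event), focal individual id, the two species labels, an ordinal
proximity category (1 = 0–24 cm, 2 = 25–49 cm, 3 = 50–74 cm,
4 = 75–100 cm), an outcome (`passive`, `signal`, `chase`) and, iff the
outcome is a chase, the chase distance in metres. Validation enforces these
invariants row by row and either raises with row numbers or collects a
rejects table.

Species labels are canonicalized by trimming, whitespace-collapsing and
case-folding; no synonym resolution is attempted. Individual identity is
meaningful only within reef × period — the field protocol (a U-shaped search
observing one member of each mated pair) minimises resampling but cannot
link individuals across periods — so nothing in the package treats
before/after as paired observations.

The unit of analysis is the unordered species pair. A pair enters the
analysis only with ≥ `min_encounters` encounters across ≥ `min_individuals`
distinct focal individuals (defaults 5 and 5). Open choices resolved here:

* **Which individuals count.** Only focal individuals are identified in the
  data, so the five-individual criterion counts focal ids.
* **Pooling across periods.** The filter pools both periods by default; a
  `per_period` switch applies it within period instead.
* **The matched subset** keeps only species that pass the filter in at least
  one conspecific *and* one heterospecific pair. Filtering on the focal
  species can in principle re-expose a pair to the thresholds, so the
  reduction is iterated to a fixed point; this makes the operation
  idempotent and the result independent of how many times it is applied
  (the iteration almost always terminates after one pass).
* **Chase capping.** Rare very long chases are grouped at ≥ 10 m; this is
  represented as capping at exactly 10.0 m (configurable). CVs are computed
  on capped distances by default (`cv_on_capped`), i.e. the cap is applied
  before any dispersion statistic; a switch computes them uncapped instead.
* Means of the ordinal proximity codes are used because the four bins have
  equal 25 cm widths, making the 1–4 codes an equal-interval scale.

## Permutation tests

**Rank test.** For two samples of per-individual mean proximities, the
statistic is the standardized mid-rank sum
Z = (T − E[T])/sd[T], where E and sd are the exact permutation moments of a
sum of n_x values drawn without replacement from the pooled mid-ranks
(Var = n_x·n_y/(N(N−1))·Σ(r−r̄)²; ties enter through the rank variance, which
is the tie-corrected form). The p-value is Monte-Carlo: the proportion of
random relabellings with |Z| ≥ |Z_obs| (two-sided), counting the observed
permutation, so p ≥ 1/(n_resamples+1). Default 10 000 resamples; the count
is recorded in every result. If every pooled value is tied the statistic is
defined as 0 with p = 1.

**Contingency test.** Pearson's X² (no continuity correction) of the 2×2
class × (signal, chase) table, against the permutation null of the labels;
for a 2×2 table the permuted statistic is a function of a single cell whose
permutation law is hypergeometric, which is sampled directly (verified in
tests against brute-force enumeration of label permutations). Upper-tail
Monte-Carlo p with the observed permutation counted. A table with a zero
margin is degenerate: statistic 0, flagged. Because the permutation
distribution of X² on discrete data is itself discrete, the test is slightly
conservative at small n — an inherent property of exact-style tests, not a
defect; calibration is essentially nominal once cell counts are moderate.

**One-per-individual bootstrap.** Repeated encounters by one focal fish are
not independent. Each of B = 1000 replicates draws one encounter per
individual uniformly at random, runs the inner test, and the replicate
(statistic, p) pairs are summarised by their means and 95% percentile
intervals (2.5/97.5); the interval type is a package choice, since a bare
"±" display does not identify one. Selection is one encounter per focal
individual across all of that individual's encounters in the analysis
subset, not per pair.

## CV equality (SLRT / MSLRT)

The coefficient of variation is reported with the n−1 sample standard
deviation; the likelihood machinery uses MLE (n-denominator) quantities
internally. Under a normal working model with per-group mean μ_i and
σ_i = τ μ_i, the constrained maximum over a common τ profiles each mean
analytically: the optimal μ_i is the positive root of
τ²μ² + x̄μ − (v + x̄²) = 0 (v the MLE variance), leaving a bounded
one-dimensional maximization over τ (Brent, converged to ~1e−12 in τ;
verified against a dense independent grid search over (τ, μ₁, μ₂)). The
signed likelihood-ratio statistic is Λ = 2(ℓ̂₁ − ℓ̂₀) ≥ 0, referred to
χ²(k−1).

The χ² approximation drifts upward in small samples, so the **modified**
statistic rescales Λ by a parametric Monte-Carlo moment (Bartlett-type)
calibration at the constrained MLE: simulate `n_sim` (default 2000) datasets
with the fitted common CV, group means and group sizes, and set
Λ_M = (k−1)·Λ / mean(Λ_sim). This is what makes the test robust to unequal
group sizes. The simulated statistics are maximized by vectorized bracketed
grid refinement (6 rounds × 33 points), accurate far beyond the Monte-Carlo
noise in the mean. The correction's simulation seed is part of every result.

The normal working model is applied to capped chase distances even though
capping (and the underlying right skew) violates normality; the same
working-model-on-skewed-data behaviour is exercised deliberately in the
type-I simulations with the generator's lognormal chases, and the modified
test remains approximately calibrated at the sample sizes used here.

## Comparative models

Patristic distances (sum of branch lengths along the leaf-to-leaf path) come
from the Newick phylogeny via dendropy; absent branch lengths are an error
unless a default is configured. Body-size difference is |max length a − max
length b| in cm from the trait table. Pair observations are heterospecific
only (conspecific pairs would concentrate zeros in the distance predictor):
mean proximity over all the pair's encounters, (n_signal, n_chase) over its
aggressive encounters, and the chase CV only when the pair has at least
`min_chases` (default 5, mirroring the global inclusion rule) chases. OLS
(with intercept) is used for mean proximity and chase CV — adjusted R² is
reported raw in the machine report, where it may be negative, and floored at
0 only in human-readable output — and a logit-link binomial GLM on the
aggregated counts for signalling, with McFadden's R² = 1 − ℓ̂/ℓ̂₀ (exactly 0
for an intercept-only fit). Period is pooled in these models by default. No
phylogenetic error structure (e.g. PGLS) is applied: the responses are pair
properties, not species traits, so ordinary regressions are the appropriate
fit here.

## Synthetic generator

`simulate.generate_dataset` draws: individuals per species × reef × period
(independent; no territory geometry), encounter counts 1 + Poisson(mean−1),
conspecific partners with a fixed probability, ordinal proximity by
thresholding a latent Normal approach distance (clipped into (0, 100) cm) at
25/50/75 cm, aggression with probability decaying geometrically per
proximity bin (contests start close), signal-vs-chase resolution with
class/period probabilities, and lognormal chase distances parameterised by
mean and CV. All before→after differences are multiplicative
`PeriodEffects` on per-class baselines, so identity effects give an exact
before/after null, and equal class parameters give an exact class null —
the configurations used for calibration tests.

`field_scenario` fixes the study conditions once: ~2350/1300 encounters
before/after; aggressive fractions ~0.16/0.06; signalling proportions
0.07/0.28 (con/het) before and 0.05/0.08 after; conspecific latent approach
35 cm vs heterospecific 60 cm (45 cm after); conspecific chases lognormal
mean 3.46 m, CV ~1.01 in both periods; heterospecific mean 1.35 m, CV 1.34
before and 1.67 m, CV 0.99 after. Two caveats documented deliberately:
the lognormal mean/CV describe the *uncapped* distribution, so the 10 m cap
compresses observed conspecific CVs (≈0.76 rather than 1.01) while barely
touching heterospecific ones — the class ordering and its before→after
convergence are preserved; and with ~25–30 heterospecific chases in the
after period, sample CVs carry standard errors of ~0.2–0.3, so the
*point-estimate* convergence of the class CVs after the event is reproduced
in most but not all simulated datasets. What passing tests show is that the
machinery recovers planted effects and is calibrated under the null; they do
not show that real encounter data meet the working models' assumptions
(observer effects, spatial structure and cross-period identity are not
simulated).

## Numerical and reporting conventions

* Monte-Carlo p-values use the add-one convention; seeds and resample counts
  are recorded in every result object and in the run report.
* All pipeline randomness derives from one master seed via a seeded child
  sequence (each child < 2³¹, logged in the report); identical inputs and
  master seed give a byte-identical machine report (JSON with sorted keys).
* Stages after filtering are independent: a failure in one prediction is
  recorded under `errors` and the rest still run.
* Degenerate inputs are results, not crashes: all-tied rank data → Z = 0,
  p = 1; zero-margin tables → X² = 0 with a flag; no aggressive encounters →
  signalling proportion NaN; fewer than 2 chases in a class → the CV
  comparison is skipped with a note.
* Problem sizes in tests and the acceptance script: calibration uses 1000
  null datasets per test; direction recovery uses 100 field-scale datasets
  with reduced resampling depth (the direction checks are point estimates
  and do not depend on the Monte-Carlo depth); the acceptance script runs
  the full depths (10 000 / 1000 / 2000).
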