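# Methods

## Model and estimation

The package fits the Andrich rating-scale model (RSM): polytomous Rasch
model in which every item shares one vector of category thresholds.  For
internal categories k = 0…K,

    P(X_ni = k) ∝ exp( Σ_{j≤k} (θ_n − δ_i − τ_j) ),

with the empty sum for k = 0.  θ, δ and τ live on one logit scale.  The RSM
(rather than the partial-credit model) is the right choice for a short
instrument whose items all use the same verbal rating scale; it also makes
the pooled category diagnostics of Step 1 well defined.

Estimation is joint maximum likelihood (JMLE): alternating damped
Newton–Raphson sweeps over persons, items and thresholds.  The person and
item sweeps use the exact diagonal information (observed raw score minus
expected score over summed cell variances); the threshold sweep uses the
exact coordinate-wise curvature P(X≥j)(1−P(X≥j)) summed over cells.
Identification: mean(δ) = 0 over non-extreme items and Σ τ = 0, re-applied
every cycle.  Defaults: convergence when the largest absolute parameter
change drops below 1e−4 logits, 200-cycle cap, Newton steps clipped to ±1
logit, PROX-style logit starting values.  JMLE was chosen for fidelity to
the Winsteps-family workflow this protocol mirrors; its finite-test
inconsistency is accepted and documented rather than hidden: with L = 10
items the estimated δ spread is inflated by roughly L/(L−1), which leaves
correlation-based recovery untouched (r(δ̂, δ) ≈ 0.999 at N = 1000) but
puts uncorrected RMSE(δ) near 0.14 logits.  An optional (L−1)/L shrinkage
flag (`EstimationSettings.bias_correction`) brings RMSE(δ) to ≈ 0.04
logits and is used by the recovery checks.

Extreme persons and items (minimum or maximum raw score) carry no
information about their own location; they are excluded from estimation and
afterwards assigned measures at their raw score pulled in by 0.3 score
points (`extreme_adjust`), via test-characteristic-curve inversion.  A
category never observed among non-extreme cells leaves its threshold
unidentified (it would drift to ±∞); estimation refuses such data with a
pointer to the category-collapse transformation.

`score_to_measure` inverts Σᵢ Eᵢ(θ) = raw score by Brent root-finding on
[−30, 30] logits; SE = 1/√ΣWᵢ.

## Fit statistics

Per cell: residual e = x − E, variance W, fourth central moment C.  Outfit
MnSq is the unweighted mean of z² = e²/W; infit MnSq is Σe²/ΣW.
Standardized values use the Wilson–Hilferty cube-root transform with
variance q² built from C and W (outfit: Σ(C/W²)/n² − 1/n; infit:
Σ(C − W²)/(ΣW)²), the Winsteps convention — the protocol's "z-value" has no
printed formula anywhere else.  Cells belonging to extreme persons/items
are excluded (their residuals are artifacts of the assigned measures).

Decision rules: item misfit iff infit MnSq outside the closed interval
[0.7, 1.3] (the published criterion says "between"; the closed convention
means a boundary value passes — boundary cases are visible in the fit
table).  The criterion is stated in "logits" in the source protocol; mean
squares are unitless and are implemented as such.  Person flagging requires
the conjunction infit MnSq ≥ 1.4 AND infit z ≥ 2, with a 5 % chance budget
on the flag rate.  Person fit uses infit for the verdict; outfit is
reported.

## Rating-scale diagnostics

Average measure per category = mean θ̂ of persons contributing observations
in that category, pooled across items (one shared rating scale); a per-item
breakdown is available (`per_item=True`) since the protocol's wording can
be read either way.  Category outfit = mean z² over the category's
observations.  Verdict: monotone average measures and all category outfits
< 2.0.

A caveat the synthetic experiments expose: on a severely mistargeted cohort
(persons ≈ 2.5 logits above the items, as the ceiling-prone survey
population requires) the bottom categories are observed mainly as rare,
highly unexpected responses, and their conditional mean z² sits near or
above 2.0 even when the data are generated exactly from the model.  The
category-outfit criterion is therefore sensitive to targeting, not only to
scale malfunction, and Step 1 can fail on the survey-shaped cohort while
passing comfortably on a well-targeted one.  Category collapsing is
provided as an explicit transformation (`collapse_categories`) but never
applied automatically — the protocol under study kept all five steps.

## Internal structure

Local independence: pairwise Pearson correlations of standardized-residual
columns (pairwise-complete when missingness is allowed); screen at |r| <
0.7 ⇔ shared variance < 50 %.

Unidimensionality: variance explained by measures =
100·ΣᵢVarₙ(E_ni)/(ΣᵢVarₙ(E_ni) + ΣᵢVarₙ(e_ni)) over non-extreme cells —
the decomposition of observation variance into model-expectation variance
plus residual variance, mirroring the "raw variance explained by measures"
bookkeeping of the Winsteps tradition (versions differ subtly; exact parity
with any one program is not claimed).  The first contrast is the largest
eigenvalue of the L×L residual correlation matrix; on the correlation
(not covariance) scale eigenvalues sum to L, so the 2.0 cut-off reads as
"two items' worth" of residual covariation.  Null simulations at N = 761,
L = 10 put the first contrast near 1.25–1.45; an additive secondary trait
with loading 0.8 and SD 1.25 on half the items pushes it past 2.0 with
probability ≥ 0.9.

## Reliability and precision

Over non-extreme persons: R = (Var(θ̂) − mean SE²)/Var(θ̂) clipped at 0,
G = √(R/(1−R)), strata H = (4G+1)/3.  The pass criterion is G ≥ 2.0 and
R ≥ 0.7 ("three distinguishable levels"); H is reported as supporting
information.  Raw-score Cronbach alpha is computed alongside because the
protocol invokes the KR-20/alpha equivalence and the published reliability
of 0.83 could be either quantity.  Floor/ceiling counts scan raw response
patterns of all persons, extremes included — they are exactly the extreme
patterns.  The Wright map is rendered as a binned text display plus a CSV
bin table; targeting offset = mean θ̂ − mean δ̂.

## Differential item functioning

Mantel chi-square for polytomous items, two groups at a time, stratified by
total raw score on the retained item set (the sufficient statistic for θ
under complete data; adjacent score levels merged to ≥ 10 respondents per
stratum).  Within stratum s the focal score sum O_s is compared with its
hypergeometric mean E_s and variance V_s = n_f n_r Σ(y−ȳ)²/(n(n−1));
χ² = (ΣO − ΣE)²/ΣV on 1 df.  Exact enumeration of group allocations on
tiny strata validates E and V.  Merging two strata with identical
group-by-score tables changes the statistic only through the finite-stratum
factor (n−1 in each part vs 2n−1 pooled), so strict merge-invariance holds
only asymptotically; the test asserts it with a matching tolerance.

Multi-level factors are compared pairwise (a g-level factor gives
g(g−1)/2 pairs per item); the Bonferroni family is items × pairs within
each factor, and eNPS enters as its three classes.  Factor levels under 10
respondents are dropped; single-group strata are dropped; no purification
loop (single-pass scan, as in the protocol being mirrored).

## Protocol orchestration

The removal loop in Step 2b removes one item per pass — the misfitting item
with the largest |infit − 1| — then refits, because fit statistics are
interdependent; it stops when everything fits (or fewer than two items
would remain, which aborts).  Steps 1 and 2a are computed on the full
instrument, Steps 2c–5 and the index on the retained set.  Verdicts are
pure functions of (data, config); reports serialize to JSON and re-running
with the same inputs is byte-identical.

The mean-value index is the plain raw mean of the index items (default:
all retained items, i.e. the first ten after the contaminated item drops; a
nine-item convention is available via `AnalysisConfig.index_items`),
rescaled as (mean−1)/4×100 to a 0–100 axis.  Its Pearson correlation with
the Rasch measure excludes the all-minimum (floor) pattern by default,
optionally the ceiling; under complete data the raw-sum→measure map is
strictly monotone, so the Spearman correlation is exactly 1 and Pearson r
falls below 1 only through the ogive's curvature at the extremes.

## Synthetic data

The generator draws θ ~ N(μ, σ), samples categories from the RSM, and can
inject three pathologies matched to the protocol steps that must detect
them: uniform DIF (difficulty shift for a focal group), an additive
secondary trait on an item subset, and careless (uniform-random)
responders.  Background factors are drawn with the study organisation's
composition (88 % female, 82 % co-workers, three age and tenure bands, eNPS
available for ~40 %) and independently of responses unless a DIF spec ties
them — giving exact type-I-error nulls.

The default survey-shaped cohort is N = 761, 11 items, 5 categories,
δ spread ≈ 1 logit with the patient-involvement item hardest, τ = (−1.8,
−1.5, 0.3, 3.0) (the first two thresholds close together squeeze category
2, as the published category-probability curves show), and θ ~ N(2.5, 2.0),
calibrated once against the published per-item category frequencies: pooled
category shares ≈ (2.6, 3.4, 14.4, 40.6, 39.1) % against the published
(1.3, 3.3, 15.3, 40.8, 39.2) %, with an all-maximum ceiling group near 5 %.
What this cohort does NOT emulate: the real respondents' clustering by
unit, any true multidimensionality or item-specific rating-scale use, and
the unknown real ability distribution (only its right-skewed, ceiling-prone
shape).  Passing the pipeline on synthetic cohorts therefore demonstrates
that the machinery detects what it claims to detect at the stated powers —
not that any particular real instrument is valid.

`fixture_from_marginals` rebuilds a matrix whose per-item category counts
equal a printed frequency table exactly by shuffling each item's multiset
column independently; its joint structure is random, so it validates I/O
and marginal bookkeeping only, never fitted statistics.

## Problem sizes and numerical choices

Simulation-based checks use N = 761–1000 persons and 10–11 items (50 seeds
for null calibration, 10–20 seeds for power checks), matching the scale of
the survey the pipeline targets.  The brute-force likelihood oracle for
JMLE runs on a 4×3, three-category matrix with persons profiled out on a
0.01-logit grid and three free structural parameters (coarse-to-fine grid).
Probabilities are computed on the log scale with max-subtraction; cell
variances are floored at 1e−300 only to keep 0/0 cells defined; eigenvalues
come from `numpy.linalg.eigvalsh` and are cross-checked against power
iteration to 1e−8.

## Known limitations

- JMLE bias: uncorrected estimates inflate the logit spread at small L;
  the correction flag is off by default for fidelity to common practice.
- Standard errors are diagonal-information approximations (as in the
  Winsteps tradition); no joint covariance is computed.
- The category-outfit criterion conflates mistargeting with scale
  malfunction (see above).
- DIF power at the tested 0.6-logit shift assumes ~500 per group; the
  small-group factors of a real cohort (e.g. 88 vs 673) have less power.
- No longitudinal or unit-level (multilevel) analysis; single cross-section
  only.
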