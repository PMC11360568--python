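# Methods

## Scope and data model

`arealrisk` analyzes disease incidence over a collection of areal units.
The inputs are person-level records (observation window, unit of
residence, sex, birth year, first event date per disease), unit polygons
in a planar projected CRS, a population grid (cell centroid + count), and
unit-level covariates. All coordinates are Euclidean meters; geographic
lat/lon must be projected first, and loaders refuse coordinate ranges
that look geographic unless overridden.

Each person carries a single unit of residence. In cohorts with
migration, the convention is: cases belong to the unit of residence at
event time, censored person-time to the last known residence. The
synthetic generator does not simulate moves, so the distinction is moot
there.

## Incidence rates

Person-time uses the ACT/365.25 day count. For each disease
independently, a person contributes time from entry to the earliest of
first disease-specific event, censoring, or study end, and at most one
case; a person remains at risk for disease B after an event of disease A,
so denominators differ per disease. Rates are reported per 1000
person-years.

Exact Poisson limits for a count Y come from the chi-square link:
lower = χ²₍₂Y,α/2₎/2, upper = χ²₍₂(Y+1),1−α/2₎/2, each divided by
person-time (lower bound 0 when Y = 0). This is equivalent to inverting
Poisson tail sums, which the test suite verifies with an independent
root-finding oracle.

Direct age–sex standardization uses 5-year bands top-coded at 90+ crossed
with sex. The packaged standard is the 2013 European Standard Population
age vector, applied to each sex with half weight and normalized to 1.
Stratum rates are computed from the global (cohort-wide) stratum counts.
Strata present in the standard but empty in the data contribute zero with
a warning; a flag renormalizes the remaining weights instead. The default
(contribute zero) is conservative and keeps the estimator linear in the
data; renormalization is preferable when empty strata reflect data
coverage rather than genuine absence.

### Local empirical Bayes smoothing

Raw rates of small-population units are unstable. Smoothing shrinks each
unit's rate toward its local neighborhood (the unit plus its first-order
rook neighbors):

- m_i: population-weighted mean rate of the neighborhood,
- s²_i: population-weighted variance of neighborhood rates,
- n̄_i: mean population of the neighborhood,
- C_i = s²_i / (s²_i + m_i/n̄_i),
- smoothed_i = m_i + C_i·(raw_i − m_i).

m_i/n̄_i is the Poisson sampling variance of a rate estimated from n̄_i
person-years, so C_i → 1 (no shrinkage) for large populations and C_i → 0
for noisy small-population units. The computation runs on the
per-person-year scale so this variance term is dimensionally coherent,
and results are rescaled to per 1000. Island units (no neighbors) pass
through unsmoothed and are flagged. On connected lattices the
population-weighted global mean rate is preserved to within 1% (verified
in the suite).

## Spatial autocorrelation

Contiguity weights: queen (any shared boundary point) or rook (shared
boundary segment of positive length), built from polygon intersections
with an STRtree. Weights are binary or row-standardized; Moran/LISA
conventionally use row-standardized queen weights, smoothing uses binary
rook weights. Islands are retained with empty neighbor lists and excluded
from statistics that are undefined for them.

Global Moran's I is computed on mean deviations; both the
normality-assumption and randomization analytic variances are reported,
along with a free-permutation pseudo p-value
(1 + #extreme)/(1 + nperm), one-sided in the direction of the observed
statistic (two-sided by flag).

Local Moran's I_i uses the standard mean-deviation form scaled by
m₂ = Σz²/n, so that Σᵢ I_i / n equals the global I under row-standardized
weights and quadrant labels (HH/LL/HL/LH from the signs of z_i and its
spatial lag) are well defined. A literal raw-value form
(I_i = x_i Σ w_ij x_j) is available behind `scale="raw"` for comparison;
it is not the default because quadrants and the global–local identity do
not hold on raw values. Inference is by conditional permutation — z_i
held fixed, neighbor values drawn from the remaining units — with a
shared permutation pool across units for speed, 999 replicates by
default, seeded. Bonferroni-corrected significance (α/n) is reported
alongside the nominal flag.

## Spatial scan statistic

The scan is purely spatial, circular, discrete-Poisson, high-rate only.
Candidate windows: for every unit taken as a center, units join in order
of Euclidean distance between population-weighted centroids; every prefix
whose share of the expectation basis lies within [0.5%, 10%] of the total
forms a window; distance ties join atomically; identical member sets from
different centers count once. The expectation basis is person-time by
default (e_z = C·T_z/T_total); unit population is a supported
alternative. The log-likelihood ratio for a window with observed c and
expected e cases out of C total is c·ln(c/e) + (C−c)·ln((C−c)/(C−e))
when c > e, else 0.

Monte-Carlo inference redistributes the C cases multinomially over units
proportional to the basis; each replicate records the maximum llr over
all windows, and p = (1 + rank)/(1 + nsim) with nsim = 999, so achievable
p-values are k/1000. The primary cluster maximizes llr; secondary
clusters follow in decreasing llr among windows disjoint from everything
already reported, each ranked against the same null-maximum distribution,
and only those with p below α = 0.01 are reported (the primary is always
reported with its p). Setting nsim = 0 skips inference and returns NaN
p-values, useful when only the maximizing window is needed. The reported
radius is the distance from the center to the farthest member centroid.
Cluster relative risk: RR = (o/e)/((O−o)/(O−e)), infinite when o = O.

## Cluster characterization

Features per unit: three Kroll-weighted socioeconomic composites computed
from z-standardized raw variables — education = −0.33·z(no schooling) +
0.66·z(university degree); occupation = −0.61·z(unemployment) +
0.27·z(purchasing power) + 0.50·z(employment); income = −0.41·z(debtor
rate) + 0.52·z(net household income) — plus four conservative-milieu
shares, inhabitants per household, inhabitants per km², dentists per 1000
inhabitants, and the mean raw incidence of the other diseases. The label
is membership in the primary scan cluster.

The 80/20 train/test split is seeded and stratified by label, which under
severe class imbalance guarantees both classes appear in the test set.
ROSE rebalancing draws each synthetic training record by picking a class
with probability ½, a seed record uniformly within the class, and adding
Gaussian noise with per-feature bandwidth
h_j = σ_j·(4/((d+2)·n_class))^(1/(d+4)) (multivariate Silverman rule on
the class subsample); output size equals the input, expected class ratio
1:1.

Five classifiers are fitted (scikit-learn): logistic regression, decision
tree with information-gain (entropy) splits, random forest (500 trees),
RBF-kernel SVM tuned over cost ∈ {0.1, 1, 10, 100} × gamma ∈
{0.01, 0.1, 1} by 5-fold CV on the balanced training set, and a
feed-forward network with one hidden layer of 5 logistic units (width
configurable). Inputs to the scale-sensitive models pass through a
standardizer inside the pipeline. All models expose class-1
probabilities; classification uses the 0.5 threshold. SVM probabilities
come from Platt scaling.

Evaluation on the untouched (imbalanced) test split: confusion counts and
accuracy, specificity, precision, recall, NPV, PPV, F1 from the
0.5-threshold matrix, with zero-denominator ratios reported as NaN;
ROC-AUC by the trapezoidal rule; PR area by step-wise interpolation
(average precision), the convention that avoids optimistic linear
interpolation. Model selection maximizes (accuracy + F1)/2 — the two
headline metrics averaged, since no published composite formula exists —
with ties broken by ROC-AUC, then PR-AUC, then the fixed model order.

Permutation importance: baseline L⁰ = RMSE between predicted probability
and the 0/1 label on the held-out test set (log-loss by flag; RMSE is the
primary loss, matching the stated loss of the methodology this
implements). Each feature column is shuffled 10 times with a seeded
schedule that is independent of the model object, and
vip_diff = mean(L*ʲ − L⁰), sign retained. Importance is computed on the
test set; computing it on training data would reward memorization.

## Synthetic generator

The generator emulates the statistical structure of an areal claims
cohort, not any real geography: a rows×cols lattice of square units
(default 20×20, 1 km cells), log-normal unit populations (median 200,
σ_log 0.35), four grid cells per unit with Dirichlet-jittered population
shares (so population-weighted centroids are informative), persons
entering at study start with exponential censoring (hazard 0.02/year)
over a 6-year window, and disease-specific first-event times exponential
at baseline × RR(unit), with baseline 20 events per 1000 person-years by
default. Covariates are standard normal with a configurable mean shift
inside planted clusters; a separate helper generates feature tables whose
label follows a logistic model for classifier tests.

Planted clusters are discs in centroid space. A disc is centered **on a
unit centroid**: the scan's hypothesis class is "circles around unit
centroids", and a truth set outside that class (e.g. centered on a
lattice corner) caps the achievable membership Jaccard below 1 for any
correct implementation — the test would then measure geometry, not the
method. The default validation disc (radius 2.7 km → 21 of 400 units,
~5% of the population at risk) mirrors the size share of primary clusters
in national ZIP-code analyses.

What passing tests do not show: real geographies are irregular (varying
unit sizes, holes, islands), populations are spatially autocorrelated,
covariates are collinear and non-Gaussian, and disease risk varies by age
and sex within units. The generator's homogeneous-within-unit Poisson
process and independent Gaussian covariates are the simplest structure
that exercises every code path with known ground truth.

## Problem sizes and numerical choices

Validation runs use desk-scale sizes chosen so the whole suite runs in a
few minutes: 400-unit lattices with ~200 persons/unit for cluster
recovery (50 replicates), 144-unit lattices with 199 Monte-Carlo
replicates for null calibration (200 datasets), and 800-row feature
tables for importance recovery (25 replicates). Monte-Carlo and
permutation p-values use the (1 + rank)/(1 + n) convention throughout, so
they never reach zero. All randomness flows through
`numpy.random.default_rng` seeds; the CLI derives independent per-stage
substreams from one master seed by hashing the stage name.

Degenerate inputs: constant attribute vectors make Moran's I undefined
(error); units with zero-population grids error unless an
arithmetic-centroid fallback is enabled; islands pass through smoothing
and are flagged in LISA output; windows excluded by the population bounds
can leave the scan with an empty (warned) result.

## Known limitations

- Circular windows cannot capture irregularly shaped clusters; elongated
  true clusters are reported fragmented or diluted.
- The LLR-maximizing window tends to slightly over- or under-shoot a true
  cluster's boundary in noisy data; membership at the rim is the least
  reliable part of a reported cluster.
- The adopted local-EB shrinkage factor is one member of a family of
  empirical Bayes smoothers; alternatives weight the neighborhood or the
  prior variance differently and will move borderline units differently.
- Analytic Moran z-values are asymptotic; permutation inference is
  preferred and is what the pipeline reports by default.
- Secondary clusters use the strictest non-overlap rule (disjoint from
  all previously reported clusters); looser center-exclusion rules report
  more, partially overlapping, secondaries.
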