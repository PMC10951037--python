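# Methods

## Overview

`cbrel` quantifies how disproportionately a gene is expressed in the
cerebellum relative to other grey-matter regions across development, and
characterises the gene's co-expression context. Its unit of analysis is the
per-specimen, per-gene **cerebellar-relative z-score**

z = (c − mean(x₁…x_k)) / sd(x₁…x_k),

where c is the cerebellar RPKM and x₁…x_k the RPKM of the specimen's other
sampled regions. The z is scale-free within a specimen (multiplying all of a
specimen's values by a positive constant leaves it unchanged), which is what
lets specimens of very different ages and library depths sit on one axis.

## Ages

Donor ages arrive as mixed-unit labels ("12 pcw", "4 mos", "8 yrs") and are
mapped to days post conception with birth at 280 days, one month at 30.44
days and one year at 365.25 days. Any monotone convention preserves rank
structure but Pearson correlations depend mildly on the spacing, so the
constants are module-level attributes rather than literals. Ages are used
linearly; a log-age axis changes the trajectory r and is deliberately not
the default.

## Specimen and gene inclusion

A specimen enters the analysis iff it has a cerebellar sample (whole
cerebellum `CB` or cerebellar cortex `CBC`; the label set is configurable)
and at least 4 other non-cerebellar regions. All non-cerebellar structures
present are used as the comparison set — no blacklist. Absent samples are
missing values, never zeros, because zeros would corrupt the z denominator.

Genes with no recorded expression anywhere (all values 0 or missing) are
removed before any z-based analysis. Ahead of the co-expression sweep two
further filters apply, in a fixed order that the filter report makes
auditable: (1) genes whose mean RPKM over all samples lies strictly below
the 25th-percentile threshold of that distribution (linear-interpolation
percentile, computed after the never-expressed removal); (2) genes with
more than 5 missing z-scores across the included specimens. A z-score is
missing when the cerebellar value is missing, fewer than 2 other regions
are available, or the other-region SD is 0; degenerate cells become missing
(never 0 or ±∞) and are counted in the log.

## Trajectory and centile benchmark

The target gene's z is correlated with age by Pearson's r in two phases:
an early window [0, 280 + 365.25) days (conception through the first
postnatal year) and a late window [280, ∞). First-year infants therefore
belong to both windows by default; a configuration switch starts the late
window at one year instead, and both conventions are reported by the
real-data script, since the choice measurably moves the late-phase r.
P-values are two-sided from the t reference distribution with n − 2 df;
fits require at least 3 usable specimens. Elevation is a strict inequality
(z > 1.96, the two-sided 5% normal point).

The centile benchmark ranks the target's z against all other genes' z in
the same specimen using midrank percentiles (ties counted half), excluding
the target from its own background. Midrank is what makes the
null-uniformity property exact: a target drawn from the background null has
centiles uniform on (0, 100), which the acceptance suite verifies by
Kolmogorov–Smirnov test. Background quantiles (5/25/50/75/95) use numpy's
linear interpolation.

One empirical subtlety: for skewed (e.g. log-normal) regional noise the
z-score of a null gene has a small positive mean of order skewness/k; with
15 regions and mild log-normal noise the bias is below 0.01 and the
property tests bound the mean at |mean| < 0.05 at the cohort's scale.

## Co-expression sets

Each retained gene's z profile is correlated with the target's over
pairwise-complete specimens (listwise deletion would discard most of the
matrix for no gain, given the ≤ 5 missing-z cap); genes with fewer than 3
complete pairs are reported without an r. The vectorised sweep is checked
bit-for-bit against a per-gene scipy loop. Set membership is strict:
r > 0.6 positive, r < −0.6 negative; genes with missing r join neither set.

## Overrepresentation

Annotation terms come from GMT files; no ontology-hierarchy propagation is
performed — the GMT's memberships are the contract. Each term is tested
with a two-sided Fisher exact test on (query vs rest) × (in term vs not),
implemented as the total hypergeometric probability of outcomes no more
likely than the observed one (relative tie tolerance 1e-7, the scipy/R
convention; verified against scipy and against an exact-integer enumeration
oracle for every table with N ≤ 60). The universe is the filtered retained
gene list — the population actually eligible for set membership — not the
whole genome. Fold enrichment (k/n)/(K/N) classifies direction, so over-
and under-represented terms fall out of a single sweep. BH adjustment uses
the statsmodels step-up implementation behind a validating wrapper and is
tested against the direct definition.

## The simulator

`cbrel.synth` generates cohorts in the exact on-disk dialect the reader
consumes. Defaults are the study conditions: 42 donors with log-uniform
ages from 56 to 14,890 days post conception (dense prenatal coverage), 16
regions of which `CBC` is cerebellar (the youngest 3 donors carry a whole
cerebellum `CB` instead), ~20,000 null genes plus 60-gene positive and
negative modules, 3.6% never-expressed genes, 10% region dropout plus 12
"sparse" donors at 70% dropout who usually fail the inclusion rule —
emulating the roughly two-thirds inclusion rate of real multi-region
cohorts.

Generative model: log RPKM = μ_g + b_gd + σ·ε with gene baselines
μ_g ~ N(−1, 2²) (natural log; many near-zero genes), donor effects
b ~ N(0, 0.3²) and region-exchangeable noise σ = 0.25. Planted genes
(target and modules) draw their baselines from N(1, 0.5²) — an
ATM-like, well-expressed level — so the low-expression filter does not
destroy planted structure; their cerebellar samples carry noise SD
τ = 0.05 (`noise_sd`, the trajectory noise knob). Values below a 0.01 RPKM
detection floor are recorded as 0, which both creates realistic all-zero
profiles and produces zero-SD denominators, exercising the missing-z
machinery. RPKM non-negativity is automatic (effects are planted on the
log scale and exponentiated).

Because the z-score cancels μ and b, a cerebellar log-effect
δ(ζ) = (σ² − τ²)/2 + log(1 + ζ·√(e^{σ²} − 1)) gives the cerebellar sample
a population z of exactly ζ — the closed-form core of the calibration.
The target's ζ(age) rises linearly at 2.5 z/year from 8 pcw to one
postnatal year (peak ζ ≈ 4) then declines at 0.065 z/year (ζ ≈ 1.5 at 40
years), reproducing a rise-then-fall of cerebellar-relative expression.
Requests with ζ below −1/√(e^{σ²} − 1) would need a negative cerebellar
mean and raise an infeasibility error.

Module genes are co-expressed with the target in the textbook sense: their
deviation field is a·(target's deviations) + √(1 − a²)·(independent noise
of the same scales), across all regions. An earlier design that scaled
only the deterministic cerebellar effect has a structural correlation
ceiling (~0.8 even at vanishing noise) because each gene's z carries
independent denominator-estimation noise that grows with the planted
effect; sharing the regional deviations — exactly what real co-expressed
genes do — removes that ceiling, so any |r| < 1 is attainable. The loading
a (and likewise the phase-1 slope for a requested age–z correlation) is
solved by Brent's method on a common-random-numbers Monte-Carlo estimate
of the realized population correlation (20,000 draws; the estimate's own
error is ~0.005, well inside the recovery tolerances). The trajectory
calibration does retain a noise ceiling, and unreachable requests raise.

What the simulator does **not** emulate: gene–gene covariance beyond the
planted modules, region identity effects (regions are exchangeable),
age-dependent library composition, and count-level sampling noise. Passing
recovery tests therefore demonstrate that the pipeline's estimators are
calibrated and its filters faithful under a clean generative model — not
that real BrainSpan data satisfies that model.

## Problem sizes and tolerances

The test suite runs everything at scales chosen to keep the whole suite in
a few minutes while leaving Monte-Carlo error well below the asserted
tolerances: trajectory recovery uses 200 replicates of 12-donor cohorts
(tolerance ±0.15 on mean r), module-correlation recovery 200 replicates of
30-donor cohorts (±0.1), membership recovery 40 replicates (≥ 80% recall),
planted-term ranking 200 replicates (≥ 95% top-ranked), and the Fisher
sweep covers all 635,375 tables with N ≤ 60. The acceptance script runs
one default-scale cohort (42 donors, ~20,000 genes) in seconds.

## Known limitations

- Pearson trajectories assume the within-phase relationship is linear in
  age; the package deliberately fits no richer curve family.
- The quartile filter's threshold depends on the percentile interpolation
  rule; linear interpolation is used and logged, and the strict `<`
  comparison means genes exactly at the threshold are kept.
- Whether z-scores should be computed on raw or log-transformed RPKM is
  analysis-dependent; raw is the default, `log_transform=True` is provided
  for robustness studies.
- The enrichment stage detects over/under-representation against the GMT
  as given; results inherit the annotation database's version and
  propagation choices.
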