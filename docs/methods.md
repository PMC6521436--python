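# Methods

## Severity synchronization

Each patient's alignment reference is the maximal Marshall MOF score
(neurological component excluded) over hospital days 0–28. When the
maximum recurs, the *unstable phase* runs from its first to its last
occurrence and may contain days of lower score; the whole stretch is
treated as the acute window. The window span is counted inclusively
(`last − first + 1`), so a single-day maximum has span 1 and the
"unstable phase ≤ 3 days" inclusion rule reads `span ≤ 3`. The
alternative reading (`last − first ≤ 3`) would admit 4-day windows; the
inclusive-span reading was adopted because the unstable phase is defined
as the *period* from the first to the last maximal day.

Offsets before the window are measured from its first day and offsets
after it from its last day. This keeps the analysis interval at seven
day-positions (−3…+3) regardless of window span and is symmetric under
time reversal; measuring both sides from a single anchor would skew
multi-day windows. Days in a trajectory that were not observed are
simply absent — no interpolation or carry-forward is applied, because
any imputation rule would manufacture severity data.

Inclusion filters are evaluated in a fixed order (age 16–50, max MOF
> 1, span ≤ 3, ≥ 1 sample mapping into the window) and only the first
failing criterion is recorded, which makes exclusion-reason counts
unambiguous.

## Expression preparation

Inputs are assumed already background-corrected and normalized on a log
scale (e.g. RMA); raw-array processing is out of scope. Detection
filtering keeps probes with detection p ≤ α (default 0.05) in at least
one sample; the minimum fraction of samples is configurable because the
appropriate stringency depends on the platform. Probes mapping to one
gene are collapsed by the per-sample arithmetic mean. Only autosomal
genes (chr 1–22) enter the differential analysis — X/Y genes differ
between sexes trivially and would swamp the signal of interest.

Scaled expression is the per-gene z-score across *all* samples in the
matrix, z = (x − μ)/σ with σ the sample standard deviation (n − 1
denominator). Zero-variance genes are set to z = 0 with a warning
rather than NaN so that downstream set averages stay defined. Because
the z-map is affine per gene, t-statistics are identical on raw and
scaled values; scaling matters only for the group summaries and the
interaction model, where member genes must be on a common scale.

## Directional permutation enrichment

Gene-level statistics are two-sample pooled-variance Student t-values
oriented female minus male (Welch is available via `equal_var=False`).
Genes with zero pooled variance get t = 0 when the group means agree
and are dropped with a warning otherwise (their t is undefined).

The set statistic is the mean of member t-values. The null permutes
gene labels: each permutation draws a uniform random same-size subset
of the tested universe, implemented as the first k positions of a
random permutation so that one shuffle batch serves all set sizes.
Directional p-values are counted on both tails inclusively with the
small-sample-safe estimator p = (1 + b)/(1 + n_perm), which cannot
return 0 and guarantees p_up + p_dn ≥ 1. Tail counting uses a relative
tolerance of 1e−9 so that null subsets whose mean ties the observed
mean (always including the observed subset itself) count into both
tails regardless of floating-point summation order; without it the
Monte-Carlo estimate is visibly biased low for small universes. When
C(n, k) is at most the exact-mode cap (default 10⁶), all subsets are
enumerated and p = #{null ≥ observed}/total exactly.

Sample permutation (shuffling sex labels) is a stricter null that also
breaks inter-gene correlation; gene permutation was chosen as the
default because the set statistic is built from precomputed gene
t-values, and the synthetic generator draws genes independently, where
both nulls coincide. Set-size bounds after intersection with the
universe default to 5–500.

BH correction is applied within each phase × direction family — the
two directional p-values of a set answer different questions and are
corrected as separate families (`pool_directions=True` merges them).
The per-set-per-phase significance used downstream is
min(adj p_up, adj p_dn) with the sign of the smaller tail.

With n_perm permutations the smallest achievable adjusted p in a family
of m sets is m/(n_perm + 1); detecting effects at adjusted p < 0.025
with m = 100 therefore requires n_perm ≥ 4000. The default is 50,000;
the simulation studies use 1000 (null calibration, where raw p-values
suffice) and 5000 (recovery, the minimum comfortable for the 0.025
threshold at m = 100).

## Signed-LOD clustering

Profiles are LOD = −log10(adjusted p) per phase, negated for sets
down-regulated in females. Selection requires adjusted p strictly below
0.025 in at least one phase, and the same threshold defines
significance for cluster membership — using a looser within-cluster
threshold would blur the single-/multiple-phase distinction. Clusters
are combinatorial (significance pattern × sign), not distance-based:
single-phase vs multiple-phase by the count of significant phases,
female vs male by the common sign of the significant LODs. Multi-phase
sets with conflicting signs are reported as `mixed` — a category that a
sign-pure clustering cannot place and that is surfaced rather than
silently forced.

## Confirmatory statistics

* MOF trend: OLS of score on day-offset with the standard t-test on the
  slope; a constant response returns t = 0, p = 1.
* Wilcoxon rank-sum: exact p for small tie-free samples, mid-rank
  normal approximation (no continuity correction) otherwise, so that
  identical groups give p = 1 exactly.
* Batch check: plain Pearson χ² of independence, no continuity
  correction.
* Interaction model: least squares of the set's average scaled
  expression on MOF, sex (female = 1) and their product; each
  coefficient's F-test equals its squared-t test and is computed that
  way. The model treats expression as the response; the predictors are
  severity and sex.
* Propensity matching: logistic regression of sex on the covariates
  (standardized; a very weak ridge, C = 10⁴, keeps coefficients finite
  when the sexes separate perfectly), then greedy nearest-neighbour 1:1
  matching on the propensity logit without replacement, caliper 0.2 SD
  of the logit by default. Greedy matching on the logit is deterministic
  and dependency-free; a global-optimization matcher (e.g. genetic
  search) could find marginally better balance and the matching routine
  is deliberately pluggable. Covariates are taken per patient and one
  acute-phase sample per patient (the earliest) represents each patient
  in the matched re-analysis. Standardized mean differences before and
  after matching are both computed against the full-cohort pooled SD so
  they are comparable.

## Synthetic cohort

The generator emulates a blunt-trauma cohort: defaults of 129 patients
with 36% females, ages 16–50, expression draws near days 0, 1, 4, 7,
14, 21 and 28, and a four-level batch label. MOF trajectories follow a
piecewise-linear rise from a baseline of 2 to an integer peak (default
6–12) at the planted acute day — peak-day distribution and plateau
lengths are not calibrated to any cohort; the acute day defaults to
days 2–7 and plateaus of 2–3 days occur with probability 0.3. Integer
jitter of ±1 outside the window is clipped strictly below the peak, and
interior plateau days may dip one point, so the first/last maximal days
equal the planted window by construction and window recovery is exact.
Optional violation rates plant age, low-MOF and long-plateau exclusions
for filter testing.

Expression is i.i.d. Gaussian noise (SD 1) plus additive effects:
sex-specific effects add a constant to member genes of samples in the
planted phase for the targeted sex; severity-driven effects add
`slope × (peak MOF − cohort mean peak)` for every patient, which
becomes a spurious sex signal when male peaks are shifted upward. The
expression dimension defaults to 2000 genes — large enough for stable
permutation nulls and BH families, small enough for quick studies.

What the generator does *not* emulate: inter-gene correlation,
heavy-tailed or intensity-dependent noise, missing samples, batch
effects on expression, or overlapping ontology-derived gene sets with
hierarchical redundancy. Passing tests on this generator therefore
demonstrate correctness of the statistical machinery and recoverability
of planted structure, not robustness to those real-data features.

## Simulation studies (`mofsync.experiments`)

The balanced design fixes every patient's peak on day 4 with samples on
days 2–6, giving each phase exactly one sample per patient (30/sex/phase
at the default size). Studies: window/filter recovery on 500 patients
with 10% planted violations of each filter; type-I error of raw p_up at
0.05 under a global null (20 seeds × 100 sets × 5 phases, 1000
permutations); recovery of four 1-SD effects planted in four
phase/direction combinations (20 seeds, 5000 permutations, threshold
0.025); and the confound study (male peaks shifted +2, one MOF-driven
set with slope 0.6, one genuine 1-SD female acute set, 10 seeds). The
reproduction script runs the same studies at 10 seeds each plus one
end-to-end pipeline run (60 patients, 1000 genes, 50 sets, 10,000
permutations).

## Numerical and degenerate-input conventions

* Ties in BH are handled by the step-up construction itself; the
  adjustment is order-invariant.
* `direction` for a set with mean statistic exactly 0 is reported as
  up_in_female; its p-values make it non-significant either way.
* Empty gene sets after universe intersection are skipped with a log
  entry; an empty universe is an error.
* Phases with fewer than two samples of either sex are skipped with a
  warning; an entirely unanalyzable cohort is an error.
* All writers emit `%.10g` floats and sorted JSON keys, making reruns
  with one configuration byte-identical.

## Known limitations

* Gene-permutation nulls understate significance when member genes are
  strongly co-expressed; sample permutation should be preferred for
  real cohorts with correlated modules.
* Greedy matching is order-dependent for tied distances (ties broken by
  identifier) and not globally optimal.
* Patients with multiple well-separated severity peaks are excluded by
  the span filter rather than modelled.
* The unstable-span reading (`span ≤ 3`) is one of two defensible
  interpretations; see above.
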