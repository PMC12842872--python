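# Methods

## Model

`endoscan` tests, for each variant, whether allele dosage differs across
K ordinal endophenotype categories after covariate adjustment. The model
is a reverse regression — genotype as response, phenotype category as
predictor:

    d_i = mu + alpha_{g(i)} + beta' x_i + e_i,     e_i ~ (0, sigma^2)

with d_i the dosage of sample i in [0, 2], g(i) its endophenotype
(1..K, alpha_1 = 0 as reference), and x_i the covariates (age in years,
binary sex code, ten ancestry principal components by default). The
factor is tested with the partial F comparing this model against the one
without the alpha terms:

    F = [(SSE_red − SSE_full) / (K−1)] / [SSE_full / df2],
    df2 = n − K − n_cov.

With a single factor this coincides with Type-II and Type-III tests, so
the distinction is moot. The reverse orientation means the response is a
bounded, discrete (or imputation-smoothed) dosage rather than a Gaussian
variable; the F-test is used as a working approximation, and its level is
verified empirically on null cohorts at the design sizes of interest
(measured type-I rate 0.048 at nominal 0.05 over 10^4 null variants; see
the acceptance script).

Missing dosages are handled per-variant complete-case: samples missing a
variant are dropped from that variant's fit only, keeping the effective n
explicit. Variants monomorphic within the analysis subset are reported as
NA with reason `monomorphic` rather than aborting a scan.

## Post-hoc localization

Significant scans are localized with all K(K−1)/2 pairwise contrasts of
the *covariate-adjusted* (least-squares) group means, evaluated at the
sample-mean covariates. Familywise error is controlled through the
studentized range: contrast (a, b) gets

    q_ab = sqrt(2) |m_a − m_b| / sqrt(MSE * v_ab),
    p_adj = P(Q(K, df2) > q_ab),

where v_ab = (e_a − e_b)' (X'X)^{-1} (e_a − e_b) is the exact
design-based variance factor of the adjusted-mean difference. Without
covariates v_ab = 1/n_a + 1/n_b and q_ab is exactly the Tukey–Kramer
statistic. The distinction matters here: the synthetic cohorts (like the
cohorts they emulate) have a strong age gradient across endophenotypes,
which makes the group dummies partially collinear with age and inflates
the variance of their contrasts. Using the Kramer shortcut on adjusted
means understated the SEs enough to push the measured familywise error to
0.079; with the exact covariance it is 0.048. This matches what emmeans /
multcomp compute for adjusted means, and was verified against emmeans on
a fixture. Raw-mean contrasts (with the Kramer SE) remain available
behind a flag.

The studentized-range tail itself is computed by composite Gauss–Legendre
quadrature of the classical double integral: the inner integral over the
location of the minimum mean (24 panels x 12 nodes on [−9, 9]), the outer
over the scale factor s = sqrt(chi2_df/df) (32 panels x 12 nodes placed
at equiprobable quantiles of s, so small df's heavy tail is resolved).
Node layouts are cached per (k, df); measured absolute error against an
independent implementation is ~1e-10, comfortably inside the 1e-6 target,
and the k = 2 case reduces to the two-sided t tail. Critical values are
obtained by bisection; familywise rates over many variants use the
critical value once rather than 10 tail evaluations per variant.

## One-vs-rest comparison arm

Each endophenotype k is also tested the conventional way:

    logit P(g_i = k) = gamma_0 + gamma_1 d_i + gamma' x_i,

fitted by IRLS (Newton scoring), convergence when the largest coefficient
change drops below 1e-8 (at most 100 iterations). Separation — linear
predictors exceeding 30 in absolute value, or a singular information
matrix — is flagged (`converged = False`, estimates NA); no penalized
fallback is applied, so a flag means "this contrast is not estimable at
this sample size", which is itself informative. Inference on the dosage
coefficient is Wald (one printed OR + p per contrast). Bonferroni
accounting over a family of m contrasts uses the exact threshold
alpha/m; printed values like 0.05/30 = 0.0016 are treated as display
rounding.

The severity-trend test replaces the factor with a continuous severity
score (dosage ~ score + covariates, two-sided t on the slope). The score
defaults to the ordinal group index when per-sample severity scores are
unavailable. An ordinal (proportional-odds) formulation with phenotype as
response would be the other natural reading; the linear reverse
regression was chosen for coherence with the ANCOVA orientation, and the
alternative is deliberately out of scope.

## Quality control

Filter order is fixed and auditable: (1) samples with genotype
missingness > 5% are removed; (2) variants failing call rate (< 95%),
folded MAF (< 5%), or the Hardy–Weinberg exact test (p < 1e-6) on the
remaining samples are removed. The HWE test conditions on allele counts
and sums the probabilities of all heterozygote configurations no more
probable than the observed one (computed in log space, normalized, with a
1e-12 relative guard on the <= comparison). On dosage data, hard calls
for HWE are formed by rounding; dosages more than 0.1 from an integer are
ambiguous imputed calls and are excluded from the HWE count only. QC is
idempotent and every removal is logged with reason, value, and threshold.

## LD clumping

LD is the squared Pearson correlation of dosage vectors over
pairwise-complete samples (a warning fires below 80% completeness).
Clumping is greedy over p-value-sorted hits: the best remaining p becomes
an index variant and removes every remaining same-chromosome variant that
(a) shares a sliding window with it — windows of 250 variants advancing
by 50, in variant counts as specified, with a kilobase mode for
interoperability — and (b) has r² >= 0.5 with it. Ties are broken by
(chrom, pos, id), so output is order-independent. Cross-chromosome r² is
never computed; variants whose r² is undefined are retained
conservatively.

## Synthetic cohorts

The generator emulates the *statistical* structure the scan assumes, not
human genomes. Defaults are the discovery-cohort design: group sizes
(171, 154, 168, 163, 177), group mean ages (6.96, 7.87, 9.04, 9.87,
10.88) with SD 2.0 years — the monotone gradient makes age a genuine
confounder of severity — sex fraction 0.39, ten standard-normal ancestry
PCs. The replication preset uses sizes (207, 205, 204, 207, 207) and its
own age means. Per variant, genotypes are Binomial(2, f) draws, i.e.
hard {0,1,2} dosages in within-group Hardy–Weinberg proportions:

* null variants share one frequency across groups, drawn U(0.05, 0.5)
  (the post-QC common-variant band);
* planted variants have per-group frequencies, e.g. (0.25, 0.25, 0.25,
  0.37, 0.37) for the delta-MAF ≈ 0.12 gradient scale reported for the
  strongest replicated loci;
* confounded variants add per-PC slopes to the frequency (clamped to
  [0.01, 0.99], with a loud warning if clamping exceeds 1% of draws), so
  PC adjustment in the scan demonstrably removes inflation;
* an optional truncated-Gaussian dosage-noise mode mimics imputation
  uncertainty; an optional AR(1)-latent block mode produces correlated
  variants solely to exercise clumping — it is not a model of human LD.

Cohort pairs share generative truth (null frequencies and planted
patterns), with planted effects optionally shrunk toward their mean by an
attenuation factor; attenuation 0 makes the replication cohort null.
Everything is bit-reproducible from the config seed.

What the generator does *not* emulate: realistic LD structure, allele
frequency spectra, relatedness, batch effects, or imputation error
correlated with frequency. Passing calibration and power tests on these
cohorts therefore shows the statistics behave as designed under the
assumed model, not that the pipeline is robust to everything real data
does.

## Benchmark and replication harness

The power benchmark is paired: each replicate's simulated cohort is fed
to all methods (ANCOVA-F; one-vs-rest Bonferroni, which rejects when any
of the K logistic p-values is <= alpha/K — the within-variant contrast
family; trend), and per-replicate rejection indicators are stored so
comparisons can use McNemar-style discordant counts. Power scenarios use
alpha = 1e-4 rather than 5e-8 so 1000-replicate runs give meaningful
rates; the genome-wide threshold is exercised in the calibration suite.
Representative run (seed 1): diffuse two-group shift of delta-MAF 0.10 at
discovery sizes gives ANCOVA power 0.22 vs one-vs-rest-Bonferroni 0.04.
Under a single-group alternative the gap narrows or reverses; the harness
records it without asserting a direction.

The replication harness re-fits the identical ANCOVA on discovery hits in
a second cohort, flags nominal replication (p < 0.05), intersects the
Tukey-significant contrast sets, and reports severity-direction
concordance: a variant is concordant when the sign of (mean MAF in the
two most severe groups minus the two mildest) agrees across cohorts —
one operationalization of "the same upward MAF gradient", chosen because
no formula-level definition exists for it.

## Prediction arm and selection leakage

Features are variants passing a scan p-value screen (default p <= 1e-5)
then clumping. The classifier is K one-vs-rest elastic-net logistic
models (scikit-learn saga; C in {0.03, 0.3, 3}, l1_ratio in {0.2, 0.8}
tuned per class on inner stratified folds for AUC), evaluated by pooled
held-out decision scores over outer stratified folds. Two modes:
*naive* screens once on the full cohort before cross-validating (the
held-out folds have informed feature selection); *nested* re-runs the
entire screen inside every outer training fold. The difference of average
AUCs, naive − nested, is the selection-leakage optimism. On null cohorts
(300 variants, no signal, screen at p <= 0.05 so the screen has something
to overfit to) the optimism is positive in 20/20 runs with mean ≈ +0.09,
while the nested AUC sits at chance (≈ 0.50) — the within-cohort
discrimination that in-sample screening manufactures is entirely
illusory. Gradient-boosted comparators are deliberately omitted: they add
a heavy dependency without a distinct mechanism, and the elastic net
carries the leakage result.

## Numerical and design choices

* Dosage QR factorizations are shared across variants: one decomposition
  of the (common) design matrix serves every variant without missing
  calls, so a 10^4-variant scan takes well under a second.
* Degenerate inputs: empty post-QC cohorts, rank-deficient designs (the
  offending columns are named), emptied groups, constant severity scores,
  single-class outcomes, and all-missing dosage vectors all raise typed,
  informative errors; scan-level failures become NA rows with reasons.
* Allele orientation: group MAF tables fold on the *pooled* frequency so
  group values stay comparable and allele relabeling is a no-op. The
  one-vs-rest OR is reported for the dosage as coded; flipping the coding
  inverts the OR exactly.
* Published six-locus summary tables (discovery/replication F, p,
  post-hoc contrasts, one-vs-rest OR and p) ship in
  `endoscan.datasets` so the multiplicity accounting can run on real
  printed numbers without individual-level data.
* Problem sizes in the test and acceptance runs (10^4 null variants for
  calibration, 1000 paired replicates for power, 20 runs for the leakage
  demonstration, exhaustive HWE enumeration to n = 50) were chosen so the
  Monte-Carlo error of each reported rate is small relative to the
  assertion bands.

## Known limitations

* The F-test on bounded discrete dosages relies on large-group CLT
  behavior; calibration is verified at the shipped design sizes, not for
  tiny groups or MAF near the 5% boundary.
* The trend test is a linear reverse regression, not proportional-odds
  ordinal regression.
* The simulator's independence across variants makes genome-wide
  significance counts trivial; claims about correlated-variant behavior
  are limited to what the AR(1) block mode exercises (clumping).
* One-vs-rest separation at small case counts is flagged, not rescued;
  power comparisons treat non-converged fits as non-rejections, which is
  the operational reality of an analyst discarding them.
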