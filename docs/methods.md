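# Methods

This note records the models implemented in `hiskit`, the conventions and
defaults chosen where the underlying study protocol left them open, what
the synthetic-data generators do and do not emulate, and the package's
known limits. No empirical claim is made here beyond what the test suite
and `scripts/acceptance.py` compute.

## HIS scoring

For a panel of checkpoint genes (default: 34 mouse genes; the eleven
checkpoints central to the analyses — Pdcd1, Cd274, Ctla4, Lag3, Havcr2,
Tigit, Cd200, Pvrig, Nt5e, Tdo2, Cd33 — completed to 34 with commonly
studied co-inhibitory genes; any study should supply its own panel), each
gene's fold change is

FC_g = (mean FPKM in comparison group + c) / (mean FPKM in baseline group + c)

with pseudocount c (default 0.01 FPKM) keeping ratios finite for
zero-expression genes; c = 0 is allowed and raises on a zero baseline
mean. The group mean is the arithmetic mean of FPKM, not a log-space
mean. The tumor state is HIS-high when ≥ `high_min` (10) genes have
FC ≥ `fc_cut` (2.0), HIS-low when ≤ `low_max` (5) do. The dichotomy as
stated has a gap at 6–9 qualifying genes; rather than force a binary
call, the classifier returns INDETERMINATE there. The FC comparison is
inclusive (= 2.0 qualifies).

Directional counts use the reciprocal rule: up = FC ≥ cut,
down = FC ≤ 1/cut, so swapping the groups swaps the counts (at c = 0).
This is a plain fold-change census, deliberately simpler than a
DESeq2-style differential-expression call (dispersion-moderated tests and
FDR control are out of scope); the two will not generally agree on noisy
data. Per-gene standardization for distribution plots uses the sample
(n−1) standard deviation, mapping constant genes to zero rather than NaN.

## Preclinical growth

Caliper volume: V = long · short² · π/6 (mm³), axes validated
long ≥ short. Serpentine allocation sorts animals by baseline volume
(descending; ties broken by a seeded shuffle) and deals them 1..k, k..1,
… so arm sizes differ by ≤ 1 and baseline means are tighter than random
splits (asserted empirically over 1000 trials in the tests).

TGI has no single standard formula, so both common variants are
implemented and the result records which was used:

* endpoint_ratio: TGI% = (1 − V̄_T(d)/V̄_C(d)) · 100
* delta_ratio (default): TGI% = (1 − ΔV̄_T/ΔV̄_C) · 100, deltas from each
  curve's first measured day.

delta_ratio is the default because it discounts baseline size; when arms
start matched the two nearly coincide. Regression below baseline is
clipped at 100 % so both variants share one ≤ 100 % scale; negative
values (treated outgrowing control) are kept. Missing measurement days
raise — no interpolation, so data problems surface instead of being
smoothed over.

A mouse responds when V(final) ≤ V(baseline)·(1 + tol); "stable" needs a
number, and the default tolerance is 0.20 (20 % over baseline still
stable), configurable.

## Cohort prediction

The RECIST-derived responder rule is the operational simplification used
for retrospective response calls: a responder shrinks to ≤ 70 % of
baseline at some visit and shows no progression (> 1.2 × the running
nadir, the conventional progression margin; the factor is configurable)
before week 24. Full RECIST 1.1 lesion bookkeeping is out of scope.

Empirical ROC curves place one operating point per distinct score
(positive = score ≥ threshold); the AUC is the tie-corrected
Mann–Whitney statistic P(s_resp > s_non) + ½P(equal), computed via
midranks. Youden cutoffs maximize J = sens + spec − 1, ties broken toward
the smaller (more sensitive) threshold. For a binary marker,
AUC = (sens + spec)/2 exactly — the identity that makes published
operating points sufficient to recompute AUCs.

### Table reconstruction

A published (sensitivity, specificity) pair plus class sizes determines a
2×2 table up to rounding: responders-positive = round(sens·n_resp),
non-responders-negative = round(spec·n_non), remaining cells by
subtraction; reconstructed tables are validated against independently
published margins (e.g. marker-positive totals), and validation failure
is an error, not a warning.

The 2×2×2 (BTV stratum × TPS indicator × response) table is pinned by
its margins up to a single free cell — the responders among BTV-small,
TPS-positive patients. That cell is resolved by requiring the combined
model's positive region to reproduce the published combined
sensitivity/specificity after rounding to their printed precision. The
positive region is every cell except BTV-large ∧ TPS-negative: under the
published coefficients that cell has the uniquely lowest logit, so this
threshold is the combined model's published operating point. The search
enumerates all integer candidates, errors if none or several match, and
verifies the winner collapses exactly to every supplied margin.

### Logistic regression and DeLong

The grouped-binomial logistic fit is Newton/IRLS, converged when the
score equations Xᵀ(y − n·p) vanish below 1e−8; divergence past |β| = 30
or 100 iterations raises with a pointer to separation. The BTV indicator
codes 1 = below cutoff (BTV-small): this is the only coding consistent
with positive published coefficients, since small tumors respond more
often, and it satisfies the score equations on the reconstructed tables.
Standard errors come from the inverse Fisher information; statsmodels GLM
serves as an independent oracle in the tests, never as the
implementation.

DeLong's test uses the structural-components (placement-value) covariance
estimate with midrank ties, z = ΔAUC/√var, two-sided normal p. When the
placements are identical the variance degenerates; z = 0, p = 1 are
returned flagged rather than raising.

The BTV cutoff 10575.21 shipped in `hiskit.presets` is the reference
cohort's published Youden-optimal threshold; it cannot be recomputed
without the patient images and is a documented constant, not a derived
quantity. Its units follow the source imaging pipeline's volume units.

## Survival

Kaplan–Meier, log-rank, and binary Cox are implemented from their
defining formulas (product-limit; hypergeometric O−E/V summation;
Newton on the partial likelihood) so each can be cross-checked against
lifelines in the suite. Conventions: censored subjects at an event time
remain at risk for it; ties use Breslow by default (simplest correct
choice; ties are rare at month resolution) with Efron optional; the CI is
the 95 % Wald interval exp(β ± 1.96·se) and p is the Wald z-test.
Monotone likelihoods (all events in one group before any in the other)
raise as non-estimable.

## Synthetic data

The generators reproduce the *statistical structure* the analyses assume,
with minimal standard noise models — log-normal for FPKM and volumes
(positive, multiplicative error), exponential for survival (closed-form
hazard ratios):

* Expression: baseline samples are log-normal with median `base_mean`
  (default 20 FPKM) and coefficient of variation `noise_cv` (default
  0.2); comparison medians are `base_mean × planted_fc`. Both groups
  share σ, so planted fold changes hold for medians and means alike, and
  at `noise_cv = 0` they are reproduced exactly. Default 3 samples per
  group mirrors a typical small bulk RNA-seq design.
* Growth: V(t) = v0·e^{rt} with v0 = 50 mm³ (a 4–5 mm tumor),
  r = 0.18/day, 10 mice/arm measured every 3 days to day 21,
  multiplicative noise cv 0.10. Treated responders (probability
  `responder_fraction`) get rate r·(1 − effect); effect > 1 means
  shrinkage.
* Cohorts: explicit mode expands a 2×2×2 table into exactly those
  patients; generative mode samples cells multinomially and responses
  from a logistic model. Continuous TPS is uniform within the positive /
  negative band and BTV log-spread on the correct side of the cutoff —
  every analysis in the package uses only the band indicators, so these
  draws affect nothing measurable.
* Survival: exponential event times with the target group hazard ratio
  (baseline median 20 months) and independent censoring at the stated
  rate.

What passing tests on these data do **not** show: real FPKM is
heavy-tailed across genes and correlated between genes; real tumor growth
decelerates and real responses can be transient; real TPS and BTV are
correlated with each other and with survival beyond the band structure.
The generators make no attempt at any of that, so recovery results here
demonstrate correctness of the estimators, not robustness to real-data
misspecification.

## Problem sizes and numerics

Simulation-based checks run at sizes chosen to make their statistical
assertions sharp while keeping the suite quick: type-I error of DeLong
and log-rank over 1000 null replicates at n = 200; Cox recovery of
HR 2.9 at 500/arm with CI coverage over 500 replicates; logistic
recovery on 5000-patient generative cohorts; the DeLong asymptotic p is
compared with a 10⁴-draw sign-flip permutation oracle at n = 12 within
0.1 (the asymptotic-vs-exact gap at that n). All tolerances for exact
identities are 1e−6 or tighter; all generators and tests are seeded.

## Known limitations

* Only binary-indicator logistic designs are exercised (the package will
  fit any grouped binomial design, but continuous-covariate models are
  untested and out of scope).
* Single-covariate Cox only; no proportionality diagnostics.
* The reconstruction machinery assumes published percentages were
  computed on the stated denominators and rounded half-up to the printed
  precision.
* Mouse-level figures that depend on unpublished raw growth curves
  (specific TGI percentages, arm response rates) are emulated only
  qualitatively by the growth generator; they are not recomputable
  quantities.
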