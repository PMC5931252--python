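# Methods

`ccmirnet` implements an integrated analysis of paired tumor/normal
expression data for colorectal cancer: which cell-cycle genes change between
carcinoma and adjacent normal mucosa, which miRNAs co-vary with those
changes, whether either is prognostic, and which gene–miRNA pairs are
candidates for direct (seed-mediated) regulation. This note describes each
model, its assumptions, the tunable parameters, and the deliberate design
choices; it also states what the synthetic-data generator does and does not
emulate.

## Normalization

**RPMPCG.** A gene's expression in a sample is its read count divided by the
sample's total protein-coding count, times 10^6 ("reads per million
protein-coding genes"). It is linear in counts for fixed totals and
invariant to global rescaling of counts and totals. Samples with a
non-positive total are an error, named in the message.

**miRNA 75th-percentile scaling.** Each sample's total-gene-signal column is
multiplied by `median(q75 of all samples) / q75(sample)`. After scaling,
every sample's 75th percentile equals the pre-scaling median of 75th
percentiles, which makes the operation idempotent up to float tolerance.
Percentiles use linear interpolation between order statistics (numpy's
default, the "type 7" convention) and the median of an even number of
samples is the mean of the two central values; the percentile convention is
stated because different choices change the factors slightly, though
idempotence holds regardless. Scaling is applied to raw (not log) signal.
All-zero miRNA rows are retained — they are removed later by the expression
filter — but an all-zero sample is an error.

## Paired differential expression

Per gene, a negative-binomial regression with log link:

    log E[count_is] = log(pc_total_s) + a_i + b * 1[s is carcinoma]

where `pc_total_s` enters as an exposure offset, `a_i` is a fixed intercept
per subject, and `exp(b)` is the model fold change. With exactly two
samples per subject, the subject intercepts absorb the pairing, so `b` is
effectively the paired within-subject contrast. The NB variance is
`mu + alpha * mu^2` (equivalently size `theta = 1/alpha`).

**Dispersion.** The default estimator chooses `alpha` so that the Pearson
chi-square equals the residual degrees of freedom (solved by Brent's method
over `log10(alpha)` in [-8, 2], floored at 1e-8 to avoid overflow in the
Poisson limit). Plain maximum likelihood is available
(`dispersion="ml"`), but with one intercept per subject the design spends
half the degrees of freedom and ML dispersion suffers the classic
incidental-parameter bias: in a simulated null (30 pairs) ML dispersion was
roughly half the truth and Wald tests ran at a 0.15 type-I error at nominal
0.05. The Pearson moment estimator's df correction restored both the
dispersion (0.049 recovered for a true 0.05) and test calibration (0.033),
which is why it is the default.

**P-values.** Wald tests of `b` against a t reference with `n_obs - n_params`
degrees of freedom. Fold changes are reported two ways: `fc_model = exp(b)`
and the descriptive `fc_ratio` = (mean carcinoma RPMPCG)/(mean normal
RPMPCG); report tables print `fc_ratio` rounded half-even to 2 decimals,
because that ratio-of-means is what the published summary tables print. On
synthetic data with moderate dispersion the two agree within 10%.

**Band filter.** Genes with `fc_ratio > 1.50` or `< 0.67` (strict
inequalities; boundary values fall "within") and BH-adjusted p < 0.05
proceed to the association stage. Benjamini–Hochberg adjustment preserves
input order, is monotone-enforced, and capped at 1. No shrinkage or
moderated dispersion is applied. MSI/MSS subset analyses are the same
procedure on a filtered sample set driven by a metadata column.

## Gene–miRNA association

The regression unit is the differential profile: per subject,
carcinoma minus normal (RPMPCG for genes, scaled signal for miRNAs).
Subjects lacking either tissue are dropped with a logged count. miRNAs are
kept only if detected (signal strictly > 0 after scaling) in strictly more
than 20% of normal samples; ">0" is a declared convention, since no
detection rule accompanies the published filter.

For each candidate pair (by default: every banded gene × every kept miRNA):

    full:  mrna_diff ~ 1 + mirna_diff + age + sex
    null:  mrna_diff ~ 1 + age + sex

The nested F statistic has (1, n-4) degrees of freedom. Age is centered
(affects neither the slope of interest nor F); sex is a single indicator.
Significance comes from a residual bootstrap under the null: resample the
null model's raw residuals i.i.d. with replacement, form
`y* = null fit + resampled residuals`, recompute F, and report
`(1 + #{F* >= F_obs}) / (n_boot + 1)` with `n_boot = 10,000` by default.
Covariates are held fixed across replicates (standard residual bootstrap);
the plus-one correction keeps p-values off zero. The bootstrap is
implemented as a single matrix product per pair using orthonormal design
bases, so 10,000 replicates cost milliseconds. Residuals are not leverage-
adjusted; that alternative was considered and rejected to keep the null
resampling exactly as stated above.

Multiple-testing adjustment is at the gene level: BH within each gene across
its tested miRNAs, independently per gene. This is the literal reading of
adjusting "at the gene level"; a global-BH variant is available behind a
flag for comparability.

## Survival

Endpoint: colorectal-cancer-specific death. Deaths from other causes are
censored at the death time; everyone else is censored at last follow-up.
Each feature's differential profile enters a Cox proportional-hazards model
adjusted for age at diagnosis, sex, and AJCC stage (stages 2–4 as
indicators against stage 1 — no linearity assumption across stages). The
hazard ratio is reported per interquartile range of the profile,
`HR = exp(beta * IQR)`, so effect sizes are comparable across features with
very different expression scales; the Wald CI is scaled the same way. The
IQR uses the same percentile convention as normalization and is computed on
the analysis sample after exclusions. HR per IQR is invariant to affine
transforms of the profile (shifts cancel in the Cox model; scale cancels
through the IQR).

Ties are handled with the Efron approximation, accurate for
monthly-resolution survival times; switching tie conventions shifts the
partial likelihood but not the permutation calibration, since observed and
permuted statistics use the same convention. The Newton–Raphson solver is a
small dedicated implementation whose coefficients, log-likelihood, and
standard errors are asserted against lifelines' `CoxPHFitter` (also Efron)
in the test suite; it exists because the permutation test refits the model
hundreds of thousands of times and benefits from precomputing the risk-set
structure once per outcome (~0.7 ms per refit at n=200).

Significance uses a permutation likelihood-ratio test: the profile column
is shuffled across subjects with outcomes and covariates fixed — the exact
null of no expression–outcome association conditional on covariates — and
`LRT = 2(loglik_full - loglik_null)` is compared to its permutation
distribution with the plus-one correction (`B = 10,000` by default). The
covariates-only null model is unaffected by the permutation, so it is fit
once. BH adjustment runs within feature class (mRNAs together, miRNAs
together).

## Seed matching

Seeds are taken at positions 2–7 (6-mer), 2–8 (7-mer) and 2–9 (8-mer) of
the mature miRNA — the canonical seed family anchored at nucleotide 2. The
anchor is configurable because published seed conventions differ (e.g.
whether an 8-mer includes an opposite-A1); the 2-anchored family is the
field-standard default. A candidate site is the reverse complement of the
seed (U→T) on the sense strand of the 3' UTR. All overlapping occurrences
are reported with 1-based starts; matching is case-insensitive; `N` never
matches and sequences with >10% N are skipped with a warning. A pair
matches if any isoform in any scanned genome build matches ("either build"
rather than "both" — the permissive reading). Under the nested definition,
an 8-mer match at position p implies a 7-mer match at p+1 and a 6-mer at
p+2; this is asserted as a property test. No thermodynamic scoring, wobble
pairing, or conservation filtering is attempted.

A significant association with a seed match is "direct": repression-
consistent when the slope is negative (`direct_negative`), a feedback/
feed-forward candidate when positive (`direct_positive`). No match means
"indirect". A zero slope with a match is classified by the match alone
(`direct_none`).

## Synthetic data

The generator produces every input the pipeline consumes, with known ground
truth. Defaults mirror the study population the pipeline targets: 217
paired subjects; age from a truncated normal on the 30–79 eligibility
window whose *truncated* mean is 64.8 (the latent location is solved
numerically — naively truncating Normal(64.8, 10.1) would shift the mean to
~63.2); 54.4% male; AJCC stage frequencies (27.1, 28.5, 33.6, 10.8)%.

* **Counts:** NB with subject intercepts `a_i ~ Normal(0, 0.5)`, baseline
  expression log-uniform on 5–500 RPMPCG, library sizes log-normal around
  2×10^6, and per-gene planted log fold changes. The residual dispersion
  default is `theta = 20` (`alpha = 0.05`), a typical residual/tagwise value
  for bulk RNA-seq once between-subject variability is carried by the
  subject intercept; it also makes the package's stated recovery tolerance
  (FC 2.0 recovered within [1.9, 2.1] at 500 pairs) a ±2.5σ statement
  rather than a coin flip.
* **Associations:** for a planted (gene, miRNA, beta) edge the miRNA
  differential profile is drawn first and the gene's differential value is
  built as `beta * mirna_diff + age/sex terms + noise` — forward
  construction is what makes the slope recoverable by regressing the gene
  on the miRNA. When a full dataset is written to disk, the same shift is
  applied to the gene's carcinoma NB mean so the association survives the
  count-level round trip. A configurable fraction of miRNAs is generated
  rarely-detected to exercise the >20% inclusion filter.
* **Survival:** exponential event times with log-hazard
  `(planted log-HR / IQR) * profile + covariate effects`, an independent
  other-cause exponential that censors at the death time, and
  administrative censoring at 120 months. The baseline hazard (0.003/month)
  gives overall mortality in the 40–55% range over the horizon, matching
  the target population's 42.6% dead at ≥5 years of follow-up.
* **Sequences:** random mature miRNAs (RNA, 20–24 nt) and UTRs (DNA,
  configurable length); each planted site writes the reverse complement of
  the miRNA's seed into the gene's UTR at a recorded position, with
  disjoint windows when one gene hosts several sites.

Randomness is split into one `SeedSequence`-derived stream per (generator,
feature), so identical configs give bit-identical output and adding genes
never perturbs existing ones.

What the generator does **not** emulate: read-level sequencing (no FASTQ),
probe-level microarray structure, correlated miRNA co-expression (clusters),
UTR base composition or conservation, non-proportional hazards, and
informative censoring. Passing tests therefore demonstrate the estimators'
correctness and calibration under the stated models, not robustness to
those real-data features.

## Problem sizes used in the checks

The repository's own checks run at sizes chosen to make Monte-Carlo noise
small relative to the stated tolerances while staying cheap: null
calibration of the bootstrap-F test uses 500 replicate pairs at n=217
subjects with 2,000 bootstrap draws; the permutation-Cox calibration uses
500 replicates at n=200 with B=1,000; parameter recovery uses 500 pairs
(FC and slope) and 100 simulations at n=2,000 (HR coverage); end-to-end
determinism runs the full pipeline twice at 40 subjects, 8 genes, 6 miRNAs
with 200 bootstrap/permutation draws and compares outputs byte for byte.

## Known limitations

* The fixed-effects NB estimator is a deliberate, reproducible
  approximation to a subject-random-intercept NB model; with two samples
  per subject the two approximate the same paired contrast, but p-values
  are not expected to equal any particular mixed-model implementation's.
* Wald p-values for the NB tissue effect use a t reference; small-sample
  calibration relies on the Pearson dispersion's df correction.
* The bootstrap and permutation p-values have a resolution floor of
  `1/(B+1)`; gene-level BH inherits it.
* The published fold-change table that ships with the package prints fold
  changes computed from unrounded means; on 4 of 71 rows the ratio of the
  *printed* (2-decimal) means lands on the other side of a rounding
  boundary, so exact 2-d.p. reproduction from printed means alone is
  impossible for those rows.
* Seed matching is purely lexical; a match is evidence of binding
  potential, not of regulation.
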