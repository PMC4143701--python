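# Methods

## Trait and analysis model

The trait is the progression of systolic blood pressure,
ΔSBP/Δt = (SBP_last − SBP_first)/(AGE_last − AGE_first), in mm Hg per year.
On imputed (complete) data first/last are exams 0 and 3; in
`no_imputation` mode they are the individual's actually attended exams
(attendance at a wave = SBP and AGE both observed there). Candidate
covariates are the first non-missing values AGE₀*, SBP₀*, MED₀*, SMK₀*
(equal to the exam-0 values once data are imputed), the first-to-last
changes ΔMED and ΔSMK, and SEX. A covariate is retained when its univariate
regression on the trait over completers has p < 0.05; "completer" always
means an individual with every AGE/SBP/MED/SMK value recorded at all four
exams. ΔMED and ΔSMK are last-minus-first values, not divided by Δt — they
are categorical-change indicators, and dividing a 0/1 change by a variable
time span would conflate the two.

The single-marker test is OLS of the trait on the additive minor-allele
dosage plus retained covariates and an intercept, with the two-sided t-test
on the dosage coefficient (the 1-df test; at these sample sizes t and Wald
χ² are numerically indistinguishable). Missing genotypes are handled by
per-SNP listwise deletion. Scan calibration is summarized by the
median-based genomic-control factor λ = median(χ²_obs)/0.4549.

## Allelic interaction statistic

For a SNP pair the additive model M^A = β₀+β₁x₁+β₂x₂ is compared with
M^{A,I} = M^A + β₁₂x₁x₂ through their residual sums of squares. Two
statistics are reported: the SSE ratio t = (SSE^A − SSE^{A,I})/SSE^A, and
the standard nested-model F = (SSE^A − SSE^{A,I})/(SSE^{A,I}/(n−4)). The
ratio t is monotone in F (t = F/(F + n − 4)) but is not itself
F-distributed, so p-values always come from F(1, n−4); using the ratio as
if it were F-distributed would destroy calibration. The interaction models
carry no covariates by default (a flag adds the retained set to both nested
models, leaving the comparison valid). SSE^{A,I} is clamped to SSE^A from
above to absorb ~1e−15 floating-point wobble in the nested identity.

The pair enumerator visits all unordered pairs of SNPs with MAF ≥ 5%
(versus 1% for single markers — products of rare dosages are almost always
zero) in (i < j) index order, keeping a bounded top-K heap plus any pair
below a reporting threshold; memory is governed by K and the chunk size,
not the pair count, and results are invariant to chunking.

## Missingness diagnostic

OLS of SBP₀ on the follow-up presence indicators x₁, x₂, x₃ (x_i = 1 iff
SBP at follow-up i was recorded), optionally with AGE₀, restricted to
individuals with SBP₀ observed — the outcome must exist, and the printed
model has no x₀ term, so β₀ is the intercept. The joint test of
β₁ = β₂ = β₃ = 0 is the standard nested-model F. Baseline age is recovered
from birth year where not recorded, so the adjusted model loses nobody.
Verdict rule: `MAR-suspected` when the unadjusted joint p < 0.05 while the
age-adjusted p ≥ 0.05; otherwise `consistent-with-MCAR`. Both p-values are
always reported — the verdict is a label for the classic pattern, not a
formal MAR test (MAR vs MNAR is not identifiable from the data alone, and
no omnibus MCAR test is attempted). Constant indicators are dropped with a
warning; if all three are constant the joint p is undefined-with-warning.

## Imputation: choices inside the distance

- **Normalization population.** The per-variable per-exam mean and SD are
  computed over *all* individuals with that value observed at that exam,
  and the same constants standardize completers and non-completers:
  distances compare a C against an N, so both must live on one scale. The
  SD is the population form √(E[x²]−μ²) (ddof = 0).
- **Weight signs.** The distance weights are |α_k/β|. Raw correlation
  ratios can be negative and a negative weight on a squared difference is
  not a distance; only the magnitude of co-movement should set a
  variable's influence on the match.
- **SBP weight.** The SBP term has implicit weight 1 and weights are not
  re-normalized; SBP is the anchor variable of the match.
- **ΔSBP in the weights** is SBP₃ − SBP₀ over completers, *not* divided by
  Δt — it feeds the distance weights only and is distinct from the trait.
- **Binary variables** (MED, SMK) are z-scored exactly like continuous
  ones; no special-casing.
- **Ages** are integers (exam year − birth year); average exam calendar
  years are rounded to the nearest integer. Ages are always recoverable
  from birth year, so age terms are never gated and ages are never donated.
- **Ties** in donor distance go to the lexicographically smallest donor ID
  and are counted in the audit table. A `same_sex_donors` flag restricts
  candidates to same-sex completers (off by default — the distance itself
  has no sex term).
- **Zero variance.** A zero-variance baseline predictor zeroes its α with
  a warning; |β| < 1e−8 is a hard error (all weights undefined); a
  zero-SD exam term is silenced with a warning.

Observed values are never overwritten, imputing a complete table is the
identity, and every donated value is traceable through the audit table
(non-completer, donor, distance, filled slots).

## Permutation engine

Each replicate redistributes trait values uniformly over individuals
(covariates stay attached to their rows — permuting the trait alone tests
the SNP-trait association conditional on the covariate structure) and
recomputes the identical statistic: squared t for a marker, nested F for a
pair. p_MC = k/N with k counting *strictly* larger statistics; ties are
counted separately and the positively-biased (k+1)/(N+1) is always
reported alongside, since k/N can legitimately return exactly 0.
Permutations come from a counter-based Philox stream in fixed blocks of
10 000, so extending N reuses earlier replicates; validating several hits
applies the same permutations to every hit.

## Genotype QC

IBS for a pair = Σ(2 − |d_a − d_b|) / (2·m_shared) over SNPs genotyped in
both (allele-wise and SNP-wise denominators give the same ratio). The
relatedness threshold defaults to an absolute IBS of 0.84, with a
mean + k·SD alternative (k default 14); from each flagged pair the member
with the lower call rate is removed (ties: larger ID). The HWE test is the
exact conditional test on genotype counts, summing the probabilities of
all heterozygote counts no likelier than the observed one (computed in log
space via lgamma; the standard choice where low MAF makes χ² misbehave; no
installed library exposes it, so it is implemented here and checked
against full enumeration). Default thresholds, all strict as stated:
sample missing rate > 40% removed; SNP call rate < 99%, HWE p < 1e−6, or
MAF < 1% removed, with reasons recorded in the order
callrate → HWE → MAF (membership of the retained set is order-independent).
MAF and HWE are computed on called genotypes of retained samples.

## Synthetic cohort generator

The generator emulates a four-wave longitudinal SBP study with exam
calendar years 1993/1998/2003/2009. Defaults (all config-exposed):

| parameter | default | meaning |
|---|---|---|
| `age0_range` | (20, 70) | baseline age, uniform integer years |
| `sbp_intercept` | 120 mm Hg | SBP at reference age 40, female, untreated |
| `sbp_age_coef` | 0.5 mm Hg/yr | cross-sectional age effect at baseline |
| `sbp_sex_coef` | 5 mm Hg | male offset |
| `sbp_indiv_sd` | 10 mm Hg | random individual intercept |
| `slope_mean`, `slope_sd` | 0.5, 0.4 mm Hg/yr | latent SBP slope |
| `slope_age_coef` | 0.01 /yr | slope increase per year of baseline age |
| `exam_noise_sd` | 5 mm Hg | per-exam measurement noise |
| `med_intercept`, `med_sbp_coef` | −2.0, 0.04 | medication-uptake logit at/per mm Hg above 140 |
| `med_sbp_effect` | −5 mm Hg | treatment effect while on medication |
| `smk_init`, `smk_persist`, `smk_start` | 0.3, 0.9, 0.02 | smoking chain |
| `dropout_intercept`, `dropout_strength` | 1.5, 0.06 | attendance logit at the predictor center / per unit |
| `maf_range` | (0.05, 0.5) | per-SNP MAF, uniform |

Medication feeds back on SBP across waves (uptake probability rises with
current SBP; being treated lowers the next wave's SBP), so trajectories,
medication and smoking are mutually correlated as in real cohorts. Planted
genetic effects act on the latent slope (per-allele, and per dosage
product for interactions), and phenotypes are re-materialized from stored
latent draws so planting changes nothing else. Dropout masks whole waves
1–3 via a logistic attendance model whose predictor is the wave's age
(`mar_age`), the wave's SBP (`mnar_sbp`) or a constant (`mcar`); default
settings yield roughly 40–55% non-completers, inside the 30–70% band
typical of long follow-ups. Exam 0 is exempt unless configured otherwise,
and an optional per-item MCAR rate produces partial-wave records.
Genotypes are independent biallelic loci (dosage ~ Binomial(2, MAF));
cryptic relatives are injected by near-copying a genotype vector with a
per-entry resampling rate. One integer seed feeds four named RNG streams
(phenotypes, genotypes, dropout, relatives), so toggling one component
never shifts another's draws.

What the generator does **not** emulate: linkage disequilibrium between
loci (independent SNPs only), pedigree structure beyond duplicated-vector
pairs, MNAR mechanisms other than current-SBP dependence, diastolic
pressure or hypertension status, and secular trends in exam timing beyond
integer-year jitter. Passing tests therefore demonstrate correctness and
calibration of the algorithms under a realistic but idealized cohort, not
performance on any particular real data set.

## Problem sizes used in verification

The automated checks run at desk scale, chosen so the full suite completes
in a couple of minutes: calibration on one cohort of n = 300 with 2000
SNPs (single-marker) and 101 SNPs/5050 pairs (interaction); planted-effect
recovery over 100 replicates at n = 300, MAF 0.2; interaction ranking over
50 replicates at n = 400 with 50 SNPs drawn from MAF 0.2–0.4 (a common-
variant band where a dosage-product effect of 2.0 is identifiable);
imputation quality at n = 500 under age-driven dropout tuned near 40%
non-completers; the MAR signature over 200 replicates at n = 1000; and
permutation agreement at N = 10⁵ replicates. The pair enumerator and
permutation stream are designed to scale far beyond these sizes (bounded
memory, extendable replicate streams), but genome-scale runs are out of
scope here.

## Known limitations

- Hot-deck imputation is single imputation: downstream standard errors do
  not reflect imputation uncertainty. A multiple-imputation sensitivity
  analysis is the natural extension and is deliberately not implemented.
- The donor search is O(non-completers × completers); fine for cohort
  sizes in the thousands, not tuned for biobank scale.
- The verdict of the missingness diagnostic is heuristic; MAR vs MNAR is
  not identifiable from observed data.
- `genomic_inflation` warns below 100 p-values; the median estimator is
  noisy on small scans.
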