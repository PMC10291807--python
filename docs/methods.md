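# Methods

This note documents the statistical models behind `coloxwas`, the design
choices that were genuinely open, and what the synthetic-data harness does
and does not establish about real-data behaviour.

## Summary-statistic association (xWAS)

For a feature with cis weight vector `w` over m SNPs, GWAS z-scores `z`,
and reference LD correlation `R`, the association statistic is the
weighted score `z_xWAS = wᵀz / √(wᵀRw)`, standard normal under the null.
`R` is estimated from the reference dosage matrix and ridge-stabilized
before the quadratic form: the diagonal is inflated by 0.01 and the matrix
renormalized to unit diagonal. This guards against non-positive `wᵀRw`
with finite reference panels; the in-sample oracle test (exact regression
of the trait on the imputed feature, n = 5000) shows the statistic agrees
with individual-level regression to well below 1% when the panel is the
GWAS sample and the ridge is off.

Weights are matched to the GWAS and panel by SNP identifier plus allele
pair; allele swaps flip the weight (or z) sign, strand-ambiguous (A/T,
C/G) SNPs are dropped by default, and irreconcilable pairs are dropped and
counted. A result is flagged `degraded` when fewer than half the model's
weights survive; it is reported, not suppressed.

Multiple testing is Bonferroni over *unique* features per modality:
a gene modelled in several tissues contributes several tests but one unit
to the divisor, as does one aptamer. 12,893 unique genes at α = 0.05 give
3.9×10⁻⁶ (two significant figures); 1342 aptamers give 3.7×10⁻⁵.

## cis prediction models

Elastic-net regression (scikit-learn) of the standardized feature on
column-standardized dosages within gene span ± 500 kb; mixing parameter
l1_ratio = 0.5, 5-fold cross-validation over 20 log-spaced penalties, the
penalty with the best out-of-fold prediction correlation wins, and
`training_r2` records that correlation squared. A feature is flagged
untrainable — an empty model excluded from screens — when the best CV
correlation is non-positive or not nominally significant (one-sided
p ≥ 0.01); without the significance gate roughly half of pure-noise
features would acquire spurious weights through a chance-positive CV
correlation. Features are z-standardized only (no rank normalization).
Dosage standardization uses panel-estimated frequencies throughout, for
internal consistency between training and imputation.

## Conditional & joint decomposition

The multiple-regression solution over a selected SNP set is reconstructed
from marginal statistics (b, se, f, N per SNP) and reference LD. With
`s_k = √(2f_k(1−f_k))` the Hardy-Weinberg genotype SD, the cross-product
matrix uses `D_kk = s_k²N_k` on the diagonal and
`B_jk = r_jk·s_j·s_k·min(N_j,N_k)` off it — the pairwise minimum is the
conservative reconciliation of heterogeneous per-SNP sample sizes. Joint
effects solve `B·b_joint = D·b_marginal`; the phenotypic variance is the
region median of `s_k²(N_k·se_k² + b_k²)`, which follows from the
simple-regression identity up to O(1/N).

Forward selection seeds with the smallest marginal p below the entry
threshold (default 5×10⁻⁸), then repeatedly adds the SNP with the
smallest conditional p whose reference r² with every selected SNP is at
most the collinearity cutoff (default 0.1, deliberately strict; both are
flags). After each addition a backward pass drops selected SNPs whose
joint p rises above the threshold — backward elimination is the safer
default even where a pure forward pass is described, and can be disabled.
Ties in minimal p break toward the smaller genomic position for
determinism. Conditional statistics for non-selected SNPs subtract the
LD-projected contribution of the selected joint effects; the conditional
standard error uses the conditioning-set residual variance over `D_tt`
(the usual summary-statistic approximation — the exact-OLS oracle in the
tests bounds its error at the few-percent level within the collinearity
cutoff). Targets in high LD (r² above the cutoff) with the conditioning
set are masked as missing, never reported as zero. A ridge of 0.01 on the
selected-set correlation stabilizes small reference panels; the oracle
tests disable it because panel = GWAS sample there.

## Fine-mapping and colocalization

Per SNP, with V = se² and prior effect variance W, the Wakefield log
approximate Bayes factor is `labf = ½[ln(V/(V+W)) + z²·W/(V+W)]`; under a
single causal variant, PIPs are the softmax of the labfs (computed via
log-sum-exp; stable for spreads far beyond 700). For two traits over the
same m SNPs the five hypothesis masses are

    L0 = 1,  L1 = p1·S1,  L2 = p2·S2,
    L3 = p1·p2·(S1·S2 − C),  L4 = p12·C

with S1, S2 the per-trait labf sums and C the sum of products — the
`S1·S2 − C` term removes same-SNP configurations from the two-distinct-
variants hypothesis; all sums are evaluated in log space, and an
enumeration oracle over all causal configurations verifies the masses to
10⁻¹⁰. Defaults: W = 0.15² (quantitative traits), p1 = p2 = 10⁻⁴,
p12 = 10⁻⁵, reporting threshold PP(H4) ≥ 0.8 — all overridable. Note
that with 100 uniformly null SNPs these priors put PP(H0) ≈ 0.979, not
higher: the single-trait masses p1·m and p2·m are not negligible at
m = 100.

Region analysis windows are the gene span ± 250 kb. Each dataset (QTL and
trait) is decomposed independently; with two or more leads, each lead's
signal uses statistics conditioned on all *other* leads, with the lead
itself re-inserted at its joint estimate — marginal and conditional
statistics are never mixed within one signal. With one or no
genome-wide-significant lead, marginal statistics form a single signal.
Every (QTL signal × trait signal) pair is tested; pairs with fewer than
10 common SNPs are flagged low-coverage rather than dropped.

## Genomic regions

Significant features merge into one region iff their gene spans padded by
500 kb overlap as closed intervals (touching endpoints merge), closed
transitively to a fixpoint; merging is idempotent and permutation-
invariant. Any feature whose padded span intersects chr6:25.5–34 Mb is
absorbed into a single MHC region, even a lone feature — the literal
one-region rule. Region ids are ordinals in genomic order. A region-trait
pair is *supported* when at least one member feature is xWAS-significant
for the trait and at least one of its colocalization pairs reaches the
PP(H4) threshold; supported regions whose best regional GWAS p exceeds
5×10⁻⁸ are flagged as detected through xWAS only. Overlap counts over
all nonempty trait subsets sum to the number of supported regions.

## Cross-feature prioritization

The cis-regulated genetic correlation ρ of two features is the Pearson
correlation of their imputed genetic values in a common reference panel.
Conditioning one feature's xWAS z on another's uses
`z_cond = (z_t − ρ·z_c)/√(1−ρ²)`, exact for jointly normal scores with
correlation ρ; under the null it remains standard normal (verified by
simulation). At |ρ| ≥ 0.9 the two instruments are statistically the same
association and a collinear/shared verdict replaces the number — the
bound is configurable since no canonical value exists. Multi-feature
conditioning is iterated pairwise, an approximation documented as such.
Verdicts reuse the modality's Bonferroni threshold: `independent` when
both directions survive conditioning, `explained` when exactly one does,
`shared_attenuated` when neither does.

## Synthetic-data generator

The generator reproduces the statistical structure the chain depends on,
at desk scale:

* **LD**: one latent Gaussian AR(1) process per haplotype (coefficient
  `ld_decay`, default 0.7) thresholded at each SNP's MAF quantile; two
  haplotypes sum to a dosage. Dichotomization attenuates the dosage-scale
  correlation below the latent coefficient; the bivariate-normal orthant
  formula used in the tests predicts the realized r.
* **Features**: 1–3 causal SNPs with effects rescaled so the genetic
  variance share equals `h2_cis` (default 0.2) exactly in-sample; noise
  tops the variance up to ~1.
* **GWAS**: z drawn directly from the asymptotic law `N(√N·R·b, R)` —
  the exact target distribution of marginal z-scores under LD, without
  simulating individual phenotypes. beta, se, freq, N are back-filled
  consistently on the standardized-trait scale.
* **Scenarios**: `null`, `single_shared`, `distinct_in_ld` (causal pair
  rejection-sampled into r² 0.2–0.5), `two_signals` (pair at r² < 0.05),
  and `coregulated_pair` (one shared plus one private causal SNP per
  feature, shared variance fraction |ρ_target|, sign from ρ_target).
  Each bundle carries a TruthRecord oracle.

Standing study conditions (chosen once as field-realistic defaults, since
no canonical effect-size spectrum exists for the traits): 100 SNPs per
region at 2 kb spacing, MAF ∈ (0.05, 0.5), reference and QTL panels of
2000 individuals, GWAS effective N = 10⁵, mediation effect 0.15 SD per SD
of feature. What the generator does *not* emulate — coalescent LD
structure, allele-frequency spectra, polygenic background, sample overlap
between GWAS and QTL studies, imputation error — bounds what passing
tests show: they validate the inference machinery under its own
assumptions, not robustness to real-data misspecification.

## Problem sizes and numerical choices

The test-suite and acceptance-script simulations use 100 seeded
replicates for scenario-recovery rates, n = 5000 individuals for the
exact-regression oracles, 2000 features/draws for type-I checks, and
n_ref = 2000 for correlation recovery — sizes at which the binomial or
sampling error is comfortably inside each asserted margin. All randomness
flows through explicit seeds (`numpy.random.default_rng` /
`SeedSequence`); reruns are bit-identical. Degenerate inputs are rejected
eagerly (empty SNP sets, constant dosage columns, se ≤ 0, malformed
spans), monomorphic simulated SNPs are resampled marginally so panels
never contain constant columns, and the H3 mass is clamped to zero with a
log record if rounding drives `S1·S2 − C` negative.

## Known limitations

Single-causal-variant colocalization only (no SuSiE-style multi-causal
regression); two traits per colocalization; pairwise (not joint)
cross-feature conditioning; no sex chromosomes; the per-SNP sample-size
reconciliation `min(N_j, N_k)` is conservative and untested against
designs with extreme N heterogeneity.
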