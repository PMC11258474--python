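# Methods

## Generative model for the synthetic cohort

Genotypes are drawn per LD block from a latent multivariate normal with
AR-1 correlation ρ between adjacent SNPs, thresholded at Hardy–Weinberg
quantiles of each SNP's minor-allele frequency into dosages 0/1/2. The
thresholding attenuates correlation, so a latent ρ of 0.9 yields dosage
r² ≈ 0.6–0.7 at common MAF; ρ is therefore a tuning knob for the clumping
and HEIDI tests rather than a literal haplotype model. Default study
layout: six gene-sized blocks (one per drug-target gene, ρ = 0.55, 4–6
SNPs each) plus ten independent background SNPs; per-allele BP effects are
drawn once from ±U(0.4, 1.2) mmHg, the range of genome-wide-significant BP
loci.

True systolic BP is

    SBP = 125 + Σᵢ βᵢgᵢ + 0.45·(age−55) + 4·male + 0.5·(BMI−27)
          + 0.1·PC1 + 5·U + ε,   ε ~ N(0, 16²) mmHg,

with U ~ N(0,1) an unmeasured confounder; DBP analogously (scaled 0.55,
noise 9 mmHg, floored at SBP − 10 so pulse pressure stays positive).
Individuals with true SBP > 160 mmHg start antihypertensive medication
with probability 0.7; medication lowers *observed* SBP/DBP by exactly
15/10 mmHg, so the standard +15/+10 correction inverts the mechanism and
the corrected BP equals true BP up to within-visit reading noise
(sd 4 mmHg per reading; 3% of individuals have a single reading).

Deficit item j is present iff

    aⱼ + θ·(SBP − 140) + 0.3·U + eᵢⱼ > 0,   eᵢⱼ ~ N(0, 1),

with θ = 0.02 liability SD per mmHg by default. Intercepts aⱼ are
parameterised so that item prevalences at the reference SBP run from 1% to
22% across the 49 items, placing the cohort FI mode below the 0.12 cutoff
with a small frail tail, as in population FI distributions. Writing the
liability in terms of SBP − 140 rather than raw SBP is an intercept
reparameterisation only; it keeps aⱼ interpretable as baseline
prevalences.

A second outcome mode draws the frailty category directly from a
multinomial logit in true SBP with known coefficients. It exists for
estimator validation: the deficit-liability mechanism is the realistic
default, but its implied category-level RRR is not an analytic function of
θ, so the validation studies use the mode whose ground truth is exact.

What the generator deliberately omits: population structure and
relatedness, imputation uncertainty, haplotype-level LD, item-specific
deficit semantics, fractional deficit codings, X-chromosome SNPs.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to those real-data
complications.

## Discovery GWAS and LD reference

Instrument weights come from per-SNP marginal regressions of
medication-corrected BP in an independently simulated discovery cohort
(n = 150,000), written in `.ma`-style columns; LD for clumping is the
dosage correlation in an independent 10,000-person panel. Using separate
samples for weights, LD, and the analysis cohort mirrors the
three-data-source structure of the real design and avoids winner's-curse
leakage into the one-sample MR.

## Frailty index

FI = (sum of non-missing deficit values) / (number answered). Categories:
FI < 0.12 non-frail, 0.12 ≤ FI ≤ 0.24 pre-frail (both printed boundary
values assigned to the closed middle band), FI > 0.24 frail. Persons with
every item missing carry an undefined FI and are excluded downstream. The
modified FI drops a configurable cardiometabolic item set (default: the
first eight synthetic items, a labelled stand-in — the real eight-item
list is not public). The missingness sensitivity rule excludes persons
with ≥ 10 missing items.

## Instruments and risk scores

Candidates per drug class: SNPs within ±100 kb of any of the class's
target genes with association p < 5×10⁻⁸ (strict) and MAF > 1% (strict).
Greedy clumping sorts by p (ties: position, then id) and accepts a SNP iff
r² < 0.4 against every accepted SNP — verified against exhaustive subset
enumeration on 12-SNP windows; 0.1 and 0.01 are the sensitivity
thresholds, 0.001 the genome-wide setting. Weights are oriented so every
effect allele raises BP; the weighted score

    GRS = (β₁·SNP₁ + … + βₙ·SNPₙ) × n / Σᵢβᵢ

is invariant to rescaling all β by a constant and to allele-label flips,
and collapses to the dosage for a single SNP. Missing dosages are
mean-imputed per SNP. Instrument strength is reported as r² and
F = (r²/1)/((1−r²)/(n−2)) from the simple BP-on-GRS regression. A drug
class with zero surviving instruments (ARB by construction) flows through
the pipeline as an explicit "no proxy available" row.

## Two-stage predictor substitution

Stage 1: OLS of corrected BP on GRS + covariates (categorical covariates
one-hot with first-level reference; incomplete rows dropped and counted;
rank deficiency raises an error naming the collinear columns). Stage 2:
maximum-likelihood multinomial logit (Newton, tolerance 1e-10, ≤ 100
iterations, via statsmodels) of the three-level frailty category on the
stage-1 fitted BP plus the same covariates, non-frail as reference.
Per-contrast coefficients are log-RRRs per mmHg, rescaled as
RRR = exp(−unit·coef) per 10-mmHg (SBP) or 5-mmHg (DBP) decrease with
Wald 95% CIs; p < 0.025 is significant (two exposures), 0.025–0.05
suggestive. Age-restricted (≥ 60), modified-FI, missingness-restricted
and unweighted-GRS variants are switches on the same pipeline.

Known limitations, by design: Wald standard errors ignore first-stage
estimation uncertainty (second-order with F in the hundreds), and fitted
values from a linear first stage are carried into a non-linear second
stage — the standard predictor-substitution compromise.

### What "true RRR" means in the validation studies

A logit-scale RRR is non-collapsible: the estimator never conditions on
the BP variation the instrument does not carry (residual BP noise, the
confounder), so it targets the *marginal* RRR — the quantity a randomized
BP intervention would produce — which is attenuated relative to the
subject-specific coefficient by a few percent at these parameter values.
The validation studies therefore solve the generator's conditional
coefficient from the target marginal RRR by Gauss–Hermite integration of
the generative model (`studies.conditional_coef_for_marginal_rrr`); the
integration uses only the data-generating parameters, never the
estimator. Recovery is summarised as the geometric mean of replicate RRRs
(the mean on the log scale), the natural scale for ratio estimates.
Validation cohorts use n = 20,000, sixteen 1.2-mmHg instruments
(first-stage F in the hundreds), a confounder shifting BP by 5 mmHg/SD
and both category log-odds by 0.3/SD, and a reduced covariate set
(age, sex); the full 40+-column covariate design is exercised by the
pipeline and its tests.

## SMR and HEIDI

For each gene, the top cis-eQTL (lowest p within ±1 Mb, requiring
p < 5×10⁻⁸; ties broken by |z| then position) gives
b_xy = b_zy/b_zx with T_SMR = z_zx²z_zy²/(z_zx²+z_zy²) referred to χ²(1)
and se_xy = |b_xy|/√T_SMR. HEIDI uses cis SNPs with p_eQTL ≤ 1.6×10⁻³ and
r² ≤ 0.9 to the top SNP (optionally also r² above a floor, off by
default), capped at the 20 smallest-p SNPs and requiring at least 3; the
differences dᵢ = b_xy(i) − b_xy(top) get a first-order delta-method
covariance with zero cross-study terms (independent eQTL and GWAS
samples), and T_HEIDI = Σ z_d,ᵢ² is referred to its null — a weighted sum
of correlated χ²(1) variables — by seeded Monte Carlo over the eigenvalue
mixture (10⁵ draws by default; a Satterthwaite moment-matched χ² is
computed alongside as a cross-check and the two agree within a factor of
two for p in [0.01, 0.5]). Fewer than three difference SNPs or a singular
difference covariance yields a missing HEIDI p rather than a number.
Significance over 15 genes uses 0.05/15 rounded to one significant digit
(0.003); HEIDI p < 0.01 flags heterogeneity.

The summary-scenario generator propagates causal effects through an AR-1
LD matrix (marginal effect = r to the causal variant × causal effect) and
adds correlated sampling noise per study. Defaults: 25 SNPs, ρ = 0.9, top
eQTL |z| ≈ 14 (GTEx-scale tissue panel), outcome effects of magnitude
0.02 FI units with se 5×10⁻³ — an outcome |z| ≈ 4, the scale of published
FI SMR signals. The HEIDI delta approximation is sensitive to this
choice: when the outcome z is pushed an order of magnitude higher, the
eQTL-denominator noise dominates the difference terms and the test
over-rejects (≈2.5% at the 1% level) even with exact covariances — a
finite-z property of the first-order expansion worth remembering when
interpreting HEIDI on very strong outcome signals. The linkage scenario
places a second causal variant at r ≈ 0.6 affecting the outcome only.

## Numerical choices

Seeds: every generator and study derives child seeds from a single root
via `numpy.random.SeedSequence`; identical configuration and seed give
byte-identical written reports. Monte-Carlo tail probabilities use an
add-one correction so p > 0. PSD repairs clip eigenvalues at zero and
restore unit diagonals. Percentages print at one decimal with half-up
rounding. Ties in clumping and eQTL selection are broken
deterministically (position, then id). Problem sizes in tests and the
acceptance script — 1000/400 replicates at n = 20,000 for the MR studies,
2000 gene windows for the SMR/HEIDI calibrations, 100 twelve-SNP windows
for the clumping oracle — were chosen so Monte-Carlo error is small
against each check's tolerance.
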