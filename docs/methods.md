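# Methods

`lipidmr` implements the summary-statistic Mendelian-randomisation (MR)
workflow used to ask which of several highly correlated lipoprotein traits
carries a direct causal effect on coronary heart disease, together with a
synthetic-study generator that reproduces the statistical structure of that
problem so every stage can be tested end to end without external data.

## The estimation problem

For SNP *j* let β̂_Xjk be its estimated association with exposure *k* (per
allele, on the 1-SD scale of the inverse-rank-normalised trait) and β̂_Yj its
log-odds association with the binary outcome, estimated in a non-overlapping
sample. Under the instrumental-variable assumptions the Wald ratio
β̂_Yj/β̂_Xj estimates the causal log-odds per 1-SD exposure, and the
estimators combine ratios across independent SNPs:

- **IVW**: weighted regression of β̂_Y on β̂_X through the origin with
  weights 1/se(β̂_Y)²; algebraically the inverse-variance-weighted mean of
  the Wald ratios with weights β̂_X²/se².
- **MR-Egger**: the same regression with a free intercept after orienting
  each SNP so β̂_X ≥ 0; the intercept estimates average directional
  pleiotropy (requires InSIDE).
- **Weighted median**: interpolated 50% point of the ratio distribution
  under weights β̂_X²/se²; consistent when ≥50% of the weight is valid.
- **Weighted mode**: argmax of a normal-kernel weighted density over
  ratios, bandwidth `0.9·min(sd, IQR/1.349)·J^(−1/5)` (modified Silverman,
  tunable by φ), evaluated on a fixed 512-point grid spanning the ratio
  range ±3 bandwidths.
- **Multivariable IVW / MR-Egger**: weighted multiple regression of β̂_Y on
  the J×K exposure-beta matrix (no intercept / free intercept after row
  orientation); coefficient *k* is the *direct* effect of exposure *k*
  conditional on the others — the quantity that separates apolipoprotein B
  from LDL cholesterol.

Standard errors for the regression estimators are multiplicative
random-effects: the classical SE times max(1, σ̂), σ̂² the weighted residual
mean square. The clip means SEs are never anti-conservative; the cost is
mild over-coverage when the residual dispersion is genuinely below one.
P-values use the standard normal. Weighted median and mode use a seeded
parametric bootstrap (β̂ resampled from N(β̂, se), 1,000 draws by default);
this bootstrap treats the estimates as truth and measurably over-states the
SE of these order-statistic estimators (~15–25% in our diagnostics), so
their intervals are conservative — see Calibration below.

Instrument strength: the mean F per exposure is the summary approximation
`mean((β̂_X/se)²)`; the conditional F for exposure *k* in a K-exposure model
is the Sanderson–Windmeijer form Q_k/(L−K+1), where Q_k is the weighted
residual sum of squares of β̂_Xk regressed (weights se_Xk⁻², no intercept)
on the other exposures' betas. Conditional F far below the univariable mean
F signals that instruments barely separate an exposure from its correlates
— exactly the situation with apoB and LDL cholesterol.

## Instrument selection and harmonisation

SNPs pass at P < 5×10⁻⁸ (strict inequality), then greedy LD clumping at
r² < 0.001: sort by p (log-scale, so underflowing p-values still rank;
ties by larger |β| then SNP id), keep the best remaining SNP, discard
same-chromosome SNPs correlated at or above the threshold. No distance
window is used — affordable at desk scale and strictly more conservative.
Novelty annotation flags an index SNP as novel iff every catalogue SNP on
the same chromosome within 1 Mb has r² < 0.001 with it; we read the
"within 1 Mb and r² < 0.001" rule as independence from every reported SNP
in the window (the union reading would declare almost everything novel).

Harmonisation aligns each SNP's outcome record to the exposure effect
allele: direct match, effect/other swap (negate β, complement frequency),
strand complement, and palindromic SNPs oriented by allele frequency only
when both frequencies are outside [0.42, 0.58] (window configurable; the
source study does not state its convention, so the conservative default is
ours). SNPs missing from the outcome set are replaced by the best LD proxy
with r² > 0.8 (strict), oriented by the *signed* reference-panel r — with
only unsigned r² available, proxies are disabled rather than risk silent
sign errors. Exposure rows with allele labels identical to the reference
are taken as aligned (one GWAS source), bypassing the palindromic rule that
would otherwise discard mid-frequency A/T and C/G SNPs from the
multivariable model.

## The synthetic study generator

The generator emulates the study design: five standardized lipid-like
exposures (apoB, LDL, TG, HDL, apoA-I analogues), a binary outcome caused
directly only by the apoB-like trait (θ = 0.65 log-odds/SD) and weakly by
the TG-like trait (0.10), and two samples sharing a SNP map but no
individuals.

**Genotypes** are independent biallelic SNPs, dosage ~ Binomial(2, f),
f ~ U(0.05, 0.95); optional LD blocks copy a template SNP and resample a
configurable fraction of genotypes (pairwise r ≈ 1 − fraction), giving
tunable LD for clump/proxy tests.

**Exposures** follow X = G_std·A + U·λ + C·Γ + E with a latent confounder
U (loadings 0.2/0.2/0.2/−0.15/−0.15, outcome loading 0.25), measured
covariates (age, sex, genotyping chip, fasting time — the fasting loading
is −0.12 on the TG-like trait only, emulating non-fasted triglycerides)
and multivariate normal noise E. Two calibration devices make the target
correlation matrix exact in expectation rather than approximate:

1. effects are per 1-SD dosage and the effect matrix is *whitened* —
   A = W(WᵀW)^{−1/2}·√h²·Lᵀ with LLᵀ the target genetic correlation — so
   AᵀA = h²·R holds exactly for the drawn matrix, not just on average;
2. the environmental covariance is solved as (1−h²)R − λλᵀ − ΣΓΓᵀ
   (checked positive definite at preset construction), so genetic and
   non-genetic parts sum to R.

A single rank-1 shared factor cannot produce this correlation matrix
(0.96, −0.49 and 0.92 cells simultaneously), which is why the generator
uses a full environmental covariance; a rank-1 factor hook remains for
simple designs. The two pinned cells (corr(LDL-like, apoB-like) = 0.96,
corr(HDL-like, TG-like) = −0.49) reproduce the reported phenotypic
correlations; the remaining cells are plausible lipid-panel values chosen
once.

**Genetic architecture.** The joint SNP heritability is 0.35 concentrated
in 15 causal loci (of 300 panel SNPs). Sparsity is deliberate: lipid GWAS
instruments are large-effect loci, and the diagnostic that matters for
multivariable MR — the conditional F — lands near 35 for the apoB-like
trait under this preset, the same regime as the real instruments. A dense
architecture at desk-scale sample sizes would put every instrument at the
significance threshold, where winner's curse and errors-in-variables under
corr 0.96 distort the multivariable estimates qualitatively.

**Outcome**: logit P(case) = α + Xθ + G_c·π + 0.25·U, with α solved by
Brent's method so the case fraction matches the configured prevalence
(default 0.33, the case fraction of the outcome consortium data) within
±0.01. Pleiotropy π is zero, balanced (mean 0), directional (mean ≠ 0), or
InSIDE-violating (correlated with instrument strength). The logistic
choice matches the odds-ratio scale of the application; the alternative
liability-threshold model would estimate a different quantity.

**Non-collapsibility (important).** Because the outcome model is
logistic, per-SNP outcome associations are *marginal* log-odds and are
attenuated relative to the conditional generating effects by roughly
1/√(1 + 0.346·var(η)) where η is the non-SNP linear predictor — ≈ 0.916
under the default preset. Summary-statistic MR therefore targets ≈ 0.92·θ,
exactly as real two-sample MR with a binary outcome estimates a
marginally-scaled effect. The recovery harness reports this factor; the
acceptance check against the raw θ fails for the apoB-like component by
about this factor while matching the attenuation-adjusted target. This is
a property of the estimand, not an implementation error, and no correction
is applied because none is applied in practice.

**Two-sample structure**: a pooled cohort is split so samples overlap in
exactly `round(overlap_fraction·n₂)` individuals (default 0, i.e.
disjoint); exposure GWAS (OLS on the inverse-rank-normalised trait,
adjusted for age, sex and chip) uses sample 1 only, outcome GWAS
(per-SNP logistic ML, adjusted for age and sex) sample 2 only. The LD
reference is the full exposure-sample panel: a small reference (e.g.
hundreds of individuals) would make the empirical r² noise floor (~1/n)
exceed the 0.001 clumping threshold and spuriously merge independent SNPs.

What the generator does **not** emulate: realistic human LD maps,
population structure and relatedness (hence plain OLS/logistic instead of
mixed models), imputation uncertainty (INFO is fixed at 1), multi-allelic
variants, and the shared-causal-locus structure is total (all causal SNPs
affect all traits through the correlation structure) rather than partial.
Passing tests therefore certify the statistical machinery, not robustness
to those real-data features.

## Numerical choices

- Per-SNP GWAS is vectorised: linear via Frisch–Waugh residualisation on an
  SVD basis of the covariate space (redundant covariate columns are
  harmless); logistic via batched Newton–Raphson (tolerance 1e-9 on the
  step, 40 iterations max), with separated/singular fits dropped and
  logged. Agreement with statsmodels OLS/Logit is asserted in tests.
- Monomorphic SNPs get β = 0, se = +∞, p = 1: never significant, never
  fatal.
- P-values are carried as log10 alongside, so genome-wide associations that
  underflow doubles still sort, filter and tie-break deterministically.
- The Blom offset (3/8) is used for rank normalisation with average ranks
  for ties; the transform's offset is a convention, not prescribed by the
  source study.
- The mode estimator's bandwidth falls back to the SD when the IQR is zero;
  identical ratios short-circuit to that ratio with SE 0.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` children; identical configuration implies
  byte-identical outputs, which the test suite asserts at file level.

## Calibration and known limitations

At 500 null replicates (θ = 0, strong instruments, 6,000 per sample), IVW
(0.966) and MR-Egger (0.960) 95% CIs cover zero at rates inside the exact
binomial 99% band, as does the Egger intercept under balanced pleiotropy.
The weighted median sits near the band's upper edge (0.96–0.976 across
seeds) and the weighted mode over-covers (≈0.98): their parametric
bootstrap resamples around the estimated betas and demonstrably inflates
the SE of these order-statistic estimators by ~15–25% (true sampling SD
0.073 vs mean bootstrap SE 0.085 for the median on a fixed design), so the
intervals are conservative. We keep the textbook bootstrap definition
rather than re-tune it; users needing tighter median/mode intervals should
increase instrument counts or use the regression-based estimators.

Monte-Carlo problem sizes — 100 recovery replicates at n = 20,000 and
m = 300; 500 calibration replicates at n = 6,000 and m = 60; bootstrap 200
inside harnesses — are the package's chosen balance between Monte-Carlo
error and turnaround time.

The conditional F uses the summary-data Q formulation given above; the
implementation accepts a user-supplied alternative by operating on the
`HarmonisedData` matrices directly if a different variant is preferred.
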