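# Methods

## The question and the design

Whether the aggregate (genome-wide) genetic influences on a quantitative
trait are stable across adult ages can be asked without individual-level
data: run separate GWAS on non-overlapping age tranches, estimate the
genetic covariance matrix across tranches from the summary statistics, and
test which longitudinal covariance structure fits. The design is
*pseudo-longitudinal* — independent cross-sections treated as repeated
measures — and therefore assumes no birth-cohort genetic heterogeneity;
nothing in the machinery requires the tranches to share subjects.

The default study conditions emulate six five-year BMI tranches from a
single population cohort: sample sizes 34,001 / 45,294 / 53,602 / 64,891 /
89,824 / 71,178, SNP heritabilities 0.22–0.29, and pairwise genetic
correlations around 0.94–0.95.

## Simulator

For SNP j with LD score l_j and panel size M, the vector of z-scores
across the k tranches is drawn

    z_j ~ MVN(0, Sigma_j),    Sigma_j[t,u] = C[t,u] + sqrt(N_t N_u) S[t,u] l_j / M,

independently across SNPs. C holds the LDSC intercepts: 1 on the diagonal
(no confounding) and 0 off it (no sample overlap). This *is* the moment
model LD-score regression estimates, so the estimand is exact by
construction and every recovery study has a known truth.

What the simulator deliberately does not emulate: realized inter-SNP LD
correlation (SNPs are independent given their LD scores), population
stratification, sample overlap (supported through C but off by default),
binary traits, and realistic allele-frequency/LD architecture. Because
neighbouring SNPs are independent, contiguous jackknife blocks are
independent too, which makes the block-jackknife SEs *well* calibrated
here and *anti-conservative relative to real data*, where residual
between-block LD inflates sampling noise. Passing calibration tests
therefore validates the estimator's internal logic, not its real-data SE
accuracy. LD scores are drawn 1 + Gamma(shape 2, scale 10) (mean 21);
positions sit on one synthetic chromosome at 1 kb spacing; a configurable
fraction of SNPs gets strand-ambiguous alleles (5%) and, in tranches 2..k,
swapped A1/A2 with negated z (5%), so the harmonization code path is
exercised end to end. Allele frequencies are Uniform(0.005, 0.995) and
INFO is 1 − Beta(1, 40), so the MAF and INFO filters each remove a small,
predictable share.

### Generative structures

*Common factor*: S = λλ′ψ + diag(θ) with λ₁ = 1 fixed, so ψ is directly
the common-factor SNP heritability. Defaults: ψ = 0.24, θ₁ = 0.01, and for
t ≥ 2 the factor carries 94% of the tranche heritability
(λ_t = √(0.94 h²_t / ψ), θ_t = 0.06 h²_t). Note the first tranche's total
heritability is then 0.25: with λ₁ = 1 a factor variance of 0.24 cannot sit
under a tranche heritability of 0.23 without a negative residual, so the
first tranche's heritability, not the factor variance, was adjusted.

*Simplex*: latent chain η_t = β_t η_{t−1} + ζ_t with variances
v₁ = ζ₁, v_t = β_t² v_{t−1} + ζ_t and cov(t, t+s) = v_t ∏ β; defaults
β = 0.95 per interval, ζ₁ = 0.22 (all variance accumulated by the first
tranche), ζ_t = 0.02 thereafter, θ = 0.01 — a near-stable autoregression
whose implied correlations decay with lag.

## Munge

Filter order is fixed and reported per rule: duplicates (keep first) →
MAF < 1% → INFO < 0.9 → MHC interval (default chromosome 6, 26–34 Mb,
GRCh37 convention; configurable because the region is conventionally named
without coordinates) → strand-ambiguous pairs (A/T, C/G) → cross-tranche
allele alignment to the first tranche's orientation (swapped pairs flip
the z sign and frequency; other mismatches drop) → restriction to the
common SNP set, sorted by position. Munge is idempotent and
order-independent; missing INFO/FRQ columns skip the corresponding filter
with a logged warning.

## Multivariate LD-score regression

Each of the k(k+1)/2 regressions fits E[z_t z_u | j] = c + √(N_t N_u) σ_tu
l_j / M by weighted least squares on a shared partition of the
position-sorted common SNP set into B contiguous blocks (default 200).
Weights follow the standard two-pass scheme: pass 1 uses 1/l; pass 2 plugs
the pass-1 estimates into the heteroskedasticity model — univariate
1/[l (1 + N h² l/M)²], cross-trait
1/[l ((1+N_a h²_a l/M)(1+N_b h²_b l/M) + (√(N_aN_b) ρ l/M + c₀)²)].
Intercepts are free by default (fixable at 1/0). The sampling covariance V
of vech(S) is the delete-one block jackknife computed jointly over all
pairs, so its off-diagonal captures cross-estimate dependence; this is
what makes the downstream weighted fit coherent.

The χ² outlier cap (default max(80, 0.001·N̄)) is a real-data robustness
guard. At desk-scale M (10⁴–10⁵ SNPs) the expected per-SNP χ² under the
default conditions reaches 5–25 and the cap would truncate genuine
polygenic signal (we measured ~25% downward bias in ĥ² at M = 2×10⁴), so
all simulation studies disable it. With real panels (M ~ 10⁶) the default
is appropriate.

S estimated this way can be indefinite; `smooth_to_pd` floors eigenvalues
at 1e-6 of the largest before any model is fitted (a no-op on PD input).

## DWLS fitting and the test statistic

Models are declarative parameter maps (free / fixed(value) / equality
groups) with an implied-covariance function; degrees of freedom are
k(k+1)/2 minus free slots. Fitting minimizes
(s − σ(θ))′ diag(V)⁻¹ (s − σ(θ)) with s = vech(S) via trust-region
least squares; variances are optimized on a log scale (so non-negativity
is structural), transmission coefficients and loadings are unconstrained.
Starts: variances at half the observed diagonal, loadings/βs at 0.5, plus
jittered restarts (default 5, seeded). Variance estimates below 1e-4 of
the largest observed variance are flagged as Heywood-adjacent;
non-convergence is flagged on the result, never silent.

Because diag(V)⁻¹ is not the inverse sampling covariance, the minimized
fit value is not χ² distributed. The model test is the residual-based
statistic

    T = r′ [V⁻ − V⁻ D (D′ V⁻ D)⁻ D′ V⁻] r,   r = s − σ(θ̂),

(D the Jacobian at the solution, pseudo-inverses throughout), which is
asymptotically χ²(df) for any consistent estimator. One finite-sample
correction is applied: V is itself estimated from B jackknife blocks, and
plugging V̂ into the quadratic form inflates it by ≈ (B−1)/(B−q−2) (the
first moment of the inverse-Wishart), so T is multiplied by (B−q−2)/(B−1).
Without the correction we measured a mean statistic of 11.3 at df 9 and a
16% type-I rate at nominal 5% (B = 100, q = 21, 200 replicates); with it,
8.8 and 4.5%. The correction is a scalar shared by all models on the same
(S, V), so pseudoAIC ordering and nested-χ² monotonicity are unaffected.
Parameter SEs use the DWLS sandwich
(D′WD)⁻¹ D′W V WD (D′WD)⁻¹ with W = diag(V)⁻¹.

Fit indices: pseudoAIC = χ² + 2·free (sample size is not well defined for
summary-based fits); CFI = 1 − (χ²_m − df_m)/(χ²_b − df_b) against the
independence baseline, deliberately not capped at 1; TLI analogous,
negative values reported as-is; SRMR is the root mean square of
(S − Σ̂)/(sd_i sd_j) over unique elements *including* the diagonal, with
sd from the observed S (conventions differ here; this one is fixed and
stated). Indices are reported as undefined when the baseline χ² ≤ its df.

## Identification notes

- Factor model: identified for k ≥ 3 (just-identified at k = 3, where the
  DWLS solution equals the method-of-moments closed form; the test suite
  checks agreement to 8 significant digits).
- Full simplex (free ζ, β, θ; 3k−1 = 17 free at k = 6): the classic
  quasi-simplex indeterminacies apply. θ₁/ζ₁ and θ_k/ζ_k trade off (only
  their sums and ζ-weighted products are identified), and consequently β₂
  is only identified through the product ζ₁β₂. The optimizer still
  converges (the implied-moment manifold is well defined) and the χ²
  projection handles the rank-deficient Jacobian via pseudo-inverse, but
  individual endpoint estimates should not be interpreted. The recovery
  study therefore averages β₃..β_k. The equality-constrained variant
  (equal βs, equal θs; 8 free, df 13) is fully identified and selectable.
- The single-innovation simplex (all ζ beyond the first fixed at 0) is
  covariance-equivalent to the common-factor model — both imply
  rank-one-plus-diagonal structure with 2k free parameters — so equal fit
  between the two is expected, and pseudoAIC ties are reported as ties.

## Problem sizes and calibration results

Replicate counts and SNP counts in the shipped studies are the package's
own compute-scale choices; all statistical tolerances are self-scaling
(3 Monte-Carlo SEs, binomial bands), so they remain honest at other sizes.

| study | setting | result (seeded run) |
|---|---|---|
| factor-variance recovery | 20 reps, m = 10⁵, full pipeline | mean ψ̂ = 23.99% vs 24% generated |
| type-I error of T | 200 reps, m = 1.2×10⁴, B = 100 | 4.5% at nominal 5% |
| jackknife SE calibration | 200 reps, m = 2×10⁴ | SD(ĥ²)/mean SE = 1.05 |
| jackknife 95% coverage | 100 reps, m = 5×10⁴, N = 5×10⁴ | 95/100 |
| simplex β recovery | 30 reps, m = 2×10⁴ | mean β̂₃..₆ = 0.951 vs 0.95 |
| model selection | 20 reps, factor-generated | factor wins pseudoAIC 95% |

(Each figure is recomputed by the test suite or `scripts/acceptance.py`;
the table records one seeded run of those same functions.)

## Known limitations

- No realized LD between SNPs: jackknife SEs are anti-conservative
  relative to real data; block size has no LD interpretation here.
- Covariance-scale fitting only; standardized quantities are derived
  post hoc. No mean structure (S/V carry no mean information), hence no
  growth or mixture models.
- DWLS with diag(V) weights only; full-V WLS is not offered because the
  jackknife V is too ill-conditioned at q = 21 to invert as a weight.
- Liability-scale conversion, partitioned/stratified LD-score regression
  and individual-SNP follow-up are out of scope.
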