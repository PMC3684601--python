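# Methods

## The statistical problem

Weighted kernel score tests (the SKAT family) test a genomic region of M
markers against a quantitative trait through the statistic Q = Σ_m w_m T_m,
a weighted sum of per-marker score statistics, with a Σ λ_j χ²₁ null. The
standard machinery assumes independent individuals: the trait enters as if
its residuals were exchangeable with a single variance σ². In family
samples the trait covariance is V = σ²_g R + σ²_e I, with R the additive
relationship matrix (2× kinship), and both failure modes are severe:
testing the raw (covariate-centered) trait inflates the null — genotypes of
relatives are correlated exactly along the directions in which the trait is
over-dispersed — while testing environmental residuals (the centered trait
minus the BLUP of the polygenic component) over-corrects, because the
residuals carry less variance than the scale the test assumes.

`famkernel` implements the phenotype-transformation solution: premultiply
the centered trait by V̂⁻¹ once per trait, rescale, and hand the result to
unchanged unrelated-sample kernel machinery.

## The transformation

Write ỹ = y − Xα̂ (GLS fixed effects at the REML optimum) and
g̃ = g − mean(g). The exact mixed-model score statistic per marker is

    T_m = (g̃ᵀ V̂⁻¹ ỹ)² / (g̃ᵀ V̂⁻¹ g̃),

and the marker-specific shrinkage caused by relatedness is

    γ_m = σ̂² (g̃ᵀ V̂⁻¹ g̃) / (g̃ᵀ g̃).

For a polygenic architecture the γ_m concentrate around their mean. The
analytic average implemented here is

    γ̄ = σ̂² tr(V̂⁻¹ R) / N = (1/N) Σ_i σ̂² λ_i / (σ̂²_g λ_i + σ̂²_e),

with λ_i the eigenvalues of R. Two properties pin this form: γ̄ ∈ (0, 1]
for any PSD R with unit mean diagonal (Jensen, concavity of
λ ↦ σ²λ/(σ²_gλ + σ²_e)), and it equals the expectation of γ_m over
gene-dropped markers, whose covariance across individuals is proportional
to R — the simulation suite verifies agreement within 2% at N = 500. A
superficially similar quantity, σ̂² tr(V̂⁻¹)/N, is ≥ 1 on the same spectra
and is **not** the mean gamma factor; using it mis-scales the transformed
trait by ~40% on a deep-pedigree design and collapses the kernel test's
type I error by an order of magnitude. (It does appear below, as the
variance inflation of y⁺.)

The GRAMMAR+ trait is

    y⁺ = (σ̂² / √γ̄) V̂⁻¹ ỹ,

so the simple-regression score T⁺_m = (g̃ᵀ y⁺)² / (σ̂² g̃ᵀ g̃) equals
T_m · (γ_m/γ̄): exact when R = I (any h²), and accurate to a per-marker
relative error of order var(γ_m)/γ̄² otherwise. The square root (rather
than the GRAMMAR-Gamma division by γ̄, also provided) is what makes the
*squared* score land on the right scale; the variance of the square root of
the gamma factors is larger than that of the factors themselves, which is
why the plain GRAMMAR-Gamma correction remains preferable for single-marker
effect estimation while the transformation route is what generalizes to
kernel tests.

One deliberate consequence: y⁺ is calibrated in *score* scale, not in
variance. Its sample variance is inflated relative to σ̂² by the factor
(σ̂² tr(V̂⁻¹)/N)/γ̄ ≥ 1 (~1.4 on the default 50-family design). The kernel
test therefore uses the polygenic fit's σ̂² carried by the transformed
trait, never a variance re-estimated from y⁺ itself — re-estimation would
make every presentation miscalibrated by exactly this spectral factor. The
`TransformedTrait` container keeps the fit attached so the right scale
travels with the vector; `sigma2` can be overridden explicitly.

## Null model fitting

`PolygenicModel` fits y = Xα + u + e by REML (default) or ML. After one
eigendecomposition R = U Λ Uᵀ the model rotates to independent coordinates,
the profile over h² ∈ [0, 1) is one-dimensional (α and σ² concentrate in
closed form per h²), and each likelihood evaluation is O(NC²). A 33-point
grid scan brackets the optimum before bounded Brent refinement (tolerance
1e-6), so the fit is deterministic and robust to the occasional flat or
bimodal profile. Boundary estimates (h² at 0 or ~1) are returned with a
flag, not truncated — the transformation stays defined there. R is
conditioned PSD beforehand by adding (|λ_min| + 1e-8)·I when λ_min < 0
(relevant for genomic relationship estimates), and the jitter is recorded.

## Kernel test

Genotype columns are centered, unit-normalized and Beta(MAF; a, b)-weighted
(weights squared by default, the convention SKAT uses inside its linear
weighted kernel; plain densities via `convention="pdf"`). The three
standard parameter sets (0.5, 0.5), (1, 1), (1, 25) are predefined. MAFs
are the analyzed sample's own. Monomorphic markers are excluded; a testable
region needs ≥ 2 polymorphic markers. Missing genotypes are mean-imputed
per variant before testing (keeps the score algebra exact on complete
matrices); missingness is logged.

Q = Σ w_m T⁺_m is computed as a quadratic form in the covariate-projected
trait; null mixture weights are the eigenvalues of
W^{1/2} G̃ᵀ P G̃ W^{1/2} (P the covariate projector), truncated at
1e-10 × λ_max — a single unit-weight marker gives λ = 1 and Q ~ χ²₁
exactly. Mixture P values use Imhof's inversion integral with absolute
accuracy 1e-6. With few eigenvalues the integrand decays as slowly as
u^(-3/2), so the oscillatory tail is split by the angle-sum identity and
passed to QUADPACK's Fourier-integral routine; only if the inversion still
fails does the Liu-Tang-Zhang moment-matched noncentral χ² take over
(flagged on the result). P values are clipped to (1e-16, 1], never 0.

**Resampling P values** use structure-preserving permutation rather than a
raw shuffle. A transformed trait is not exchangeable: its covariance is
known up to scale (∝ V for the centered original trait, ∝ V⁻¹ for the
V⁻¹-premultiplied presentations), and a raw permutation widens the null by
the variance-inflation factor above (observed: mixture-vs-permutation
correlation capped near 0.92). The implementation whitens through the fit's
eigen-cache, permutes, and recolors — folded into the kernel side so the
cost per permutation is one M-vector product. For unrelated samples this
reduces exactly to plain residual permutation. The estimator is the
add-one rule p = (1 + #{Q_perm ≥ Q_obs})/(1 + B), seeded and reproducible.

An exact related-sample kernel oracle (`exact_kernel_test`) builds Q from
the dense mixed-model scores with the full covariance of the score vector,
cov(ỹ) = V − X(XᵀV⁻¹X)⁻¹Xᵀ. It is O(N³) per region and exists to quantify
the approximation (P-value correlation > 0.99 at N = 200 in the test
suite), not for production use.

## What the simulator emulates — and what it does not

The generator reproduces the statistical structure the method assumes, at
configurable desk scale. Defaults define the study conditions used in the
calibration experiments:

| parameter | default | rationale |
|---|---|---|
| families × structure | 50 three-generation families, 2 offspring/couple (10 members, N = 500) | deep-pedigree relatedness (relationships 0.5 down to 0.125) at a size where 1000 replicates run in minutes |
| markers | 200 unlinked, 10 regions × 20 | matches the 20-marker windowing used throughout |
| MAF spectrum | 50% common U(0.05, 0.5), 50% rare 0.05·Beta(1, 2) | mixture of common and rare variants, rare mass skewed low |
| trait | h² = 0.5, σ² = 1, normal | mid-range heritability; both failure modes clearly expressed |
| causal spec | off by default; e.g. 10 of 20 markers, mixed signs, \|β\| ∝ \|log₁₀ MAF\|, total variance 0.05 | the mixed-sign, rarer-is-larger architecture kernel tests are designed for |
| replicates / seeding | 1000; one global seed spawning per-replicate child streams | reproducible, order-independent |

Genotypes are gene-dropped: founder haplotypes Bernoulli(MAF), Mendelian
transmission, giving exactly cov(g_i, g_j) ∝ R_ij per variant. Not
emulated: linkage disequilibrium beyond family co-transmission (markers are
unlinked even within a region), selection, assortative mating,
genotyping error, non-normal traits, and population stratification between
families (families are exchangeable). Passing calibration here therefore
shows the method handles *pedigree* correlation correctly; it says nothing
about LD-induced correlation between null and causal regions — on real
exome data with strong LD mild inflation of any regional test is expected —
nor about robustness to non-normality.

## Evaluation harness

`run_study` runs the full loop per replicate (gene-drop → phenotype → REML
→ three presentations → all windows × weight schemes) on one fixed
pedigree, pooling region P values. Windows overlapping configured causal
markers are flagged; nulls come from the non-causal regions of the same
replicates (fully-null runs simply have no causal spec). Sliding windows
are index-based per chromosome, [kS, kS + W) with W = 20, S = 10 by
default; a trailing partial window is kept when it holds ≥ 2 markers.
Type I error is the pooled proportion of null P ≤ α with binomial SE;
empirical thresholds are the ⌊αn⌋-th order statistic of the pooled null P
values, and power is reported both at the nominal α and at that empirical
threshold (equalizing the realized type I error across presentations).
Kinship principal components (eigenvectors of the double-centered R, sign
fixed by the largest-magnitude entry, k = 10 as the standard choice) can be
added as covariates; they shrink the inflation of the untransformed trait
without restoring calibration. Replicate reproducibility comes from
deterministic per-replicate child seeds; a failing replicate is logged,
skipped and counted.

## Known limitations

- Single polygenic random effect; no household/dominance components, no
  binary traits.
- γ_m ≈ γ̄ degrades for markers whose carriers concentrate in single deep
  branches (very rare variants in large pedigrees show γ_m above the
  common-marker mean); the exact-oracle correlation check bounds the
  practical impact at desk scale.
- The mixture null treats the variance components as known; no
  small-sample (Kuonen/saddlepoint) correction is applied.
- O(N³) eigendecomposition once per relationship matrix and O(N²) per
  transformed trait: comfortable to N of a few thousand, not biobank scale.
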