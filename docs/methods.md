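# Methods

## Statistical model

The phenotype vector `y` (length n) is modelled as `y = Xb + Zu + ε` with
fixed effects `Xb`, a polygenic random effect `Zu ~ N(0, σ_g² K)` where
`K = ZZᵀ` is the genetic relatedness matrix, and spherical noise
`ε ~ N(0, σ_ε² I)`. Only quantitative phenotypes are supported. The
marginal covariance is `Σ = σ_g² K + σ_ε² I`.

`K` uses per-variant standardized dosages: column `j` is centered at
`2p̂_j` and scaled by `sqrt(2p̂_j(1−p̂_j))`, with `p̂_j` the alt-allele
frequency **in the analysis cohort** (after sample alignment), and
`K = ZZᵀ/m_used` over polymorphic variants. This is the standard
standardized-genotype ("--make-rel"-style) kernel: under Hardy–Weinberg
its diagonal averages 1. Kernels are built leave-one-chromosome-out: the
kernel used when testing chromosome c contains no variants of c, so a
variant never appears as both fixed and random effect. Single-chromosome
data can opt into a whole-genome kernel (`allow_non_loco`) with a warning.

## Variance components: AI-REML

`(σ_g², σ_ε²)` maximize the *restricted* likelihood of `y ~ N(X₀b, Σ)`
under the null design `X₀` (non-genetic fixed effects only), once per
chromosome against that chromosome's LOCO kernel. `K` is eigendecomposed
once (`K = U D Uᵀ`); rotating `y` and `X₀` by `Uᵀ` makes every iteration's
covariance diagonal, so each update costs O(nq²) after the initial O(n³).

Numerical policy:

- initialization at `σ_g² = σ_ε² = Var(y)/2`; one EM-REML step first, then
  average-information (Newton-type) steps;
- an AI step that leaves the feasible region or decreases the restricted
  log-likelihood falls back to an EM step, with step-halving as a last
  resort, so the log-likelihood is non-decreasing over accepted iterations;
- components are floored at `1e-6·Var(y)` (keeps `Σ` positive definite for
  the Cholesky step); hitting the floor is reported, not fatal;
- convergence when the relative parameter change < 1e-6 **and** the
  log-likelihood change < 1e-8, up to 100 iterations (`converged=False`
  afterwards, with a warning; the run continues);
- if the AI matrix is numerically singular (condition number > 1e8 — e.g.
  `K = I`, where only `σ_g² + σ_ε²` is identified), the variance *ratio*
  `λ = σ_g²/σ_ε²` is profiled on a log grid (λ=0 and 57 points in
  `10⁻⁸…10⁶`); for fixed λ the optimal `σ_ε²` is closed-form. Ties are
  broken toward the smallest λ, so the unidentified case resolves to the
  `σ_g² → 0` boundary while preserving `σ_g² + σ_ε² = RSS₀/(n−q₀)` exactly.

## Whitening and the likelihood-ratio scan

`Σ = LLᵀ` (Cholesky); `y_mm = L⁻¹y` and `X_mm = L⁻¹X` are obtained by
triangular solves — explicit inverses are banned throughout. The null model
is fitted once per chromosome by QR-based OLS; each variant's full design
binds the formula token `x` to its dosages, is whitened with the *same* L,
and is compared by the exact Gaussian ML ratio for nested linear models,

    LRT = n · ln(rss₀ / rss₁),   p = P(χ²_df ≥ LRT),  df = q_full − q₀.

ML (not REML) likelihoods are used for this comparison because REML
likelihoods are not comparable across different fixed-effect designs.
Rounding ties (`rss₁ > rss₀` at machine precision) clamp the statistic to
zero; p-values are clamped into (0, 1]. Per-variant degeneracies
(monomorphic `x`, `x` collinear with covariates) yield `p = 1` plus a
`degenerate` flag instead of aborting the chromosome.

When the full model is exactly the null plus a bare `x` term, adding one
column admits the rank-one update
`rss₁ = rss₀ − (x̃·e)²/‖x̃‖²` with `x̃` the whitened genotype residualized
against `X₀_mm`; the scan then reduces to one matrix–vector product per
(permuted) phenotype. Any other model falls back to per-variant
compilation and QR. Both paths are tested to agree to 1e-8.

## Formula dialect

A deliberately small subset of R-style formulas: implicit intercept
(removable with `0`/`-1`), `+` between terms, `:` for elementwise
interactions, and a whitelist of recodes applied to `x` or numeric
covariates: `dom(a)=min(a,1)`, `rec(a)=max(a−1,0)`, `sq(a)=a²`,
`pmin(a,c)`, `pmax(a,c)`. Categorical covariates are treatment-coded with
the lexicographically first level as reference, making compilation
bit-for-bit deterministic. Duplicate terms collapse. Nesting of the null in
the full model is verified numerically on a fixed pseudorandom probe
genotype before any scan; epistasis against a chosen variant (GxG) works by
injecting that variant's dosage as a covariate column `g_<id>`.

## Exchangeable residual permutations

After whitening, the *true* errors are i.i.d., but the realized null
residuals `e_mm = y_mm − X₀_mm b̂` are not exchangeable: estimating b̂
leaves them with singular covariance
`V = I − X₀_mm(X₀_mmᵀX₀_mm)⁻¹X₀_mmᵀ`, whose spectrum is exactly `n−q₀`
ones and `q₀` zeros (verified to 1e-8 at run time; an eigenvalue further
than 1e-6 from the clusters is an error). Projecting onto the unit
eigenvectors `U₁` gives coordinates `ζ = U₁ᵀe_mm` that are exchangeable
under the null. A permutation π produces

    y_mmᵖ = X₀_mm b̂ + U₁ ζ_π ,

which stays in the whitened space (no back-projection through `L` anywhere
in the permutation path) and is rescanned by the same OLS machinery. By
construction `‖ζ_π‖ = ‖ζ‖` exactly and `U₁ᵀX₀_mm = 0`, so the permuted
phenotype reproduces the original null fit — properties the test-suite
checks identically.

Replicate k draws one permutation of the `n−q₀` indices from
`SeedSequence([seed, k])` — deterministic and order-independent, so serial
and parallel (joblib) execution are byte-identical — and applies it to
every chromosome's ζ (all chromosomes share `q₀`), keeping the genome-wide
minimum coherent within the replicate. The threshold is the k-th smallest
of the stored minima with `k = floor(α(n_perm+1))` (exact level at the
customary `n_perm = 1/α − 1`); `k = 0` falls back to the smallest minimum
with a warning. Degenerate variants (p = 1) never contribute minima; a
scan in which *every* variant is degenerate is an error.

A `naive` permutation strategy (shuffle the raw phenotype across samples,
reuse the fitted decorrelation, rescan) is included purely as a negative
control: it is the procedure whose invalidity under structure motivates the
residual scheme.

## Missing data

No imputation by default. Samples missing the phenotype or any covariate
are dropped (and listed with reasons). Variants with any missing call among
the analysis samples are excluded when `max_variant_missing = 0` (the
default); raising the cap keeps variants up to that missing-call rate and
mean-fills the remainder — a prominent warned deviation, required because
one REML fit and one whitening per chromosome cannot accommodate
per-variant sample sets. Positions are 1-based; chromosome labels are taken
verbatim; only diploid biallelic records are accepted (multiallelic sites
are skipped with a warning).

## Synthetic cohorts

The bundled generator emulates the cohorts the method targets:

- `two_pop`: Balding–Nichols allele frequencies — ancestral `p₀ ~ U(0.1,
  0.9)`, subpopulation frequencies `~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F)` at a
  given Fst, two equal subpopulations;
- `f2_cross`: inbred founder pairs (alleles i.i.d. Bernoulli(½)), F2
  offspring formed by gametes with exactly one uniformly placed crossover
  per chromosome — the simplest model producing realistic F2 linkage
  blocks;
- `none`: i.i.d. Hardy–Weinberg genotypes.

The phenotype is `y = 1 + covariate effects + Σ β_j z_j + g + ε` with
standardized causal dosages `z_j`, polygenic term `g = Zu`
(`u` i.i.d. normal) scaled so `σ_g² = h2_target` and `σ_ε² = 1 − h2_target`
(minus any stratification variance), i.e. unit total variance; causal
effect sizes are therefore in phenotypic-SD units per genotype SD.

By default `g` is built from the observed panel itself, so the analysis
model's kernel assumption holds exactly — ideal for variance-component
recovery studies. For *null* calibration studies this default is
misleading at scaled-down panel sizes: with m = 200 panel variants each
tested variant carries a true effect of variance `σ_g²/m`, which the
genome-wide minimum detects. `background_loci` therefore draws `g` from
that many additional **unobserved** loci simulated under the same
structure (same subpopulation labels / founder assignments; appended to
the same chromosomes for the F2 cross), leaving the panel truly
non-causal; calibration studies here use 10 000 background loci as the
infinitesimal-model emulation. In the F2 cross even unobserved background
loci are in strong LD with the panel, so a heritable F2 trait is never
"null" against its own genome — a property of F2 designs, not a flaw of
the threshold. `pop_effect` adds an environmental mean shift aligned with
the two_pop split (classic stratification); note `c²vvᵀ` is not in the
span of {K, I}, so heavy stratification is deliberately mis-specified for
the LMM and inflates any phenotype-side test — it exists to study exactly
that regime.

What the generator does **not** emulate: realistic LD maps and
recombination interference, allele-frequency ascertainment, genotyping
error, non-Gaussian phenotypes. Passing tests therefore demonstrate
correctness of the algorithmic machinery and calibration under the stated
generative models, not robustness to those real-data features.

## Problem sizes used in the checks

The test-suite's end-to-end studies use: GLS/projector identities at
n ≤ 30; variance-component recovery at n = 500, m = 2000 (50 replicates);
threshold calibration on 200 null two-population cohorts (Fst 0.3,
n = 100, m = 200, h² = 0.5 from 10 000 background loci, 100 permutations,
α = 0.05); power on a planted 0.5-SD QTL at n = 300 (50 replicates). With
these sizes the calibration study measures a family-wise error slightly
above the nominal 0.05 (≈ 0.07–0.08 across independent seed sets): with
only 150 variants per LOCO kernel the estimated `Σ̂` is noisy, the residual
permutation conditions on it, and the real scan retains structure the
permuted scans cannot see. The effect shrinks as the kernel's variant count
grows. Naive phenotype permutation measures consistently *above* the
residual scheme (anti-conservative), but at these sizes the gap is small
(≈ 0.01–0.03): the LRT is scale-invariant, so naive permutation only
deflates statistics of strongly structure-aligned variants, and the
genome-wide minimum is usually attained at weakly aligned ones. The
contrast is dramatic only in heavily confounded designs (F2 families,
strong stratification).

## Known limitations

- Binary phenotypes, eQTL-style multi-gene scans and bgen input are out of
  scope; one phenotype per permutation stream (multiple phenotypes are
  independent runs sharing genotype parsing and kernels).
- Only the genome-wide min-p null is produced (no per-variant permutation
  p-values, no step-down procedures, no parametric tail fit).
- The chi-square reference for the LRT is asymptotic; at very small n an
  exact F-test would differ (both the real and permuted scans share the
  approximation, so thresholds remain internally consistent).
- One random effect only; no dominance kernels, no sparse solvers — dense
  O(n³) per-chromosome eigendecompositions cap practical cohort sizes at
  around 10⁴ samples.
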