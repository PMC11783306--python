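# permlmm

Linear mixed model GWAS with user-defined nested models and a
permutation-based genome-wide significance threshold that remains valid
under population structure and covariates.

`permlmm` is aimed at quantitative-trait mapping in *structured* cohorts —
multi-parental F2 crosses of inbred lines, diverged subpopulations, farm and
model-organism panels — where no community-accepted genome-wide significance
threshold exists and naive phenotype permutations are invalid: related
samples are not exchangeable under the null, and shuffling the phenotype
breaks its relationship with the covariates.

## Model

Each variant is tested under the linear mixed model

```
y = X b + Z u + ε,      u ~ N(0, σ_g² K),      ε ~ N(0, σ_ε² I)
```

where `K = Z Zᵀ` is the genetic relatedness matrix built from standardized
dosages (centered at `2p̂`, scaled by `sqrt(2p̂(1−p̂))`), computed
**leave-one-chromosome-out** (LOCO) so a variant is never fitted as both a
fixed and a random effect. Per chromosome:

1. `(σ_g², σ_ε²)` are estimated once by **AI-REML** under the *null* design
   (non-genetic fixed effects only).
2. `Σ = σ_g² K + σ_ε² I` is factored as `Σ = L Lᵀ` and the problem is
   whitened: `y_mm = L⁻¹ y`, `X_mm = L⁻¹ X` (triangular solves, never an
   explicit inverse). Errors are now spherical and OLS applies.
3. Every variant is tested by the Gaussian likelihood-ratio test between
   two user formulas in which the token `x` denotes the current variant,
   e.g. `y ~ x + x:env + sex` against `y ~ sex`:
   `LRT = n·ln(rss₀/rss₁) ~ χ²(q_full − q_null)`.
   Dominance (`dom(x)`), recessive (`rec(x)`) recodes, GxE interactions and
   GxG terms against a chosen variant are all just formulas.

The genome-wide threshold comes from permuting *exchangeable* residuals:
the realized null residuals `e_mm = y_mm − X_mm b̂` have singular covariance
`V = I − X_mm(X_mmᵀX_mm)⁻¹X_mmᵀ`, whose eigenvectors with unit eigenvalue
(`U₁`, `n − q` of them) span a space where the residual coordinates
`ζ = U₁ᵀ e_mm` *are* exchangeable. Each permutation replicate shuffles `ζ`,
rebuilds `y_mmᵖ = X_mm b̂ + U₁ ζᵖ` (staying in the whitened space — no
back-projection), rescans the genome, and records the minimum p-value. The
empirical `α`-quantile of those minima is the significance threshold.

## Worked example

Simulate an F2 cross of two founder pairs (200 individuals, 4 chromosomes,
50 markers each, h² = 0.4, one planted QTL of effect 0.6 SD, a sex effect),
then run a scan with 100 permutations:

```python
from permlmm import SimConfig, simulate, write_fixture
cfg = SimConfig(n_samples=200, n_chromosomes=4, variants_per_chrom=50,
                structure="f2_cross", n_founder_pairs=2, h2_target=0.4,
                causal=((87, 0.6),), covariate_effects={"sex": 0.5}, seed=7)
g, t, truth = simulate(cfg)
write_fixture(g, t, "fix", format="vcf", truth=truth)
```

```bash
permlmm run --geno fix/sim.vcf --pheno fix/pheno.tsv --covar fix/covar.tsv \
    --model "y ~ x + sex" --null-model "y ~ sex" \
    --permutations 100 --alpha 0.05 --seed 42 --out out/
```

`out/variance_components.tsv` (one AI-REML fit per chromosome, each against
its LOCO kernel):

```
chrom  sigma_g2  sigma_e2  h2     loglik    n_iter  converged
1      0.515     0.663     0.437  -266.04   9       True
2      0.368     0.924     0.285  -292.60   11      True
3      0.634     0.608     0.510  -260.88   7       True
4      0.710     0.570     0.554  -258.20   6       True
```

`out/threshold.tsv` reports the permutation threshold
(`alpha=0.05, n_perm=100, threshold=1.71e-4`), and the top of
`out/association.tsv` sorted by p-value:

```
chrom  pos    id      beta_x     lrt_stat  df  p_value
2      37000  v00086  x=1.13696  67.12     1   2.55e-16
2      38000  v00087  x=1.12296  66.97     1   2.76e-16
2      48000  v00097  x=1.06345  64.55     1   9.42e-16
```

The planted QTL (`v00087`) and its tightly linked F2 neighbours dominate
the scan, far below the threshold; `beta_x` is the per-dosage effect in the
whitened regression. `out/manhattan.png` and `out/qq.png` visualise the
scan with the threshold line.

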