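"""Structured-population genotype/phenotype simulator.

This is the test bed for the whole engine: it emulates the kinds of cohorts
the method targets — structured populations such as two diverged
subpopulations (Balding–Nichols allele frequencies at a given Fst) or an F2
cross of inbred founder lines — with a polygenic background generated from
the simulated genotypes themselves (g = Z u with standardized Z and i.i.d.
normal u), so the relatedness-kernel assumption of the analysis model holds
by construction.  Optional focal variants and covariates add fixed effects.

Focal ("causal") effect sizes are per *standardized* dosage, so with the
default unit total variance an effect of 0.5 is half a phenotypic standard
deviation per standard deviation of genotype.

By default the polygenic term is built from the observed variants
themselves, so the analysis model's kernel assumption holds exactly.  With
a scaled-down panel (hundreds of loci) this makes every *tested* variant
carry a real effect of variance sigma_g2 / m — detectable at the genome-wide
minimum.  For experiments that need a strictly null panel on a heritable,
structured trait, ``background_loci`` draws the polygenic term from that
many additional unobserved loci simulated under the same structure (same
subpopulation labels / founder assignments), leaving the observed panel
truly non-causal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .grm import _standardize
from .io_data import GenotypeData, PhenoCovarTable, VariantRecord, write_plink

__all__ = ["SimConfig", "SimTruth", "simulate", "write_fixture"]


@dataclass
class SimConfig:
    n_samples: int = 100
    n_chromosomes: int = 4
    variants_per_chrom: int = 50
    structure: str = "two_pop"  # {"none", "two_pop", "f2_cross"}
    fst: float = 0.3
    n_founder_pairs: int = 2
    h2_target: float = 0.5
    causal: tuple[tuple[int, float], ...] = ()  # (variant index, standardized effect)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    background_loci: int = 0  # unobserved same-structure loci driving the polygenic term
    pop_effect: float = 0.0  # environmental stratification: effect of the +/-1 subpopulation code
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_target < 1.0:
            raise ConfigError("h2_target must be in [0, 1)")
        if self.structure not in ("none", "two_pop", "f2_cross"):
            raise ConfigError(f"unknown structure {self.structure!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.n_chromosomes < 1 or self.variants_per_chrom < 1 or self.n_samples < 3:
            raise ConfigError("population/genome dimensions too small")
        if self.pop_effect and self.structure != "two_pop":
            raise ConfigError("pop_effect requires the two_pop structure")
        if self.h2_target + self.pop_effect**2 >= 1.0:
            raise ConfigError("h2_target + pop_effect^2 must be < 1 (unit total variance)")


@dataclass
class SimTruth:
    """Latent values the simulator used (for test assertions)."""

    polygenic: np.ndarray  # per-sample g
    noise: np.ndarray
    sigma_g2: float
    sigma_e2: float
    causal: tuple[tuple[int, float], ...]
    covariate_effects: dict[str, float]
    pop_labels: np.ndarray | None = None
    founder_haplotypes: np.ndarray | None = None  # (2*pairs, m) for f2_cross


def _genotypes_none(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    p = rng.uniform(0.1, 0.9, size=m)
    return rng.binomial(2, p, size=(n, m)).astype(float), None


def _genotypes_two_pop(
    rng: np.random.Generator, n: int, m: int, fst: float
) -> tuple[np.ndarray, np.ndarray]:
    """Balding–Nichols: pop frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    p0 = rng.uniform(0.1, 0.9, size=m)
    a, b = p0 * (1 - fst) / fst, (1 - p0) * (1 - fst) / fst
    labels = np.repeat([0, 1], [n - n // 2, n // 2])
    dos = np.empty((n, m))
    for pop in (0, 1):
        p_pop = rng.beta(a, b)
        rows = labels == pop
        dos[rows] = rng.binomial(2, p_pop, size=(int(rows.sum()), m))
    return dos, labels


def _genotypes_f2(
    rng: np.random.Generator, n: int, block_sizes: list[int], n_pairs: int
) -> tuple[np.ndarray, np.ndarray]:
    """F2 of inbred founder pairs: one uniform crossover per chromosome per
    gamete, founder alleles i.i.d. Bernoulli(1/2).  ``block_sizes`` gives the
    number of loci on each chromosome."""
    m = int(sum(block_sizes))
    bounds = np.concatenate([[0], np.cumsum(block_sizes)])
    founders = rng.integers(0, 2, size=(2 * n_pairs, m)).astype(float)

    def gamete(hap_a: np.ndarray, hap_b: np.ndarray) -> np.ndarray:
        out = np.empty(m)
        for c, m_per in enumerate(block_sizes):
            lo, hi = bounds[c], bounds[c + 1]
            cut = rng.integers(0, m_per + 1)
            first, second = (hap_a, hap_b) if rng.random() < 0.5 else (hap_b, hap_a)
            out[lo : lo + cut] = first[lo : lo + cut]
            out[lo + cut : hi] = second[lo + cut : hi]
        return out

    dos = np.empty((n, m))
    pair_of = rng.integers(0, n_pairs, size=n)
    for i in range(n):
        pa, pb = founders[2 * pair_of[i]], founders[2 * pair_of[i] + 1]
        # both parents are F1s of the same founder pair
        dos[i] = gamete(pa, pb) + gamete(pa, pb)
    return dos, founders


def simulate(cfg: SimConfig) -> tuple[GenotypeData, PhenoCovarTable, SimTruth]:
    """Draw genotypes, covariates and phenotype; return data plus latents."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    m = cfg.n_chromosomes * cfg.variants_per_chrom
    pop_labels = founders = None
    # background loci (if any) are simulated jointly with the panel so they
    # share the structure: same subpopulation labels / founder assignments,
    # and for the F2 cross the same chromosomes (appended per block)
    bg = int(cfg.background_loci)
    if cfg.structure == "f2_cross":
        per = [bg // cfg.n_chromosomes] * cfg.n_chromosomes
        for c in range(bg % cfg.n_chromosomes):
            per[c] += 1
        block_sizes = [cfg.variants_per_chrom + e for e in per]
        dos_all, founders = _genotypes_f2(rng, n, block_sizes, cfg.n_founder_pairs)
        obs_mask = np.zeros(sum(block_sizes), dtype=bool)
        lo = 0
        for c, size in enumerate(block_sizes):
            obs_mask[lo : lo + cfg.variants_per_chrom] = True
            lo += size
    else:
        if cfg.structure == "none":
            dos_all, _ = _genotypes_none(rng, n, m + bg)
        else:
            dos_all, pop_labels = _genotypes_two_pop(rng, n, m + bg, cfg.fst)
        obs_mask = np.zeros(m + bg, dtype=bool)
        obs_mask[:m] = True
    dos = dos_all[:, obs_mask]
    dos_bg = dos_all[:, ~obs_mask]
    if cfg.structure == "f2_cross":
        founders = founders[:, obs_mask]

    sample_ids = [f"s{i:04d}" for i in range(n)]
    variants = [
        VariantRecord(
            chromosome=f"{j // cfg.variants_per_chrom + 1}",
            position=(j % cfg.variants_per_chrom + 1) * 1000,
            id=f"v{j:05d}",
            ref_allele="A",
            alt_allele="T",
        )
        for j in range(m)
    ]

    Z, poly = _standardize(dos)
    sigma_g2 = cfg.h2_target
    sigma_e2 = 1.0 - cfg.h2_target - cfg.pop_effect**2
    if sigma_g2 > 0:
        if bg > 0:
            Zg, poly_g = _standardize(dos_bg)
        else:
            Zg, poly_g = Z, poly
        if not poly_g.any():
            raise ConfigError("h2_target > 0 requires at least one polymorphic variant")
        u = rng.normal(0.0, np.sqrt(sigma_g2 / poly_g.sum()), size=int(poly_g.sum()))
        g = Zg[:, poly_g] @ u
    else:
        g = np.zeros(n)
    noise = rng.normal(0.0, np.sqrt(sigma_e2), size=n)

    covar_cols: dict[str, object] = {}
    fixed = np.zeros(n)
    for name, beta in cfg.covariate_effects.items():
        if name == "sex":
            lab = rng.integers(0, 2, size=n)
            covar_cols[name] = np.where(lab == 1, "M", "F")
            fixed += beta * lab
        else:
            vals = rng.standard_normal(n)
            covar_cols[name] = vals
            fixed += beta * vals

    for idx, beta in cfg.causal:
        if not 0 <= idx < m:
            raise ConfigError(f"causal variant index {idx} out of range")
        if not poly[idx]:
            raise ConfigError(f"causal variant {idx} is monomorphic")
        fixed += beta * Z[:, idx]

    if cfg.pop_effect and pop_labels is not None:
        fixed = fixed + cfg.pop_effect * (2.0 * pop_labels - 1.0)

    y = 1.0 + fixed + g + noise

    if cfg.missing_rate > 0:
        mask = rng.random(size=dos.shape) < cfg.missing_rate
        dos = dos.copy()
        dos[mask] = np.nan

    geno = GenotypeData(sample_ids, variants, dos)
    pheno = pd.DataFrame({"pheno": y}, index=sample_ids)
    covar = pd.DataFrame(covar_cols, index=sample_ids)
    table = PhenoCovarTable(sample_ids=sample_ids, phenotypes=pheno, covariates=covar)
    truth = SimTruth(
        polygenic=g,
        noise=noise,
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        causal=cfg.causal,
        covariate_effects=dict(cfg.covariate_effects),
        pop_labels=pop_labels,
        founder_haplotypes=founders,
    )
    return geno, table, truth


# ---------------------------------------------------------------------------
# fixture writers
# ---------------------------------------------------------------------------

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def _write_vcf(g: GenotypeData, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in g.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.sample_ids) + "\n")
        for j, v in enumerate(g.variants):
            calls = [
                "./." if np.isnan(d) else _GT[d] for d in g.dosages[:, j]
            ]
            fh.write(
                f"{v.chromosome}\t{v.position}\t{v.id}\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_fixture(
    g: GenotypeData,
    t: PhenoCovarTable,
    dir: str | Path,
    format: str = "vcf",
    truth: SimTruth | None = None,
) -> dict[str, Path]:
    """Write genotype + phenotype (+ covariate, + truth) files to ``dir``.

    Returns a name -> path map; everything round-trips through io_data.
    """
    dir = Path(dir)
    dir.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    if format == "vcf":
        out["geno"] = dir / "sim.vcf"
        _write_vcf(g, out["geno"])
    elif format == "plink":
        out["geno"] = dir / "sim.bed"
        write_plink(g, dir / "sim")
    else:
        raise ValueError(f"unknown fixture format {format!r}")

    out["pheno"] = dir / "pheno.tsv"
    ph = t.phenotypes.copy()
    ph.insert(0, "sample_id", t.sample_ids)
    ph.to_csv(out["pheno"], sep="\t", index=False, na_rep="NA")

    if t.covariates.shape[1]:
        out["covar"] = dir / "covar.tsv"
        cv = t.covariates.copy()
        cv.insert(0, "sample_id", t.sample_ids)
        cv.to_csv(out["covar"], sep="\t", index=False, na_rep="NA")

    if truth is not None:
        out["truth"] = dir / "truth.tsv"
        pd.DataFrame(
            {
                "sample_id": t.sample_ids,
                "polygenic": truth.polygenic,
                "noise": truth.noise,
            }
        ).to_csv(out["truth"], sep="\t", index=False)
    return out
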