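import numpy as np
import pandas as pd
import pytest

from permlmm import SimConfig, align_samples, simulate
from permlmm.io_data import AlignedDataset, GenotypeData, PhenoCovarTable, VariantRecord


def make_aligned(
    n=60,
    n_chromosomes=2,
    variants_per_chrom=20,
    structure="two_pop",
    seed=0,
    covariate_effects=None,
    extra_covariates=None,
    **kw,
):
    """Simulated, aligned dataset; ``extra_covariates`` adds non-causal columns."""
    cfg = SimConfig(
        n_samples=n,
        n_chromosomes=n_chromosomes,
        variants_per_chrom=variants_per_chrom,
        structure=structure,
        covariate_effects=covariate_effects or {},
        seed=seed,
        **kw,
    )
    g, t, truth = simulate(cfg)
    if extra_covariates:
        rng = np.random.default_rng(seed + 991)
        for name in extra_covariates:
            if name == "sex" and name not in t.covariates:
                t.covariates[name] = np.where(rng.integers(0, 2, n) == 1, "M", "F")
            elif name not in t.covariates:
                t.covariates[name] = rng.standard_normal(n)
    return align_samples(g, t), truth


@pytest.fixture
def aligned_small():
    data, _ = make_aligned(n=50, seed=3, extra_covariates=["sex", "env"])
    return data


@pytest.fixture
def tiny_genotypes():
    """Hand-built 4-sample, 3-variant genotype set spanning two chromosomes."""
    variants = [
        VariantRecord("1", 100, "v1", "A", "G"),
        VariantRecord("1", 200, "v2", "C", "T"),
        VariantRecord("2", 100, "v3", "G", "A"),
    ]
    dos = np.array(
        [
            [0.0, 1.0, 2.0],
            [1.0, 1.0, 0.0],
            [2.0, 0.0, 1.0],
            [0.0, 2.0, 1.0],
        ]
    )
    return GenotypeData(["a", "b", "c", "d"], variants, dos)


@pytest.fixture
def tiny_table():
    ids = ["a", "b", "c", "d"]
    return PhenoCovarTable(
        sample_ids=ids,
        phenotypes=pd.DataFrame({"bw": [1.0, 2.0, 0.5, 1.5]}, index=ids),
        covariates=pd.DataFrame({"sex": ["F", "M", "M", "F"]}, index=ids),
    )
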