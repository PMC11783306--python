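"""End-to-end orchestration: kernels -> REML -> whitening -> scan -> permutations.

This module glues the pieces together in the order the method prescribes:
LOCO kernels from the aligned dosages, one AI-REML fit per chromosome under
the null design, one Cholesky whitening and one null OLS fit per chromosome
(shared by every variant and every permutation on it), then the genome scan
and the permutation engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .grm import LocoKernels, build_loco
from .io_data import AlignedDataset
from .lmm_core import AssociationResult, DecorrelatedProblem, NullFit, decorrelate, fit_null
from .model_spec import DesignMatrix, ModelPair, NestingReport, check_nesting, compile_null
from .permutation import PermutationEngine
from .variance_components import VarianceComponents, fit_aireml

__all__ = ["PreparedGwas", "prepare_gwas", "association_frame", "genomic_inflation"]


@dataclass
class PreparedGwas:
    data: AlignedDataset
    mp: ModelPair
    X0: DesignMatrix
    nesting: NestingReport
    loco: LocoKernels
    vc_by_chrom: dict[str, VarianceComponents]
    problems: dict[str, tuple[DecorrelatedProblem, NullFit]]
    engine: PermutationEngine

    def scan_genome(self) -> list[AssociationResult]:
        """Association results for every variant, genome order."""
        out: list[AssociationResult] = []
        for chrom in self.loco.chromosomes:
            out.extend(self.engine.units[chrom].scanner.scan())
        return out


def prepare_gwas(
    data: AlignedDataset,
    mp: ModelPair,
    allow_non_loco: bool = False,
    seed: int = 0,
    fixed_components: tuple[float, float] | None = None,
) -> PreparedGwas:
    """Run every per-chromosome preparation step once.

    ``fixed_components`` pins (sigma_g2, sigma_e2) instead of REML — useful
    for diagnostics such as checking the OLS limit with K = I and (0, 1).
    """
    nesting = check_nesting(mp, data, seed=seed)
    X0 = compile_null(mp, data)
    chroms_arr = data.variant_chromosomes()
    loco = build_loco(data.dosages, chroms_arr, data.sample_ids, allow_non_loco=allow_non_loco)

    vc_by_chrom: dict[str, VarianceComponents] = {}
    problems: dict[str, tuple[DecorrelatedProblem, NullFit]] = {}
    dos_by: dict[str, np.ndarray] = {}
    var_by: dict[str, list] = {}
    for chrom in loco.chromosomes:
        K = loco[chrom]
        if fixed_components is not None:
            sg, se = fixed_components
            vc = VarianceComponents(
                sigma_g2=sg, sigma_e2=se, h2=sg / (sg + se) if sg + se else 0.0,
                loglik=float("nan"), n_iter=0, converged=True,
            )
        else:
            vc = fit_aireml(data.y, X0, K)
        vc_by_chrom[chrom] = vc
        dp = decorrelate(data.y, X0, K, vc, chromosome=chrom)
        nf = fit_null(dp)
        problems[chrom] = (dp, nf)
        mask = chroms_arr == chrom
        dos_by[chrom] = data.dosages[:, mask]
        var_by[chrom] = [v for v, k in zip(data.variants, mask) if k]

    engine = PermutationEngine(problems, dos_by, var_by, mp, data)
    return PreparedGwas(
        data=data, mp=mp, X0=X0, nesting=nesting, loco=loco,
        vc_by_chrom=vc_by_chrom, problems=problems, engine=engine,
    )


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tidy per-variant table (one row per variant, TSV-ready)."""
    rows = []
    for r in results:
        beta = ";".join(f"{k}={v:.6g}" for k, v in r.beta_x.items()) or "NA"
        rows.append(
            {
                "chrom": r.variant.chromosome,
                "pos": r.variant.position,
                "id": r.variant.id,
                "ref": r.variant.ref_allele,
                "alt": r.variant.alt_allele,
                "beta_x": beta,
                "lrt_stat": r.lrt_stat,
                "df": r.df,
                "p_value": r.p_value,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows)


def genomic_inflation(p_values: np.ndarray) -> float:
    """lambda_GC: median observed chi2(1) statistic over its null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p) & (p > 0) & (p <= 1)]
    stats = scipy.stats.chi2.isf(p, 1)
    return float(np.median(stats) / scipy.stats.chi2.isf(0.5, 1))
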