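"""Exchangeable residual permutations and the genome-wide threshold.

Even when the true errors are i.i.d. after whitening, the realized null
residuals emm = ymm - X0mm b̂ are not exchangeable: estimating b̂ ties them
together with covariance structure V = I - X0mm (X0mm^T X0mm)^{-1} X0mm^T.
V has n - q0 unit eigenvalues and q0 zero eigenvalues, so projecting the
residuals onto the unit-eigenvalue basis U1 gives n - q0 coordinates
zeta = U1^T emm that ARE exchangeable under the null.  A permutation pi
yields the shuffled phenotype

    ymm_pi = X0mm b̂ + U1 zeta[pi]

which stays in the whitened space (no back-projection through L) and is
scanned with the same per-chromosome OLS machinery.  The minimum p-value of
each permuted genome scan forms the null distribution whose alpha-quantile
is the empirical genome-wide significance threshold.

A "naive" strategy (shuffling the raw phenotype across samples) is also
provided purely as a negative control: with population structure it is
exactly the procedure whose invalidity motivates the residual scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .errors import NoValidTestError, PermLMMError, ProjectorError
from .io_data import AlignedDataset
from .lmm_core import ChromosomeScanner, DecorrelatedProblem, NullFit
from .model_spec import ModelPair

__all__ = [
    "ResidualProjector",
    "PermutationNull",
    "build_projector",
    "permute_once",
    "draw_permutation",
    "PermutationEngine",
    "derive_threshold",
]

EIG_CLUSTER_TOL = 1e-6  # eigenvalues must sit this close to {0, 1}


@dataclass
class ResidualProjector:
    """Basis of the unit-eigenvalue subspace of the residual covariance V."""

    U1: np.ndarray  # n x (n - q0)
    fitted0: np.ndarray
    q0: int

    @property
    def dim(self) -> int:
        return self.U1.shape[1]


@dataclass
class PermutationNull:
    """Per-permutation genome-wide minimum p-values and the derived threshold."""

    min_p: np.ndarray
    alpha: float
    threshold: float
    seed: int
    strategy: str = "residual"


def build_projector(dp: DecorrelatedProblem, nf: NullFit) -> ResidualProjector:
    """Spectral decomposition of V = I - H0; U1 spans the unit eigenvalues."""
    n, q0 = dp.n, dp.q0
    V = np.eye(n)
    if q0:
        Q, _ = np.linalg.qr(dp.X0mm)
        V -= Q @ Q.T
    w, U = np.linalg.eigh(V)
    dist = np.minimum(np.abs(w), np.abs(w - 1.0))
    if dist.max() > EIG_CLUSTER_TOL:
        raise ProjectorError(
            f"projector eigenvalue {w[np.argmax(dist)]:.6g} off the {{0,1}} clusters"
        )
    unit = w > 0.5
    if int(unit.sum()) != n - q0:
        raise ProjectorError(
            f"expected {n - q0} unit eigenvalues, found {int(unit.sum())}"
        )
    return ResidualProjector(U1=U[:, unit], fitted0=nf.fitted0, q0=q0)


def permute_once(rp: ResidualProjector, nf: NullFit, perm: np.ndarray) -> np.ndarray:
    """Shuffled whitened phenotype ymm_pi = fitted0 + U1 * P * U1^T * emm."""
    perm = np.asarray(perm)
    if sorted(perm.tolist()) != list(range(rp.dim)):
        raise PermLMMError(f"not a permutation of {rp.dim} indices")
    zeta = rp.U1.T @ nf.emm
    return rp.fitted0 + rp.U1 @ zeta[perm]


def draw_permutation(seed: int, perm_id: int, size: int) -> np.ndarray:
    """Deterministic permutation from (seed, perm_id), replicate-independent."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(perm_id)]))
    return rng.permutation(size)


@dataclass
class _ChromUnit:
    dp: DecorrelatedProblem
    nf: NullFit
    projector: ResidualProjector
    scanner: ChromosomeScanner


class PermutationEngine:
    """Runs permuted genome scans over prepared per-chromosome problems.

    One permutation vector (length n - q0) is shared by every chromosome
    within a replicate, so the genome-wide minimum is coherent; this is
    valid because every chromosome's zeta has the same length.
    """

    def __init__(
        self,
        problems: dict[str, tuple[DecorrelatedProblem, NullFit]],
        dosages_by_chrom: dict[str, np.ndarray],
        variants_by_chrom: dict[str, list],
        mp: ModelPair,
        data: AlignedDataset,
    ):
        self.data = data
        self.units: dict[str, _ChromUnit] = {}
        q0s = set()
        for chrom, (dp, nf) in problems.items():
            proj = build_projector(dp, nf)
            scanner = ChromosomeScanner(
                dp, nf, dosages_by_chrom[chrom], variants_by_chrom[chrom], mp, data
            )
            self.units[chrom] = _ChromUnit(dp, nf, proj, scanner)
            q0s.add(dp.q0)
        if len(q0s) != 1:
            raise PermLMMError("chromosomes disagree on the null design width")
        self.q0 = q0s.pop()
        self.n = data.n_samples

    def null_scan(self, perm_id: int, seed: int, strategy: str = "residual") -> float:
        """Genome-wide minimum p-value for one permutation replicate."""
        if strategy == "residual":
            perm = draw_permutation(seed, perm_id, self.n - self.q0)
            mins = []
            for unit in self.units.values():
                ymm_pi = permute_once(unit.projector, unit.nf, perm)
                # emm_pi is orthogonal to X0mm, so the permuted null RSS is
                # exactly ||zeta||^2 = rss0; computed directly for safety
                e_pi = ymm_pi - unit.nf.fitted0
                mins.append(unit.scanner.min_p(ymm_pi, float(e_pi @ e_pi)))
        elif strategy == "naive":
            perm = draw_permutation(seed, perm_id, self.n)
            y_pi = self.data.y[perm]
            mins = []
            for unit in self.units.values():
                ymm_pi = unit.dp.whiten(y_pi)
                if unit.dp.q0:
                    coef, *_ = np.linalg.lstsq(unit.dp.X0mm, ymm_pi, rcond=None)
                    rss0_pi = float(np.sum((ymm_pi - unit.dp.X0mm @ coef) ** 2))
                else:
                    rss0_pi = float(ymm_pi @ ymm_pi)
                mins.append(unit.scanner.min_p(ymm_pi, rss0_pi))
        else:
            raise ValueError(f"unknown permutation strategy {strategy!r}")
        mins = [m for m in mins if not np.isnan(m)]
        if not mins:
            raise NoValidTestError("all variants degenerate in permutation scan")
        return min(mins)

    def run(
        self,
        n_perm: int,
        alpha: float,
        seed: int,
        strategy: str = "residual",
        n_jobs: int = 1,
    ) -> PermutationNull:
        """n_perm permuted genome scans -> empirical alpha-threshold."""
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if n_perm < 1.0 / alpha:
            warnings.warn(
                f"{n_perm} permutations is fewer than 1/alpha = {1.0 / alpha:.0f}; "
                "the threshold will fall back to the smallest minimum p-value"
            )
        ids = range(1, n_perm + 1)
        if n_jobs == 1:
            min_p = np.array([self.null_scan(k, seed, strategy) for k in ids])
        else:
            min_p = np.array(
                Parallel(n_jobs=n_jobs)(
                    delayed(self.null_scan)(k, seed, strategy) for k in ids
                )
            )
        thr = derive_threshold(min_p, alpha)
        return PermutationNull(
            min_p=min_p, alpha=alpha, threshold=thr, seed=seed, strategy=strategy
        )


def derive_threshold(min_p: np.ndarray | PermutationNull, alpha: float | None = None) -> float:
    """Empirical alpha-quantile of the min-p null: the k-th smallest value
    with k = floor(alpha * (n_perm + 1)); k = 0 falls back to the smallest."""
    if isinstance(min_p, PermutationNull):
        alpha = min_p.alpha if alpha is None else alpha
        min_p = min_p.min_p
    if alpha is None:
        raise ValueError("alpha required when min_p is an array")
    min_p = np.asarray(min_p, dtype=float)
    if min_p.size == 0:
        raise PermLMMError("empty permutation null")
    k = int(np.floor(alpha * (min_p.size + 1)))
    srt = np.sort(min_p)
    if k == 0:
        warnings.warn("too few permutations for the requested alpha; using smallest min-p")
        return float(srt[0])
    return float(srt[k - 1])
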