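"""Genetic relatedness matrices, leave-one-chromosome-out (LOCO).

K is built from per-variant standardized genotypes: each dosage column is
centered at 2*p and scaled by sqrt(2*p*(1-p)) with p the alt-allele
frequency in the analysis samples, then K = Z Z^T / m_used.  Under
Hardy-Weinberg genotypes the diagonal averages to 1.  Testing a variant
against a kernel built from its own chromosome would fit it as both a fixed
and a random effect, so each chromosome gets a kernel computed from all the
others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import KernelError

__all__ = ["LocoKernels", "compute_grm", "build_loco", "export_rel"]


@dataclass
class LocoKernels:
    """One n x n kernel per chromosome, each excluding that chromosome."""

    chromosomes: list[str]
    K_by_chrom: dict[str, np.ndarray]
    m_used: dict[str, int]
    sample_ids: list[str]

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.K_by_chrom[chrom]


def _standardize(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize dosages; returns (Z, polymorphic mask).

    Missing values (already mean-filled upstream when permitted) contribute 0
    after centering.  Monomorphic columns are flagged, not scaled.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(dosages, axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0) & ~np.isnan(p)
    scale = np.sqrt(2.0 * p * (1.0 - p), where=poly, out=np.ones_like(p))
    Z = (dosages - 2.0 * p) / scale
    Z = np.nan_to_num(Z, nan=0.0)
    return Z, poly


def compute_grm(
    dosages: np.ndarray,
    variant_chroms: np.ndarray | list[str],
    exclude_chrom: str | None = None,
) -> tuple[np.ndarray, int]:
    """K = (1/m_used) sum_j z_j z_j^T over polymorphic variants not on
    ``exclude_chrom``.  Returns (K, m_used)."""
    variant_chroms = np.asarray(variant_chroms, dtype=object)
    keep = np.ones(dosages.shape[1], dtype=bool)
    if exclude_chrom is not None:
        keep &= variant_chroms != exclude_chrom
    Z, poly = _standardize(dosages)
    keep &= poly
    m_used = int(keep.sum())
    if m_used == 0:
        raise KernelError(
            f"no usable polymorphic variants off chromosome {exclude_chrom!r}"
        )
    Zk = Z[:, keep]
    K = (Zk @ Zk.T) / m_used
    return 0.5 * (K + K.T), m_used


def build_loco(
    dosages: np.ndarray,
    variant_chroms: np.ndarray | list[str],
    sample_ids: list[str],
    allow_non_loco: bool = False,
) -> LocoKernels:
    """One kernel per chromosome, each from all the other chromosomes.

    With a single chromosome LOCO is impossible; ``allow_non_loco`` permits a
    whole-genome kernel instead (with a warning) so that tiny fixtures and
    single-chromosome datasets remain analysable.
    """
    variant_chroms = np.asarray(variant_chroms, dtype=object)
    chroms: list[str] = []
    for c in variant_chroms:
        if c not in chroms:
            chroms.append(c)
    if len(chroms) < 2:
        if not allow_non_loco:
            raise KernelError(
                "LOCO needs >= 2 chromosomes; pass allow_non_loco=True to use a "
                "whole-genome kernel"
            )
        warnings.warn(
            "single chromosome: using a whole-genome kernel (variants on the tested "
            "chromosome contribute to the random effect)"
        )
        K, m = compute_grm(dosages, variant_chroms, exclude_chrom=None)
        return LocoKernels(chroms, {chroms[0]: K}, {chroms[0]: m}, list(sample_ids))
    K_by: dict[str, np.ndarray] = {}
    m_by: dict[str, int] = {}
    for c in chroms:
        K_by[c], m_by[c] = compute_grm(dosages, variant_chroms, exclude_chrom=c)
    return LocoKernels(chroms, K_by, m_by, list(sample_ids))


def export_rel(K: np.ndarray, sample_ids: list[str], prefix: str | Path) -> None:
    """Write a kernel as plink2-style ``.rel`` / ``.rel.id`` text files."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(prefix.with_suffix(".rel"), K, delimiter="\t", fmt="%.10g")
    with open(str(prefix) + ".rel.id", "w") as fh:
        for s in sample_ids:
            fh.write(f"{s}\t{s}\n")


def check_psd(K: np.ndarray, tol_factor: float = 1e-8) -> None:
    """Raise KernelError unless K is symmetric PSD (to machine tolerance)."""
    if not np.allclose(K, K.T, atol=1e-10 * max(1.0, np.abs(K).max())):
        raise KernelError("kernel is not symmetric")
    w = np.linalg.eigvalsh(K)
    floor = -tol_factor * max(np.trace(K) / K.shape[0], 1.0)
    if w.min() < floor:
        raise KernelError(f"kernel has negative eigenvalue {w.min():.3e}")
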