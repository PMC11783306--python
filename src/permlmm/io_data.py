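"""Genotype, phenotype and covariate input.

Genotypes are read from VCF/BCF (via cyvcf2) or PLINK1 bed/bim/fam into a
dense samples x variants dosage matrix (alt-allele counts 0/1/2, ``nan`` for
missing calls).  Phenotypes and covariates come from tab-separated files with
a header row whose first column is the sample identifier.

Missing-data policy: samples missing the phenotype or any covariate are
excluded outright.  Genotype missingness is handled per variant: with the
default ``max_variant_missing=0`` any variant with a missing call among the
analysis samples is dropped, so no imputation ever happens; raising the cap
mean-fills the surviving missing calls and emits a prominent warning, since
one decorrelation per chromosome cannot accommodate per-variant sample sets.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ColumnNotFoundError,
    DuplicateSampleError,
    EmptyInputError,
    FormatError,
    InsufficientSamplesError,
)

__all__ = [
    "VariantRecord",
    "GenotypeData",
    "PhenoCovarTable",
    "AlignedDataset",
    "read_genotypes",
    "read_pheno_covar",
    "align_samples",
]

MISSING = np.nan  # missing-dosage marker in the n x m matrix


@dataclass(frozen=True)
class VariantRecord:
    """A single biallelic variant: 1-based position, VCF/bim conventions."""

    chromosome: str
    position: int
    id: str
    ref_allele: str
    alt_allele: str


@dataclass
class GenotypeData:
    """Samples x variants dosage matrix plus variant metadata.

    ``dosages[i, j]`` is the alt-allele count of sample ``i`` at variant
    ``j`` (0.0, 1.0, 2.0 or nan).  Variants are sorted by position within
    chromosome; chromosomes keep their order of first appearance in the
    source file (labels are taken verbatim, no "chr" normalisation).
    """

    sample_ids: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.variants):
            raise ValueError("dosage matrix shape does not match metadata")
        if len(set(self.sample_ids)) != n:
            raise DuplicateSampleError("duplicate sample IDs in genotype data")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        self._sort_variants()

    def _sort_variants(self) -> None:
        chrom_rank: dict[str, int] = {}
        for v in self.variants:
            chrom_rank.setdefault(v.chromosome, len(chrom_rank))
        order = sorted(
            range(len(self.variants)),
            key=lambda j: (chrom_rank[self.variants[j].chromosome], self.variants[j].position),
        )
        if order != list(range(len(self.variants))):
            self.variants = [self.variants[j] for j in order]
            self.dosages = self.dosages[:, order]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for v in self.variants:
            seen.setdefault(v.chromosome, None)
        return list(seen)

    def variant_chromosomes(self) -> np.ndarray:
        return np.array([v.chromosome for v in self.variants], dtype=object)


@dataclass
class PhenoCovarTable:
    """Named phenotype columns (numeric) and covariate columns per sample."""

    sample_ids: list[str]
    phenotypes: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DuplicateSampleError("duplicate sample IDs in phenotype/covariate table")


@dataclass
class AlignedDataset:
    """Samples common to genotypes and phenotypes, in genotype-file order."""

    sample_ids: list[str]
    dosages: np.ndarray
    variants: list[VariantRecord]
    y: np.ndarray
    pheno_name: str
    covariates: pd.DataFrame
    dropped_samples: list[tuple[str, str]] = field(default_factory=list)
    n_variants_dropped: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.variants:
            seen.setdefault(v.chromosome, None)
        return list(seen)

    def variant_chromosomes(self) -> np.ndarray:
        return np.array([v.chromosome for v in self.variants], dtype=object)


# ---------------------------------------------------------------------------
# genotype readers
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeData:
    """Read a VCF/BCF or PLINK1 fileset into a :class:`GenotypeData`.

    ``format="plink"`` expects ``path`` to be the bed file or the common
    prefix of ``.bed/.bim/.fam``.  Multiallelic and non-diploid records are
    rejected (multiallelic sites are skipped with a warning).
    """
    if format == "vcf":
        return _read_vcf(Path(path))
    if format == "plink":
        return _read_plink(Path(path))
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path: Path) -> GenotypeData:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise FormatError("cyvcf2 is required for VCF input") from exc
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise FormatError(f"could not parse {path} as VCF/BCF: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise EmptyInputError(f"{path}: no samples")
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gts = rec.genotype.array()  # (n, ploidy+1); last col = phased flag
        alleles = gts[:, :-1]
        if alleles.shape[1] != 2:
            raise FormatError(f"{path}: non-diploid record at {rec.CHROM}:{rec.POS}")
        col = np.where(
            (alleles < 0).any(axis=1), np.nan, (alleles > 0).sum(axis=1).astype(float)
        )
        variants.append(
            VariantRecord(
                chromosome=rec.CHROM,
                position=rec.POS,
                id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
            )
        )
        columns.append(col)
    vcf.close()
    if n_multi:
        warnings.warn(f"{path}: skipped {n_multi} multiallelic record(s)")
    if not variants:
        raise EmptyInputError(f"{path}: no usable biallelic variants")
    return GenotypeData(samples, variants, np.column_stack(columns))


_BED_MAGIC = b"\x6c\x1b\x01"  # PLINK1 bed, SNP-major
# 2-bit genotype codes -> count of the A1 allele (bim column 5)
_BED_CODE_TO_DOSAGE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}


def _plink_prefix(path: Path) -> Path:
    return path.with_suffix("") if path.suffix == ".bed" else path


def _read_plink(path: Path) -> GenotypeData:
    prefix = _plink_prefix(path)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f)
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    samples = list(fam_df.iloc[:, 1])
    bim_df = pd.read_csv(bim, sep=r"\s+", header=None, dtype=str)
    variants = [
        VariantRecord(
            chromosome=row[0],
            position=int(row[3]),
            id=row[1],
            ref_allele=row[5],  # A2 = ref, A1 = alt (counted allele)
            alt_allele=row[4],
        )
        for row in bim_df.itertuples(index=False)
    ]
    n, m = len(samples), len(variants)
    if n == 0 or m == 0:
        raise EmptyInputError(f"{prefix}: zero samples or variants")
    raw = bed.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{bed}: not a SNP-major PLINK1 bed file")
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_variant:
        raise FormatError(f"{bed}: unexpected size for {n} samples x {m} variants")
    body = body.reshape(m, bytes_per_variant)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.stack([(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1)
    codes = codes.reshape(m, -1)[:, :n]  # (m, n)
    lut = np.array([_BED_CODE_TO_DOSAGE[c] for c in range(4)])
    dosages = lut[codes].T  # (n, m)
    return GenotypeData(samples, variants, dosages)


def write_plink(g: GenotypeData, prefix: str | Path) -> None:
    """Write a PLINK1 bed/bim/fam fileset (SNP-major; A1 = alt allele)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in g.sample_ids:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for v in g.variants:
            fh.write(
                f"{v.chromosome}\t{v.id}\t0\t{v.position}\t{v.alt_allele}\t{v.ref_allele}\n"
            )
    n = g.n_samples
    code = np.full(g.dosages.shape, 0b01, dtype=np.uint8)  # missing
    code[g.dosages == 2.0] = 0b00
    code[g.dosages == 1.0] = 0b10
    code[g.dosages == 0.0] = 0b11
    pad = (-n) % 4
    if pad:
        code = np.vstack([code, np.full((pad, g.n_variants), 0b11, dtype=np.uint8)])
    code = code.T.reshape(g.n_variants, -1, 4)  # (m, bytes, 4)
    packed = (
        code[:, :, 0] | (code[:, :, 1] << 2) | (code[:, :, 2] << 4) | (code[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# phenotype / covariate tables
# ---------------------------------------------------------------------------


def read_pheno_covar(
    pheno_path: str | Path,
    covar_path: str | Path | None = None,
    pheno_name: str | None = None,
) -> PhenoCovarTable:
    """Read tab-separated phenotype (and optional covariate) files.

    First column = sample ID; ``NA`` or empty cells are missing.  Phenotype
    columns are coerced to numeric; non-numeric cells become missing.  With
    ``pheno_name`` given, only that column is kept.
    """
    pheno = pd.read_csv(pheno_path, sep="\t", dtype={0: str})
    if pheno.shape[1] < 2:
        raise FormatError(f"{pheno_path}: expected sample-ID column plus phenotype column(s)")
    ids = list(pheno.iloc[:, 0])
    if len(set(ids)) != len(ids):
        raise DuplicateSampleError(f"{pheno_path}: duplicate sample IDs")
    phen = pheno.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    if pheno_name is not None:
        if pheno_name not in phen.columns:
            raise ColumnNotFoundError(
                f"phenotype column {pheno_name!r} not in {list(phen.columns)}"
            )
        phen = phen[[pheno_name]]
    phen.index = ids

    if covar_path is None:
        covar = pd.DataFrame(index=ids)
    else:
        cv = pd.read_csv(covar_path, sep="\t", dtype={0: str})
        cids = list(cv.iloc[:, 0])
        if len(set(cids)) != len(cids):
            raise DuplicateSampleError(f"{covar_path}: duplicate sample IDs")
        covar = cv.iloc[:, 1:]
        covar.index = cids
        covar = covar.reindex(ids)  # samples absent from the covariate file -> NA
    return PhenoCovarTable(sample_ids=ids, phenotypes=phen, covariates=covar)


def align_samples(
    g: GenotypeData,
    t: PhenoCovarTable,
    pheno_name: str | None = None,
    max_variant_missing: float = 0.0,
) -> AlignedDataset:
    """Intersect samples, drop those with missing phenotype/covariates,
    apply the per-variant genotype missingness policy.

    Sample order follows the genotype file.  Variants whose missing-call
    rate among the retained samples exceeds ``max_variant_missing`` are
    excluded; with a nonzero cap the remaining missing calls are mean-filled
    (a warned deviation from the strict no-imputation default).
    """
    if pheno_name is None:
        pheno_name = t.phenotypes.columns[0]
    if pheno_name not in t.phenotypes.columns:
        raise ColumnNotFoundError(f"phenotype column {pheno_name!r} not found")
    tset = set(t.sample_ids)
    common = [s for s in g.sample_ids if s in tset]
    if len(common) < 3:
        raise InsufficientSamplesError(
            f"only {len(common)} samples shared between genotypes and phenotypes"
        )
    dropped: list[tuple[str, str]] = []
    for s in g.sample_ids:
        if s not in tset:
            dropped.append((s, "absent from phenotype/covariate table"))
    keep: list[str] = []
    for s in common:
        yv = t.phenotypes.at[s, pheno_name]
        if pd.isna(yv):
            dropped.append((s, f"missing phenotype {pheno_name!r}"))
            continue
        row = t.covariates.loc[s] if t.covariates.shape[1] else None
        if row is not None and row.isna().any():
            bad = list(row.index[row.isna()])
            dropped.append((s, f"missing covariate(s) {bad}"))
            continue
        keep.append(s)
    if len(keep) < 3:
        raise InsufficientSamplesError(
            f"only {len(keep)} samples remain after missing-data exclusion"
        )
    idx = [g.sample_ids.index(s) for s in keep]
    dos = g.dosages[idx, :].copy()
    y = t.phenotypes.loc[keep, pheno_name].to_numpy(dtype=float)
    covar = t.covariates.loc[keep].copy() if t.covariates.shape[1] else pd.DataFrame(index=keep)

    miss_rate = np.isnan(dos).mean(axis=0)
    keep_var = miss_rate <= max_variant_missing
    n_dropped_var = int((~keep_var).sum())
    dos = dos[:, keep_var]
    variants = [v for v, k in zip(g.variants, keep_var) if k]
    if dos.shape[1] == 0:
        raise EmptyInputError("no variants pass the missing-call-rate filter")
    if max_variant_missing > 0 and np.isnan(dos).any():
        warnings.warn(
            "mean-filling missing genotype calls (max_variant_missing > 0); "
            "this deviates from the strict no-imputation default"
        )
        col_mean = np.nanmean(dos, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(dos))
        dos[nan_r, nan_c] = col_mean[nan_c]
    return AlignedDataset(
        sample_ids=keep,
        dosages=dos,
        variants=variants,
        y=y,
        pheno_name=pheno_name,
        covariates=covar,
        dropped_samples=dropped,
        n_variants_dropped=n_dropped_var,
    )
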