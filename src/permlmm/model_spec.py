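"""Model formulas and design-matrix compilation.

The association model is given as a pair of formulas, e.g.::

    full:  y ~ x + x:env + sex
    null:  y ~ sex

where the special term ``x`` stands for the genotype dosage of the variant
currently being tested.  The dialect is deliberately small: an implicit
intercept (removed with ``0`` or ``-1``), ``+`` between terms, ``:`` for
elementwise interactions, and a whitelist of genotype recodes —
``dom(a) = min(a, 1)`` (dominance), ``rec(a) = max(a - 1, 0)`` (recessive),
``sq(a) = a**2``, and ``pmin(a, c)`` / ``pmax(a, c)`` with a numeric
constant.  Categorical covariates are treatment-coded against the
lexicographically first level, which keeps compilation deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import CollinearityError, ColumnNotFoundError, FormulaError, NestingError
from .io_data import AlignedDataset

__all__ = [
    "ModelPair",
    "DesignMatrix",
    "NestingReport",
    "compile_null",
    "compile_full",
    "check_nesting",
]

RANK_TOL = 1e-8

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*$")
_FUNC_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_]*)\((.*)\)$")
_WHITELIST = ("dom", "rec", "sq", "pmin", "pmax")


@dataclass(frozen=True)
class ModelPair:
    """Full model (contains ``x``) and nested null model (never does)."""

    full_formula: str
    null_formula: str

    def __post_init__(self) -> None:
        full_terms = _parse_rhs(self.full_formula)
        null_terms = _parse_rhs(self.null_formula)
        if not any(_term_uses_x(t) for t in full_terms.terms):
            raise FormulaError(f"full model {self.full_formula!r} must reference 'x'")
        if any(_term_uses_x(t) for t in null_terms.terms):
            raise FormulaError(f"null model {self.null_formula!r} must not reference 'x'")

    def genotype_terms_only_plain_x(self) -> bool:
        """True when the full model is exactly the null model plus a bare
        ``x`` main effect — the case where single-column score updates apply."""
        full = _parse_rhs(self.full_formula)
        null = _parse_rhs(self.null_formula)
        if full.intercept != null.intercept:
            return False
        extra = [t for t in full.terms if t not in null.terms]
        missing = [t for t in null.terms if t not in full.terms]
        return extra == [("x",)] and not missing


@dataclass
class DesignMatrix:
    """Compiled n x q numeric design with deterministic column order."""

    values: np.ndarray
    column_names: list[str]
    x_columns: np.ndarray = field(default=None)  # bool mask: columns involving x

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.x_columns is None:
            self.x_columns = np.zeros(self.values.shape[1], dtype=bool)

    @property
    def q(self) -> int:
        return self.values.shape[1]

    def rank(self) -> int:
        if self.values.size == 0:
            return 0
        return int(np.linalg.matrix_rank(self.values, tol=None))

    def is_full_rank(self) -> bool:
        return self.q == 0 or self.rank() == self.q


@dataclass(frozen=True)
class NestingReport:
    nested: bool
    df: int
    q_full: int
    q_null: int


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Rhs:
    intercept: bool
    terms: tuple[tuple[str, ...], ...]  # each term = tuple of factor strings


def _split_top(s: str, seps: str) -> list[str]:
    out, depth, cur = [], 0, []
    for ch in s:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormulaError(f"unbalanced parentheses in {s!r}")
        if depth == 0 and ch in seps:
            out.append("".join(cur))
            cur = [ch] if ch == "-" else []
            if ch == "-":
                cur = ["-"]
        else:
            cur.append(ch)
    if depth != 0:
        raise FormulaError(f"unbalanced parentheses in {s!r}")
    out.append("".join(cur))
    return [p for p in (p.strip() for p in out) if p]


def _parse_rhs(formula: str) -> _Rhs:
    if "~" not in formula:
        raise FormulaError(f"formula {formula!r} lacks '~'")
    _, rhs = formula.split("~", 1)
    pieces = _split_top(rhs, "+-")
    intercept = True
    terms: list[tuple[str, ...]] = []
    for piece in pieces:
        piece = piece.replace(" ", "")
        if piece in ("0", "-1"):
            intercept = False
            continue
        if piece == "1":
            continue
        if piece.startswith("-"):
            raise FormulaError(f"only '-1' may be subtracted, got {piece!r}")
        factors = tuple(f.strip() for f in _split_top(piece, ":"))
        if not all(factors):
            raise FormulaError(f"empty factor in term {piece!r}")
        if factors not in terms:  # duplicated terms collapse
            terms.append(factors)
    return _Rhs(intercept=intercept, terms=tuple(terms))


def _term_uses_x(term: tuple[str, ...]) -> bool:
    return any(_factor_uses_x(f) for f in term)


def _factor_uses_x(factor: str) -> bool:
    m = _FUNC_RE.match(factor)
    arg = m.group(2).split(",")[0].strip() if m else factor
    return arg == "x"


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _eval_factor(
    factor: str, data: AlignedDataset, x: np.ndarray | None
) -> list[tuple[str, np.ndarray]]:
    """A factor expands to one column (numeric) or several (categorical)."""
    m = _FUNC_RE.match(factor)
    if m:
        func, inner = m.group(1), m.group(2)
        if func not in _WHITELIST:
            raise FormulaError(f"function {func!r} not in whitelist {_WHITELIST}")
        args = [a.strip() for a in _split_top(inner, ",")] if inner.strip() else []
        if func in ("dom", "rec", "sq"):
            if len(args) != 1:
                raise FormulaError(f"{func}() takes one argument")
            (name,) = args
            base = _numeric_column(name, data, x)
            if func == "dom":
                vec = np.minimum(base, 1.0)
            elif func == "rec":
                vec = np.maximum(base - 1.0, 0.0)
            else:
                vec = base**2
            return [(f"{func}({name})", vec)]
        # pmin / pmax with numeric constant
        if len(args) != 2:
            raise FormulaError(f"{func}() takes (name, constant)")
        name, const_s = args
        try:
            const = float(const_s)
        except ValueError as exc:
            raise FormulaError(f"{func}() second argument must be numeric") from exc
        base = _numeric_column(name, data, x)
        vec = np.minimum(base, const) if func == "pmin" else np.maximum(base, const)
        return [(f"{func}({name},{const_s})", vec)]

    if not _NAME_RE.match(factor):
        raise FormulaError(f"cannot parse factor {factor!r}")
    if factor == "x":
        if x is None:
            raise FormulaError("'x' used but no genotype vector bound")
        return [("x", np.asarray(x, dtype=float))]
    if factor not in data.covariates.columns:
        raise ColumnNotFoundError(
            f"covariate {factor!r} not found; available: {list(data.covariates.columns)}"
        )
    col = data.covariates[factor]
    if pd.api.types.is_numeric_dtype(col):
        return [(factor, col.to_numpy(dtype=float))]
    levels = sorted(col.astype(str).unique())  # first level = reference
    vals = col.astype(str).to_numpy()
    return [(f"{factor}_{lvl}", (vals == lvl).astype(float)) for lvl in levels[1:]]


def _numeric_column(name: str, data: AlignedDataset, x: np.ndarray | None) -> np.ndarray:
    cols = _eval_factor(name, data, x)
    if len(cols) != 1:
        raise FormulaError(f"recode functions need a numeric argument, got categorical {name!r}")
    return cols[0][1]


def _compile(formula: str, data: AlignedDataset, x: np.ndarray | None) -> DesignMatrix:
    rhs = _parse_rhs(formula)
    n = data.n_samples
    names: list[str] = []
    cols: list[np.ndarray] = []
    x_mask: list[bool] = []
    if rhs.intercept:
        names.append("(Intercept)")
        cols.append(np.ones(n))
        x_mask.append(False)
    for term in rhs.terms:
        factor_cols = [_eval_factor(f, data, x) for f in term]
        uses_x = _term_uses_x(term)
        # cross product of the factors' column expansions
        combos: list[tuple[str, np.ndarray]] = factor_cols[0]
        for fc in factor_cols[1:]:
            combos = [(f"{na}:{nb}", va * vb) for na, va in combos for nb, vb in fc]
        for name, vec in combos:
            if vec.shape != (n,):
                raise FormulaError(f"column {name!r} has wrong length")
            names.append(name)
            cols.append(vec)
            x_mask.append(uses_x)
    values = np.column_stack(cols) if cols else np.empty((n, 0))
    return DesignMatrix(values=values, column_names=names, x_columns=np.array(x_mask, dtype=bool))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def compile_null(mp: ModelPair, data: AlignedDataset) -> DesignMatrix:
    """Compile the null design X0; rank deficiency is a hard error here."""
    dm = _compile(mp.null_formula, data, x=None)
    if not dm.is_full_rank():
        raise CollinearityError(
            f"null design is rank deficient; offending columns: {_dependent_columns(dm)}"
        )
    return dm


def compile_full(mp: ModelPair, data: AlignedDataset, x: np.ndarray) -> DesignMatrix:
    """Compile the full design with ``x`` bound to a dosage vector.

    Rank deficiency (monomorphic x, x collinear with a covariate) is NOT an
    error at this level: callers check :meth:`DesignMatrix.is_full_rank` and
    flag the variant as degenerate.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (data.n_samples,):
        raise ValueError(f"genotype vector has length {x.shape}, expected {data.n_samples}")
    return _compile(mp.full_formula, data, x=x)


def _dependent_columns(dm: DesignMatrix) -> list[str]:
    _, _, piv = scipy.linalg.qr(dm.values, mode="economic", pivoting=True)
    return [dm.column_names[j] for j in piv[dm.rank():]]


def check_nesting(mp: ModelPair, data: AlignedDataset, seed: int = 0) -> NestingReport:
    """Verify column-space containment of X0 in X_full on a probe genotype.

    The probe is a fixed pseudorandom continuous vector so that collinearity
    with real covariates is (almost surely) avoided; df is the rank gap.
    """
    rng = np.random.default_rng(seed)
    probe = rng.standard_normal(data.n_samples)
    x0 = compile_null(mp, data)
    xf = compile_full(mp, data, probe)
    if not xf.is_full_rank():
        raise CollinearityError("full design rank deficient on the probe genotype")
    if x0.q:
        coef, *_ = np.linalg.lstsq(xf.values, x0.values, rcond=None)
        resid = x0.values - xf.values @ coef
        rel = np.linalg.norm(resid) / max(np.linalg.norm(x0.values), 1.0)
        if rel > 1e-8:
            raise NestingError(
                f"null model {mp.null_formula!r} is not nested in {mp.full_formula!r} "
                f"(projection residual {rel:.2e})"
            )
    df = xf.q - x0.q
    if df < 1:
        raise NestingError("full model adds no degrees of freedom over the null")
    return NestingReport(nested=True, df=df, q_full=xf.q, q_null=x0.q)
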