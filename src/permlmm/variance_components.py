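"""Variance components by average-information REML.

The model is y ~ N(X0 b, sigma_g2 * K + sigma_e2 * I) with X0 the *null*
(non-genetic) design, so the components are estimated once per chromosome
and then reused for every variant on it.  K is eigendecomposed up front
(K = U D U^T); after rotating y and X0 by U^T the covariance is diagonal in
every iteration, which makes each AI/EM update O(n q^2).

Updates are Newton-type steps using the average-information matrix, with an
EM-REML step first (and as a fallback whenever an AI step proposes an
out-of-bounds or likelihood-decreasing move), so the restricted
log-likelihood is non-decreasing across accepted iterations.  When the AI
matrix is numerically singular — e.g. K = I, where only sigma_g2 + sigma_e2
is identified — the variance ratio lambda = sigma_g2/sigma_e2 is profiled on
a log grid instead, ties resolved toward the smallest ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import DegeneratePhenotypeError, KernelError
from .grm import LocoKernels
from .io_data import AlignedDataset
from .model_spec import DesignMatrix

__all__ = ["VarianceComponents", "fit_aireml", "fit_per_chromosome", "restricted_loglik"]

FLOOR_FACTOR = 1e-6  # components constrained >= FLOOR_FACTOR * Var(y)
TOL_PARAM = 1e-6
TOL_LOGLIK = 1e-8
MAX_ITER = 100


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float
    n_iter: int
    converged: bool
    floored: bool = False
    loglik_path: list[float] = field(default_factory=list)


class _RotatedProblem:
    """K-eigenbasis representation: covariance diagonal w = sg*d + se."""

    def __init__(self, y: np.ndarray, X: np.ndarray, K: np.ndarray):
        n = y.shape[0]
        if K.shape != (n, n):
            raise KernelError(f"kernel shape {K.shape} does not match n={n}")
        if not np.allclose(K, K.T, atol=1e-8 * max(1.0, np.abs(K).max())):
            raise KernelError("kernel is not symmetric")
        d, U = np.linalg.eigh(K)
        if d.min() < -1e-8 * max(np.trace(K) / n, 1.0):
            raise KernelError(f"kernel is not PSD (min eigenvalue {d.min():.3e})")
        self.d = np.clip(d, 0.0, None)
        self.yt = U.T @ y
        self.Xt = U.T @ X
        self.n = n
        self.q = X.shape[1]

    def quantities(self, sg: float, se: float) -> dict:
        """Restricted log-likelihood, P*y, and trace machinery at (sg, se)."""
        w = sg * self.d + se
        winv = 1.0 / w
        Wx = self.Xt * winv[:, None]
        M = self.Xt.T @ Wx
        cho = scipy.linalg.cho_factor(M, lower=True)
        logdet_M = 2.0 * np.sum(np.log(np.diag(cho[0])))
        beta = scipy.linalg.cho_solve(cho, Wx.T @ self.yt)
        Py = winv * (self.yt - self.Xt @ beta)
        yPy = float(self.yt @ Py)
        ll = -0.5 * (
            (self.n - self.q) * np.log(2.0 * np.pi)
            + np.sum(np.log(w))
            + logdet_M
            + yPy
        )
        return {"w": w, "winv": winv, "Wx": Wx, "cho": cho, "Py": Py, "yPy": yPy, "ll": ll}

    def apply_P(self, qty: dict, a: np.ndarray) -> np.ndarray:
        return qty["winv"] * a - qty["Wx"] @ scipy.linalg.cho_solve(qty["cho"], qty["Wx"].T @ a)

    def trace_PV(self, qty: dict, v: np.ndarray) -> float:
        # tr(P V) for diagonal V (entries v)
        t1 = float(np.sum(v * qty["winv"]))
        B = qty["Wx"].T @ (v[:, None] * qty["Wx"])
        t2 = float(np.trace(scipy.linalg.cho_solve(qty["cho"], B)))
        return t1 - t2

    def score(self, qty: dict) -> np.ndarray:
        """REML score vector d ll / d (sg, se)."""
        Py = qty["Py"]
        out = np.empty(2)
        for i, v in enumerate((self.d, np.ones(self.n))):
            out[i] = -0.5 * (self.trace_PV(qty, v) - float(Py @ (v * Py)))
        return out

    def ai_matrix(self, qty: dict) -> np.ndarray:
        Py = qty["Py"]
        a = [self.d * Py, Py]
        AI = np.empty((2, 2))
        for i in range(2):
            Pai = self.apply_P(qty, a[i])
            for j in range(i, 2):
                AI[i, j] = AI[j, i] = 0.5 * float(a[j] @ Pai)
        return AI


def fit_aireml(
    y: np.ndarray,
    X0: DesignMatrix | np.ndarray,
    K: np.ndarray,
    tol_param: float = TOL_PARAM,
    tol_loglik: float = TOL_LOGLIK,
    max_iter: int = MAX_ITER,
) -> VarianceComponents:
    """Estimate (sigma_g2, sigma_e2) by AI-REML under the null design."""
    y = np.asarray(y, dtype=float)
    X = X0.values if isinstance(X0, DesignMatrix) else np.asarray(X0, dtype=float)
    n, q = X.shape
    if n <= q + 1:
        raise ValueError(f"need n > q + 1 (n={n}, q={q})")
    vary = float(np.var(y, ddof=1))
    if vary <= 0.0:
        raise DegeneratePhenotypeError("phenotype has zero variance")
    floor = FLOOR_FACTOR * vary
    rp = _RotatedProblem(y, X, K)

    theta = np.array([vary / 2.0, vary / 2.0])
    qty = rp.quantities(*theta)
    path = [qty["ll"]]
    floored = False
    converged = False
    n_iter = 0

    def em_step(theta: np.ndarray, qty: dict) -> np.ndarray:
        prop = theta.copy()
        for i, v in enumerate((rp.d, np.ones(rp.n))):
            Py = qty["Py"]
            grad_part = float(Py @ (v * Py)) - rp.trace_PV(qty, v)
            prop[i] = theta[i] + theta[i] ** 2 * grad_part / rp.n
        return np.maximum(prop, floor)

    def try_accept(prop: np.ndarray, qty: dict):
        """Return (theta, qty) if prop does not decrease the loglik, else None."""
        q_new = rp.quantities(*prop)
        if q_new["ll"] >= qty["ll"] - 1e-10:
            return prop, q_new
        return None

    for n_iter in range(1, max_iter + 1):
        if n_iter == 1:
            prop = em_step(theta, qty)  # one EM step first, for stability
        else:
            AI = rp.ai_matrix(qty)
            if np.linalg.cond(AI) > 1e8:
                lam_fit = _profile_lambda(rp, floor)
                lam_fit.n_iter = n_iter
                lam_fit.loglik_path = path + [lam_fit.loglik]
                return lam_fit
            step = np.linalg.solve(AI, rp.score(qty))
            prop = theta + step
            if (prop < floor).any():
                prop = em_step(theta, qty)  # AI step out of bounds -> EM fallback
            else:
                acc = try_accept(prop, qty)
                if acc is None:
                    prop = em_step(theta, qty)  # AI step decreased loglik -> EM

        accepted = try_accept(prop, qty)
        shrink = 0
        while accepted is None and shrink < 30:
            prop = theta + 0.5 * (prop - theta)
            accepted = try_accept(np.maximum(prop, floor), qty)
            shrink += 1
        if accepted is None:
            converged = True  # no improving move exists
            break
        new_theta, new_qty = accepted
        dll = new_qty["ll"] - qty["ll"]
        rel = np.max(np.abs(new_theta - theta) / np.maximum(np.abs(theta), floor))
        theta, qty = new_theta, new_qty
        path.append(qty["ll"])
        if rel < tol_param and abs(dll) < tol_loglik:
            converged = True
            break

    floored = bool((theta <= floor * (1 + 1e-12)).any())
    sg, se = float(theta[0]), float(theta[1])
    return VarianceComponents(
        sigma_g2=sg,
        sigma_e2=se,
        h2=sg / (sg + se),
        loglik=float(qty["ll"]),
        n_iter=n_iter,
        converged=converged,
        floored=floored,
        loglik_path=path,
    )


def _profile_lambda(rp: _RotatedProblem, floor: float) -> VarianceComponents:
    """Profile the ratio lambda = sg/se on a log grid (AI-singular fallback).

    For fixed lambda the REML-optimal sigma_e2 has a closed form; the grid
    optimum is reported, with ties broken toward the smallest lambda so the
    unidentified K = I case resolves to the boundary sigma_g2 -> 0.
    """
    n, q = rp.n, rp.q
    lams = np.concatenate([[0.0], np.logspace(-8, 6, 57)])
    best = None
    for lam in lams:
        w = lam * rp.d + 1.0
        winv = 1.0 / w
        Wx = rp.Xt * winv[:, None]
        M = rp.Xt.T @ Wx
        cho = scipy.linalg.cho_factor(M, lower=True)
        beta = scipy.linalg.cho_solve(cho, Wx.T @ rp.yt)
        resid = rp.yt - rp.Xt @ beta
        yPy = float(rp.yt @ (winv * resid))
        se = max(yPy / (n - q), floor)
        ll = -0.5 * (
            (n - q) * np.log(2.0 * np.pi)
            + (n - q) * np.log(se)
            + np.sum(np.log(w))
            + 2.0 * np.sum(np.log(np.diag(cho[0])))
            + (n - q)
        )
        if best is None or ll > best[0] + 1e-9 * (1.0 + abs(best[0])):
            best = (ll, lam, se)
    ll, lam, se = best
    sg = lam * se  # exactly lam * se so sums stay consistent (0 at the boundary)
    return VarianceComponents(
        sigma_g2=float(sg),
        sigma_e2=float(se),
        h2=float(sg / (sg + se)),
        loglik=float(ll),
        n_iter=0,
        converged=True,
        floored=lam == 0.0,
    )


def restricted_loglik(
    y: np.ndarray, X0: DesignMatrix | np.ndarray, K: np.ndarray, sigma_g2: float, sigma_e2: float
) -> float:
    """Restricted log-likelihood at given components (for diagnostics/tests)."""
    X = X0.values if isinstance(X0, DesignMatrix) else np.asarray(X0, dtype=float)
    rp = _RotatedProblem(np.asarray(y, dtype=float), X, K)
    return float(rp.quantities(sigma_g2, sigma_e2)["ll"])


def reml_score(
    y: np.ndarray, X0: DesignMatrix | np.ndarray, K: np.ndarray, sigma_g2: float, sigma_e2: float
) -> np.ndarray:
    """REML score (gradient) at given components (for diagnostics/tests)."""
    X = X0.values if isinstance(X0, DesignMatrix) else np.asarray(X0, dtype=float)
    rp = _RotatedProblem(np.asarray(y, dtype=float), X, K)
    return rp.score(rp.quantities(sigma_g2, sigma_e2))


def fit_per_chromosome(
    data: AlignedDataset,
    X0: DesignMatrix,
    loco: LocoKernels,
    **fit_kwargs,
) -> dict[str, VarianceComponents]:
    """One independent REML fit per chromosome, against its LOCO kernel."""
    return {
        chrom: fit_aireml(data.y, X0, loco[chrom], **fit_kwargs)
        for chrom in loco.chromosomes
    }
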