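"""Restricted maximum likelihood for the two-component GBLUP model.

Model: y = X b + u + e with u ~ N(0, G sigma_u2) and e ~ N(0, I sigma_e2).
G is eigendecomposed once (G = U D U'); rotating y and X by U' makes the
phenotypic covariance diagonal, so every REML iteration is O(n p^2) after
the one-off O(n^3) decomposition. Updates are average-information (AI)
steps with a monotone safeguard: a proposal that leaves the parameter
space or decreases the restricted likelihood is replaced by a fixed-point
(EM-style) step, then by halved AI steps.

Standard errors come from the inverse AI matrix at the optimum; the h2
standard error is obtained by the delta method.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh

from .grm import GRMatrix


@dataclass
class VarianceComponents:
    sigma_u2: float
    sigma_e2: float
    h2: float
    se_sigma_u2: float
    se_sigma_e2: float
    se_h2: float
    n_iterations: int
    converged: bool
    log_likelihood: float
    boundary: bool = False
    loglik_path: list = field(default_factory=list, repr=False)

    @property
    def phenotypic_variance(self) -> float:
        return self.sigma_u2 + self.sigma_e2

    @property
    def lambda_(self) -> float:
        """Shrinkage ratio sigma_e2 / sigma_u2 used by the MME."""
        return self.sigma_e2 / self.sigma_u2


def heritability(sigma_u2: float, sigma_e2: float) -> tuple[float, float]:
    """Return (h2, V_P) = (sigma_u2 / (sigma_u2 + sigma_e2), sigma_u2 + sigma_e2)."""
    if sigma_u2 < 0 or sigma_e2 <= 0:
        if sigma_u2 == 0 and sigma_e2 == 0:
            raise ValueError("both variance components are zero")
        if sigma_e2 <= 0:
            raise ValueError("residual variance must be positive")
    vp = sigma_u2 + sigma_e2
    return sigma_u2 / vp, vp


def design_matrix(cg: "pd.Series | np.ndarray | None", n: int | None = None) -> np.ndarray:
    """Intercept plus full-rank dummy coding of the contemporary-group
    factor (first level, in sorted order, is the reference)."""
    if cg is None:
        if n is None:
            raise ValueError("n required when cg is None")
        return np.ones((n, 1))
    cg = pd.Series(np.asarray(cg, dtype=object))
    levels = sorted(cg.unique(), key=str)
    X = np.ones((len(cg), len(levels)), dtype=np.float64)
    for j, lev in enumerate(levels[1:], start=1):
        X[:, j] = (cg == lev).to_numpy(dtype=np.float64)
    return X


class _Profile:
    """Likelihood quantities at (sigma_u2, sigma_e2) in the rotated basis."""

    __slots__ = ("v", "B", "L", "Py", "diagP", "loglik")

    def __init__(self, ystar, Xstar, d, su, se):
        v = su * d + se
        if np.any(v <= 0):
            raise FloatingPointError("non-positive marginal variance")
        B = Xstar / v[:, None]
        XtViX = Xstar.T @ B
        L = cho_factor(XtViX)
        c = cho_solve(L, B.T @ ystar)
        Py = ystar / v - B @ c
        Binv = cho_solve(L, B.T).T  # B @ XtViX^{-1}
        diagP = 1.0 / v - np.einsum("ij,ij->i", Binv, B)
        logdet_xvx = 2.0 * np.sum(np.log(np.diag(L[0])))
        self.v, self.B, self.L, self.Py, self.diagP = v, B, L, Py, diagP
        self.loglik = -0.5 * (np.sum(np.log(v)) + logdet_xvx + float(ystar @ Py))

    def applyP(self, w):
        return w / self.v - self.B @ cho_solve(self.L, self.B.T @ w)


def _loglik_only(ystar, Xstar, d, su, se) -> float:
    try:
        return _Profile(ystar, Xstar, d, su, se).loglik
    except (FloatingPointError, np.linalg.LinAlgError):
        return -np.inf


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    Gm: "GRMatrix | np.ndarray",
    tol: float = 1e-8,
    grad_tol: float = 1e-6,
    max_iter: int = 200,
) -> VarianceComponents:
    """AI-REML estimate of (sigma_u2, sigma_e2) for y = Xb + u + e.

    Convergence: relative change of each component < ``tol`` or AI gradient
    norm < ``grad_tol``. A sigma_u2 proposal below 1e-8 * Var(y) is pinned
    at that floor; persisting there sets the boundary flag and h2 ~ 0.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    X = np.asarray(X, dtype=np.float64)
    G = Gm.values if isinstance(Gm, GRMatrix) else np.asarray(Gm, dtype=np.float64)
    n = y.size
    if X.ndim != 2 or X.shape[0] != n or G.shape != (n, n):
        raise ValueError("y, X and G dimensions are not aligned")
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design X is rank deficient")
    if n <= p + 1:
        raise ValueError("need n > rank(X) + 1 records")

    d, U = eigh(G)
    d = np.clip(d, 0.0, None)
    ystar = U.T @ y
    Xstar = U.T @ X

    # initial values from the OLS residual variance, split evenly
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    s2 = float(np.sum((y - X @ beta) ** 2) / max(n - p, 1))
    su, se = 0.5 * s2, 0.5 * s2
    floor = 1e-8 * max(np.var(y), np.finfo(float).tiny)

    prof = _Profile(ystar, Xstar, d, su, se)
    path = [prof.loglik]
    converged = False
    boundary = False
    it = 0
    AI = np.eye(2)
    pinned_prev = False
    for it in range(1, max_iter + 1):
        Py = prof.Py
        dPy = d * Py
        trPG = float(np.sum(d * prof.diagP))
        trP = float(np.sum(prof.diagP))
        yPGPy = float(Py @ dPy)
        yPPy = float(Py @ Py)
        score = np.array([-0.5 * (trPG - yPGPy), -0.5 * (trP - yPPy)])

        tu = prof.applyP(dPy)
        te = prof.applyP(Py)
        AI = 0.5 * np.array(
            [[float(dPy @ tu), float(dPy @ te)], [float(dPy @ te), float(Py @ te)]]
        )

        if np.linalg.norm(score) < grad_tol:
            converged = True
            break

        theta = np.array([su, se])
        candidates = []
        try:
            step = np.linalg.solve(AI, score)
            candidates.append(theta + step)
            candidates.append(theta + 0.5 * step)
            candidates.append(theta + 0.1 * step)
        except np.linalg.LinAlgError:
            pass
        # EM-style fixed-point fallback (positive by construction)
        em = np.array(
            [
                su * yPGPy / trPG if trPG > 0 else su,
                se * yPPy / trP if trP > 0 else se,
            ]
        )
        candidates.append(em)

        accepted = None
        for cand in candidates:
            cu, ce = float(cand[0]), float(cand[1])
            cu = max(cu, floor)
            ce = max(ce, floor)
            ll = _loglik_only(ystar, Xstar, d, cu, ce)
            if ll >= path[-1] - 1e-10:
                accepted = (cu, ce, ll)
                break
        if accepted is None:
            # no candidate improves: treat as converged at current point
            converged = True
            break

        su_new, se_new, ll = accepted
        rel = max(
            abs(su_new - su) / max(su, floor),
            abs(se_new - se) / max(se, floor),
        )
        su, se = su_new, se_new
        prof = _Profile(ystar, Xstar, d, su, se)
        path.append(prof.loglik)

        pinned = su <= floor * (1 + 1e-12)
        if pinned and pinned_prev:
            boundary = True
            converged = True
            break
        pinned_prev = pinned
        if rel < tol:
            converged = True
            break

    # standard errors from the inverse AI matrix at the optimum
    try:
        cov = np.linalg.inv(AI)
        se_su = float(np.sqrt(max(cov[0, 0], 0.0)))
        se_se = float(np.sqrt(max(cov[1, 1], 0.0)))
        vp = su + se
        grad = np.array([se / vp**2, -su / vp**2])
        se_h2 = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate AI
        se_su = se_se = se_h2 = float("nan")

    h2, _ = heritability(su, se)
    if boundary:
        h2 = 0.0
    return VarianceComponents(
        sigma_u2=float(su),
        sigma_e2=float(se),
        h2=float(h2),
        se_sigma_u2=se_su,
        se_sigma_e2=se_se,
        se_h2=se_h2,
        n_iterations=it,
        converged=converged,
        log_likelihood=float(prof.loglik),
        boundary=boundary,
        loglik_path=path,
    )


def varcomp_report(vcs: "dict[str, VarianceComponents]") -> pd.DataFrame:
    """Variance-component summary table (one row per trait)."""
    rows = []
    for trait, vc in vcs.items():
        rows.append(
            {
                "trait": trait,
                "V_G": vc.sigma_u2,
                "se_V_G": vc.se_sigma_u2,
                "V_e": vc.sigma_e2,
                "se_V_e": vc.se_sigma_e2,
                "V_P": vc.phenotypic_variance,
                "h2": vc.h2,
                "se_h2": vc.se_h2,
                "n_iterations": vc.n_iterations,
                "converged": vc.converged,
                "log_likelihood": vc.log_likelihood,
            }
        )
    return pd.DataFrame(rows)
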