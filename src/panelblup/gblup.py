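"""GBLUP mixed-model equations, SNP-effect backsolving and GEBV prediction.

Henderson's equations with Z = I on the phenotyped training animals:

    [ X'X      X'     ] [b]   [X'y]
    [ X    I + G^-1 l ] [u] = [y  ]      l = sigma_e2 / sigma_u2

Per-SNP effects are recovered from the GEBVs by the linear backsolve
a = (1/k) M' G^-1 u (equal prior SNP weights), with M the 2p-centered
training dosage matrix and k the VanRaden scale; with an unregularized
full-rank G this is exactly the ridge (SNP-BLUP) solution with penalty
k*l. GWAS p-values use the backsolving transform applied to
Var(u_hat) = sigma_u2 G - C22 (C22 = u-block of the MME inverse times
sigma_e2), giving a two-sided normal test per SNP.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin

from .genotypes import MISSING, GenotypeMatrix
from .grm import GRMatrix, allele_frequencies, centered_dosages, regularize_grm, vanraden_grm
from .reml import VarianceComponents, design_matrix, reml_fit

_LOG10 = np.log(10.0)


@dataclass
class GBLUPFit:
    """Solutions of one GBLUP training run."""

    b: np.ndarray  # fixed-effect solutions (intercept + CG contrasts)
    u: np.ndarray  # GEBV per training animal
    lambda_: float
    freqs: np.ndarray  # training allele frequencies (panel order)
    scale_k: float
    animal_ids: np.ndarray
    snp_ids: np.ndarray | None = None
    snp_effects: np.ndarray | None = None
    snp_se: np.ndarray | None = None
    snp_pvalues: np.ndarray | None = None
    snp_neglog10p: np.ndarray | None = None
    snp_var_warning: np.ndarray | None = None
    _X: np.ndarray = field(default=None, repr=False)
    _y: np.ndarray = field(default=None, repr=False)

    def solutions_table(self, snp_map: pd.DataFrame) -> pd.DataFrame:
        """SNP-solution export: id, chrom, bp, effect, se, p, -log10 p."""
        return pd.DataFrame(
            {
                "snp_id": snp_map["snp_id"].to_numpy(),
                "chrom": snp_map["chrom"].to_numpy(),
                "pos": snp_map["pos"].to_numpy(),
                "effect": self.snp_effects,
                "se": self.snp_se,
                "pvalue": self.snp_pvalues,
                "neglog10p": self.snp_neglog10p,
            }
        )


def _mme_matrix(X: np.ndarray, Ginv: np.ndarray, lam: float) -> np.ndarray:
    n, p = X.shape
    C = np.empty((p + n, p + n))
    C[:p, :p] = X.T @ X
    C[:p, p:] = X.T
    C[p:, :p] = X
    C[p:, p:] = np.eye(n) + lam * Ginv
    return C


def solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    Gm: GRMatrix,
    vc: VarianceComponents,
) -> GBLUPFit:
    """Solve Henderson's mixed-model equations for (b, u)."""
    y = np.asarray(y, dtype=np.float64).ravel()
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    if y.size != n or Gm.n != n:
        raise ValueError("y, X and G dimensions are not aligned")
    if vc.sigma_u2 <= 0:
        raise ValueError("sigma_u2 must be positive to form lambda")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the aliased columns for the caller
        _, R = np.linalg.qr(X)
        aliased = [j for j in range(p) if abs(R[j, j]) < 1e-10 * abs(R[0, 0])]
        raise ValueError(f"rank-deficient fixed-effect design; aliased columns: {aliased}")

    lam = vc.sigma_e2 / vc.sigma_u2
    Gc = cho_factor(Gm.values)
    Ginv = cho_solve(Gc, np.eye(n))
    C = _mme_matrix(X, Ginv, lam)
    rhs = np.concatenate([X.T @ y, y])
    sol = np.linalg.solve(C, rhs)
    return GBLUPFit(
        b=sol[:p],
        u=sol[p:],
        lambda_=lam,
        freqs=Gm.freqs.copy(),
        scale_k=Gm.scale_k,
        animal_ids=Gm.animal_ids.copy(),
        _X=X,
        _y=y,
    )


def backsolve_snp_effects(fit: GBLUPFit, G: GenotypeMatrix, Gm: GRMatrix) -> np.ndarray:
    """a_hat = (1/k) M' G^-1 u with M centered by the training frequencies."""
    if G.n_animals != Gm.n:
        raise ValueError("genotypes and GRM must cover the same animals")
    M = centered_dosages(G, Gm.freqs)
    Ginv_u = cho_solve(cho_factor(Gm.values), fit.u)
    ahat = (M.T @ Ginv_u) / Gm.scale_k
    fit.snp_effects = ahat
    fit.snp_ids = G.snp_ids.copy()
    return ahat


def snp_pvalues(
    fit: GBLUPFit,
    G: GenotypeMatrix,
    Gm: GRMatrix,
    vc: VarianceComponents,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (se, p, -log10 p) for the backsolved effects.

    var(a_j) = (1/k^2) m_j' G^-1 Var(u_hat) G^-1 m_j with
    Var(u_hat) = sigma_u2 G - sigma_e2 C22. Non-positive variances (numerical
    error) yield p = 1 with a per-SNP warning flag.
    """
    if fit.snp_effects is None:
        backsolve_snp_effects(fit, G, Gm)
    n = Gm.n
    X = fit._X
    p_fixed = X.shape[1]
    Gc = cho_factor(Gm.values)
    Ginv = cho_solve(Gc, np.eye(n))
    C = _mme_matrix(X, Ginv, fit.lambda_)
    Cinv = np.linalg.inv(C)
    C22 = Cinv[p_fixed:, p_fixed:] * vc.sigma_e2
    var_u = vc.sigma_u2 * Gm.values - C22

    M = centered_dosages(G, Gm.freqs)
    # T = G^-1 Var(u_hat) G^-1 applied through two triangular solves
    W = cho_solve(Gc, var_u)
    T = cho_solve(Gc, W.T).T
    TM = T @ M
    var_a = np.einsum("ij,ij->j", M, TM) / Gm.scale_k**2

    warn = var_a <= 0
    if warn.any():
        warnings.warn(f"{int(warn.sum())} SNP(s) with non-positive effect variance; p set to 1")
    se = np.sqrt(np.where(warn, np.nan, var_a))
    z = np.zeros_like(var_a)
    np.divide(np.abs(fit.snp_effects), se, out=z, where=~warn)
    # numerically stable two-sided normal tail
    logp = np.log(2.0) + norm.logsf(z)
    neglog10p = np.where(warn, 0.0, -logp / _LOG10)
    pvals = np.where(warn, 1.0, np.minimum(np.exp(logp), 1.0))
    pvals = np.maximum(pvals, 1e-300)
    fit.snp_se = se
    fit.snp_pvalues = pvals
    fit.snp_neglog10p = neglog10p
    fit.snp_var_warning = warn
    return se, pvals, neglog10p


# ---------------------------------------------------------------------------
# Prediction for new animals
# ---------------------------------------------------------------------------

def orient_dosages(
    panel: pd.DataFrame,
    G_new: GenotypeMatrix,
) -> np.ndarray:
    """Extract the panel columns from ``G_new`` matched by (id, allele pair).

    ``panel`` needs columns snp_id, a1, a2 (training orientation). Swapped
    allele pairs are flipped (dosage <- 2 - dosage); any other mismatch is
    rejected. Missing calls stay :data:`MISSING`.
    """
    idx = pd.Index(G_new.snp_map["snp_id"])
    locs = idx.get_indexer(panel["snp_id"])
    absent = panel["snp_id"].to_numpy()[locs < 0]
    if absent.size:
        raise KeyError(f"panel SNPs absent from new genotypes: {list(absent[:5])}")
    sub = G_new.snp_map.iloc[locs]
    same = (sub["a1"].to_numpy() == panel["a1"].to_numpy()) & (
        sub["a2"].to_numpy() == panel["a2"].to_numpy()
    )
    flipped = (sub["a1"].to_numpy() == panel["a2"].to_numpy()) & (
        sub["a2"].to_numpy() == panel["a1"].to_numpy()
    )
    bad = ~(same | flipped)
    if bad.any():
        raise ValueError(
            f"allele mismatch beyond swap for SNPs: {list(panel['snp_id'].to_numpy()[bad][:5])}"
        )
    d = G_new.dosages[:, locs].astype(np.int8)
    if flipped.any():
        cols = np.nonzero(flipped)[0]
        block = d[:, cols]
        obs = block != MISSING
        block[obs] = 2 - block[obs]
        d[:, cols] = block
    return d


def predict_gebv(
    snp_effects: np.ndarray,
    freqs: np.ndarray,
    G_new: GenotypeMatrix,
    panel: pd.DataFrame | None = None,
) -> np.ndarray:
    """GEBV_i = sum_j (x_ij - 2 p_j) a_j over panel SNPs.

    ``freqs`` are TRAINING allele frequencies. Missing dosages are imputed
    to 2p (zero contribution). When ``panel`` (snp_id, a1, a2) is given the
    columns of ``G_new`` are matched by id with allele-swap handling;
    otherwise ``G_new`` must already be in panel order.
    """
    snp_effects = np.asarray(snp_effects, dtype=np.float64)
    freqs = np.asarray(freqs, dtype=np.float64)
    if panel is not None:
        d = orient_dosages(panel, G_new)
    else:
        if G_new.n_snps != snp_effects.size:
            raise ValueError("G_new column count does not match effects")
        d = G_new.dosages
    Xc = d.astype(np.float64) - 2.0 * freqs[None, :]
    Xc[d == MISSING] = 0.0
    return Xc @ snp_effects


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class GBLUP(BaseEstimator, RegressorMixin):
    """Genomic BLUP regressor over SNP dosage matrices.

    ``fit(X, y, cg=...)`` builds the VanRaden GRM from the training dosages,
    estimates variance components by AI-REML (unless fixed via
    ``variance_components``), solves the mixed-model equations and
    backsolves per-SNP effects; ``predict(X)`` applies those effects to
    2p-centered dosages of new animals using the training frequencies.

    Parameters
    ----------
    blend_weight : identity blend for the GRM (positive definiteness).
    variance_components : optional (sigma_u2, sigma_e2) tuple to skip REML.
    compute_pvalues : also compute backsolved GWAS p-values at fit time.
    """

    def __init__(
        self,
        blend_weight: float = 0.01,
        variance_components: tuple[float, float] | None = None,
        compute_pvalues: bool = False,
        max_iter: int = 200,
        tol: float = 1e-8,
    ):
        self.blend_weight = blend_weight
        self.variance_components = variance_components
        self.compute_pvalues = compute_pvalues
        self.max_iter = max_iter
        self.tol = tol

    @staticmethod
    def _as_genotypes(X) -> GenotypeMatrix:
        if isinstance(X, GenotypeMatrix):
            return X
        X = np.asarray(X)
        n, m = X.shape
        snp_map = pd.DataFrame(
            {
                "snp_id": [f"snp{j}" for j in range(m)],
                "chrom": "1",
                "pos": np.arange(1, m + 1),
                "a1": "A",
                "a2": "B",
            }
        )
        return GenotypeMatrix(X.astype(np.int8), snp_map, np.array([f"a{i}" for i in range(n)], dtype=object))

    def fit(self, X, y, cg=None):
        G = self._as_genotypes(X)
        y = np.asarray(y, dtype=np.float64).ravel()
        if y.size != G.n_animals:
            raise ValueError("y length does not match the number of animals")
        Xd = design_matrix(cg, n=G.n_animals)
        freqs = allele_frequencies(G)
        Gm = regularize_grm(vanraden_grm(G, freqs), self.blend_weight)
        if self.variance_components is not None:
            su, se = self.variance_components
            vc = VarianceComponents(
                sigma_u2=su, sigma_e2=se, h2=su / (su + se),
                se_sigma_u2=float("nan"), se_sigma_e2=float("nan"), se_h2=float("nan"),
                n_iterations=0, converged=True, log_likelihood=float("nan"),
            )
        else:
            vc = reml_fit(y, Xd, Gm, tol=self.tol, max_iter=self.max_iter)
        fit = solve_mme(y, Xd, Gm, vc)
        backsolve_snp_effects(fit, G, Gm)
        if self.compute_pvalues:
            snp_pvalues(fit, G, Gm, vc)

        self.vc_ = vc
        self.sigma_u2_, self.sigma_e2_, self.h2_ = vc.sigma_u2, vc.sigma_e2, vc.h2
        self.lambda_ = fit.lambda_
        self.b_ = fit.b
        self.u_ = fit.u
        self.freqs_ = freqs
        self.snp_effects_ = fit.snp_effects
        self.snp_pvalues_ = fit.snp_pvalues
        self.snp_neglog10p_ = fit.snp_neglog10p
        self.panel_ = G.snp_map[["snp_id", "a1", "a2"]].copy()
        self.fit_ = fit
        self.grm_ = Gm
        self.n_features_in_ = G.n_snps
        return self

    def predict(self, X):
        if not hasattr(self, "snp_effects_"):
            raise AttributeError("GBLUP instance is not fitted yet")
        if isinstance(X, GenotypeMatrix):
            return predict_gebv(self.snp_effects_, self.freqs_, X, panel=self.panel_)
        return predict_gebv(self.snp_effects_, self.freqs_, self._as_genotypes(X))
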