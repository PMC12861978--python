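"""Single-marker (marker-assisted) prediction comparator.

y = Xb + g*SNP + e: ordinary least squares with contemporary-group
dummies and the genotype dosage (0/1/2) of one selected marker as a
covariate; g is the allelic substitution effect. Predictions for new
animals are g times their dosage at that marker.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .genotypes import MISSING
from .reml import design_matrix


@dataclass
class MASModel:
    snp_id: str | None
    effect: float  # allelic substitution effect g (trait units per allele)
    se: float
    fixed_effects: np.ndarray
    residual_variance: float
    n: int
    train_mean_dosage: float  # imputation value for missing dosages


def mas_fit(y, cg, dosage, snp_id: str | None = None) -> MASModel:
    """OLS fit of phenotype on CG dummies plus one marker dosage."""
    y = np.asarray(y, dtype=np.float64).ravel()
    dosage = np.asarray(dosage, dtype=np.float64).ravel()
    if y.size != dosage.size:
        raise ValueError("y and dosage lengths differ")
    obs = dosage != MISSING
    mean_dos = float(dosage[obs].mean()) if obs.any() else 0.0
    x = np.where(obs, dosage, mean_dos)
    if np.ptp(x) == 0:
        raise ValueError("marker is monomorphic in the training data")

    Xf = design_matrix(cg, n=y.size)
    # aliasing check: dosage must not be confounded with the CG structure
    coef, *_ = np.linalg.lstsq(Xf, x, rcond=None)
    resid_x = x - Xf @ coef
    if float(resid_x @ resid_x) < 1e-10 * float(x @ x):
        raise ValueError("marker dosage is aliased with a contemporary-group level")

    X = np.column_stack([Xf, x])
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = float(resid @ resid) / max(n - p, 1)
    XtX_inv = np.linalg.pinv(X.T @ X)
    se_g = float(np.sqrt(s2 * XtX_inv[-1, -1]))
    return MASModel(
        snp_id=snp_id,
        effect=float(beta[-1]),
        se=se_g,
        fixed_effects=beta[:-1],
        residual_variance=s2,
        n=n,
        train_mean_dosage=mean_dos,
    )


def mas_predict(model: MASModel, dosage) -> np.ndarray:
    """g x dosage for new animals (missing dosage imputed to the training
    mean); the fixed-effect part is deliberately not carried over."""
    dosage = np.asarray(dosage, dtype=np.float64).ravel()
    x = np.where(dosage == MISSING, model.train_mean_dosage, dosage)
    return model.effect * x


class MASRegressor(BaseEstimator, RegressorMixin):
    """Estimator facade over :func:`mas_fit` for a single-column dosage X."""

    def fit(self, X, y, cg=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("MASRegressor expects a single marker column")
            X = X[:, 0]
        self.model_ = mas_fit(y, cg, X)
        self.effect_ = self.model_.effect
        self.se_ = self.model_.se
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[:, 0]
        return mas_predict(self.model_, X)
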