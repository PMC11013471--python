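"""Ridge-regression BLUP: REML variance components, marker effects, GEBVs.

Model
-----
    y = 1*mu + Xc*u + e,    u ~ N(0, var_u * I_m),   e ~ N(0, var_e * I_t)

with Xc the per-marker mean-centered dosage matrix of the training set.  The
ridge parameter is lambda = var_e / var_u.  The marker-effect BLUP is

    beta = Xc' (Xc Xc' + lambda I)^-1 (y - mu 1)
         = (Xc' Xc + lambda I)^-1 Xc' (y - mu 1)

(the two forms are algebraically identical; the kernel (t x t) form is used
when m > t, the ridge (m x m) form otherwise).  The intercept is the
generalized-least-squares mean under V = Xc Xc' + lambda I.  REML estimates
the single variance ratio by maximizing the restricted likelihood of the
data projected orthogonally to the intercept, using the spectral
decomposition of the projected kernel so each candidate lambda costs O(t).

A genomic-estimated breeding value (GEBV) for new material is mu + X1c beta
with X1c centered by the *training* constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize_scalar
from scipy.stats import pearsonr

from .io import GenotypeMatrix, PhenotypeVector

__all__ = ["RRBLUPFit", "fit_rrblup", "predict_gebv", "prediction_ability", "reml_h2"]

LAMBDA_BOUNDS = (1e-6, 1e6)


@dataclass
class RRBLUPFit:
    """Fitted RR-BLUP model: intercept, marker effects, variance components."""

    mu: float
    beta: np.ndarray
    var_u: float
    var_e: float
    lam: float
    marker_ids: list[str]
    center: np.ndarray
    mean_kernel_diag: float = np.nan
    degenerate: bool = False

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mu": self.mu,
                    "beta": dict(zip(self.marker_ids, map(float, self.beta))),
                    "var_u": self.var_u,
                    "var_e": self.var_e,
                    "lambda": self.lam,
                    "center": dict(zip(self.marker_ids, map(float, self.center))),
                    "degenerate": self.degenerate,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "RRBLUPFit":
        with open(path) as fh:
            d = json.load(fh)
        ids = list(d["beta"].keys())
        return cls(
            mu=d["mu"],
            beta=np.array([d["beta"][m] for m in ids]),
            var_u=d["var_u"],
            var_e=d["var_e"],
            lam=d["lambda"],
            marker_ids=ids,
            center=np.array([d["center"][m] for m in ids]),
            degenerate=d.get("degenerate", False),
        )


def _helmert_basis(n: int) -> np.ndarray:
    """Orthonormal (n, n-1) basis of the orthogonal complement of the
    all-ones vector (sub-diagonal Helmert contrasts); deterministic."""
    H = np.zeros((n, n - 1))
    for k in range(1, n):
        H[:k, k - 1] = 1.0
        H[k, k - 1] = -k
        H[:, k - 1] /= np.sqrt(k * (k + 1))
    return H


def _reml_neg_loglik(log_lam: float, xi: np.ndarray, eta2: np.ndarray) -> float:
    """-2x restricted log-likelihood (up to a constant) profiled over var_u."""
    lam = np.exp(log_lam)
    w = xi + lam
    s = float(np.sum(eta2 / w))
    return float(len(xi) * np.log(s) + np.sum(np.log(w)))


def reml_lambda(
    K: np.ndarray, y: np.ndarray, bounds=LAMBDA_BOUNDS, xatol: float = 1e-8
) -> tuple[float, float, float]:
    """REML estimate of (lambda, var_u, var_e) for V = var_u (K + lambda I).

    The intercept is absorbed by projecting onto the Helmert basis of 1-perp;
    the projected kernel is eigendecomposed once and the profiled restricted
    likelihood is optimized over log(lambda) on the bounded interval.
    """
    n = len(y)
    A = _helmert_basis(n)
    M = A.T @ K @ A
    xi, U = eigh(M)
    xi = np.clip(xi, 0.0, None)
    eta = U.T @ (A.T @ y)
    eta2 = eta**2
    res = minimize_scalar(
        _reml_neg_loglik,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        args=(xi, eta2),
        options={"xatol": xatol},
    )
    lam = float(np.exp(res.x))
    var_u = float(np.sum(eta2 / (xi + lam)) / (n - 1))
    return lam, var_u, lam * var_u


def fit_rrblup(
    G_train: GenotypeMatrix,
    y: PhenotypeVector,
    lambda_fixed: Optional[float] = None,
) -> RRBLUPFit:
    """Fit the RR-BLUP model on the training genotypes named in ``y``.

    With ``lambda_fixed`` the ridge parameter is taken as given (variance
    components are then profiled at that ratio); otherwise it is estimated by
    REML.  A zero-variance phenotype produces a degenerate fit
    (mu = mean(y), beta = 0) flagged on the result.
    """
    if len(y) < 3:
        raise ValueError("RR-BLUP requires at least 3 training genotypes")
    if G_train.n_markers < 1:
        raise ValueError("RR-BLUP requires at least 1 marker")
    Gy = G_train.subset_genotypes(y.genotype_ids)
    if Gy.has_missing:
        raise ValueError("training dosages contain missing values; impute first")
    X = Gy.dosage
    t, m = X.shape
    center = X.mean(axis=0)
    Xc = X - center
    yv = y.values.astype(float)
    mean_kd = float(np.mean(np.sum(Xc**2, axis=1)))

    if np.var(yv) == 0.0:
        return RRBLUPFit(
            mu=float(yv.mean()),
            beta=np.zeros(m),
            var_u=0.0,
            var_e=0.0,
            lam=np.inf,
            marker_ids=list(Gy.marker_ids),
            center=center,
            mean_kernel_diag=mean_kd,
            degenerate=True,
        )

    K = Xc @ Xc.T
    if lambda_fixed is None:
        lam, var_u, var_e = reml_lambda(K, yv)
    else:
        lam = float(lambda_fixed)
        A = _helmert_basis(t)
        M = A.T @ K @ A
        xi, U = eigh(M)
        xi = np.clip(xi, 0.0, None)
        eta2 = (U.T @ (A.T @ yv)) ** 2
        var_u = float(np.sum(eta2 / (xi + lam)) / (t - 1))
        var_e = lam * var_u

    c, low = cho_factor(K + lam * np.eye(t))
    Vinv_1 = cho_solve((c, low), np.ones(t))
    Vinv_y = cho_solve((c, low), yv)
    mu = float(Vinv_y.sum() / Vinv_1.sum())
    resid = yv - mu
    if m > t:
        beta = Xc.T @ cho_solve((c, low), resid)
    else:
        cr, lowr = cho_factor(Xc.T @ Xc + lam * np.eye(m))
        beta = cho_solve((cr, lowr), Xc.T @ resid)
    return RRBLUPFit(
        mu=mu,
        beta=beta,
        var_u=var_u,
        var_e=var_e,
        lam=lam,
        marker_ids=list(Gy.marker_ids),
        center=center,
        mean_kernel_diag=mean_kd,
    )


def predict_gebv(fit: RRBLUPFit, G_new: GenotypeMatrix) -> np.ndarray:
    """GEBVs mu + X1c beta for new genotypes; markers matched by id and
    centered with the training constants."""
    if G_new.has_missing:
        raise ValueError("prediction dosages contain missing values; impute first")
    try:
        idx = G_new.marker_index(fit.marker_ids)
    except KeyError as e:
        raise ValueError(f"genotype matrix lacks fitted markers: {e}") from e
    X1c = G_new.dosage[:, idx] - fit.center
    return fit.mu + X1c @ fit.beta


def prediction_ability(y_obs: np.ndarray, gebv: np.ndarray) -> float:
    """Pearson correlation between observed phenotypes and GEBVs."""
    y_obs = np.asarray(y_obs, float)
    gebv = np.asarray(gebv, float)
    if y_obs.shape != gebv.shape or y_obs.ndim != 1:
        raise ValueError("y_obs and gebv must be 1-D vectors of equal length")
    if len(y_obs) < 3:
        raise ValueError("prediction ability needs at least 3 pairs")
    if np.std(y_obs) == 0.0 or np.std(gebv) == 0.0:
        raise ValueError("zero variance in observed or predicted values")
    return float(pearsonr(y_obs, gebv)[0])


def reml_h2(fit: RRBLUPFit) -> float:
    """Genomic heritability implied by the fit:
    var_u * mean(diag(Xc Xc')) / (var_u * mean(diag(Xc Xc')) + var_e)."""
    if fit.degenerate:
        return 0.0
    vg = fit.var_u * fit.mean_kernel_diag
    return float(vg / (vg + fit.var_e))
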