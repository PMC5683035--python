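"""Ridge-regression BLUP: REML of the marker-variance ratio, effects, GEBVs.

Model: y = 1 mu + Z u + eps with u ~ N(0, sigma_u2 I), eps ~ N(0, sigma_eps2 I).
Writing lambda = sigma_eps2 / sigma_u2, the restricted likelihood reduces,
after projecting out the intercept and eigendecomposing the genomic kernel
Z Z', to a one-dimensional problem in lambda solved by bounded scalar
minimization on log(lambda). Marker effects then solve the mixed-model
equations; by the Woodbury identity

    u = Z' (Z Z' + lambda I)^-1 (y - 1 mu) = (Z'Z + lambda I)^-1 Z' (y - 1 mu),

so the kernel-sized (n x n) solve used here is exactly the classical
ridge solution, and GEBVs agree with GBLUP on the linear kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["RRBlupModel", "DegenerateFitError", "fit_rrblup", "predict_gebv", "accuracy"]

logger = logging.getLogger(__name__)

LAMBDA_BOUNDS = (1e-5, 1e5)


class DegenerateFitError(ValueError):
    """Training response carries no usable signal (constant y, too few lines)."""


@dataclass
class RRBlupModel:
    mu: float
    marker_effects: np.ndarray
    lambda_: float
    sigma_u2: float
    sigma_eps2: float
    marker_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        self.marker_effects = np.asarray(self.marker_effects, dtype=float)
        if self.marker_ids is not None and len(self.marker_ids) != self.marker_effects.size:
            raise ValueError("marker_ids length does not match effects")


def _impute_column_means(z: np.ndarray) -> np.ndarray:
    if not np.isnan(z).any():
        return z
    z = z.copy()
    col_mean = np.nanmean(z, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(z))
    z[idx] = col_mean[idx[1]]
    return z


def fit_rrblup(
    y: np.ndarray,
    z: np.ndarray,
    marker_ids: tuple[str, ...] | None = None,
    lambda_: float | None = None,
) -> RRBlupModel:
    """Fit ridge-regression BLUP, estimating lambda by REML unless given.

    ``z`` holds coded genotypes (one row per line, no centering; the
    explicit intercept absorbs the mean). Missing genotypes are imputed to
    the column mean. ``lambda_`` may be fixed for oracle comparisons.
    """
    y = np.asarray(y, dtype=float).ravel()
    z = _impute_column_means(np.asarray(z, dtype=float))
    n, m = z.shape
    if y.size != n:
        raise ValueError("y and Z have different numbers of lines")
    if n < 3:
        raise DegenerateFitError("need at least 3 training lines")
    if np.ptp(y) == 0:
        raise DegenerateFitError("training phenotype is constant")

    k = z @ z.T
    if lambda_ is None:
        lambda_, sigma_u2, sigma_eps2 = _reml_lambda(y, k)
    else:
        sigma_u2, sigma_eps2 = _profiled_variances(y, k, lambda_)

    # GLS intercept and effects at the chosen lambda
    v = k + lambda_ * np.eye(n)
    vinv_y = np.linalg.solve(v, y)
    vinv_1 = np.linalg.solve(v, np.ones(n))
    mu = float(np.ones(n) @ vinv_y / (np.ones(n) @ vinv_1))
    alpha = np.linalg.solve(v, y - mu)
    u = z.T @ alpha
    return RRBlupModel(
        mu=mu,
        marker_effects=u,
        lambda_=float(lambda_),
        sigma_u2=float(sigma_u2),
        sigma_eps2=float(sigma_eps2),
        marker_ids=tuple(marker_ids) if marker_ids is not None else None,
    )


def _spectral_parts(y: np.ndarray, k: np.ndarray):
    # Orthonormal contrast basis orthogonal to the intercept (Helmert rows),
    # so the restricted likelihood is the ordinary likelihood of Q y.
    from scipy.linalg import helmert

    n = y.size
    q = helmert(n)  # (n-1) x n, rows orthonormal and orthogonal to 1
    theta, u = np.linalg.eigh(q @ k @ q.T)
    theta = np.clip(theta, 0.0, None)
    omega = u.T @ (q @ y)
    return theta, omega


def _reml_lambda(y: np.ndarray, k: np.ndarray):
    theta, omega = _spectral_parts(y, k)
    df = theta.size
    w2 = omega**2

    def neg_restricted_ll(log_lam):
        lam = np.exp(log_lam)
        denom = theta + lam
        sigma_u2 = np.sum(w2 / denom) / df
        return df * np.log(sigma_u2) + np.sum(np.log(denom))

    res = optimize.minimize_scalar(
        neg_restricted_ll,
        bounds=(np.log(LAMBDA_BOUNDS[0]), np.log(LAMBDA_BOUNDS[1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    sigma_u2 = float(np.sum(w2 / (theta + lam)) / df)
    return lam, sigma_u2, lam * sigma_u2


def _profiled_variances(y: np.ndarray, k: np.ndarray, lam: float):
    theta, omega = _spectral_parts(y, k)
    sigma_u2 = float(np.sum(omega**2 / (theta + lam)) / theta.size)
    return sigma_u2, lam * sigma_u2


def predict_gebv(
    model: RRBlupModel,
    z_new: np.ndarray,
    marker_ids: tuple[str, ...] | None = None,
) -> np.ndarray:
    """GEBV = mu + Z_new u, aligning columns by marker id when ids are given."""
    z_new = _impute_column_means(np.asarray(z_new, dtype=float))
    if marker_ids is not None:
        if model.marker_ids is None:
            raise ValueError("model was fitted without marker ids; cannot align")
        pos = {m: j for j, m in enumerate(marker_ids)}
        missing = [m for m in model.marker_ids if m not in pos]
        if missing:
            raise ValueError(f"markers absent from prediction genotypes: {missing[:5]}")
        z_new = z_new[:, [pos[m] for m in model.marker_ids]]
    if z_new.shape[1] != model.marker_effects.size:
        raise ValueError("genotype matrix does not match the fitted markers")
    return model.mu + z_new @ model.marker_effects


def accuracy(observed: np.ndarray, gebv: np.ndarray) -> float:
    """Pearson correlation between phenotype and GEBV; NaN when undefined.

    A correlation is undefined for fewer than 3 pairs or when either vector
    has zero variance; those cases return NaN (reported as a failed
    replicate upstream, never imputed as zero) and are logged.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    gebv = np.asarray(gebv, dtype=float).ravel()
    if observed.size != gebv.size:
        raise ValueError("observed and predicted vectors differ in length")
    if observed.size < 3:
        logger.debug("accuracy undefined: fewer than 3 pairs")
        return float("nan")
    if np.ptp(observed) == 0 or np.ptp(gebv) == 0:
        logger.debug("accuracy undefined: zero variance")
        return float("nan")
    from scipy import stats

    return float(stats.pearsonr(observed, gebv).statistic)
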