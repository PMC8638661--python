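"""Ridge-regression BLUP / GBLUP mixed models fitted by REML.

The model is y = 1 beta + u + e with u ~ N(0, K sigma2_u) and
e ~ N(0, I sigma2_e).  The restricted likelihood is profiled down to a
one-dimensional function of log lambda (lambda = sigma2_e / sigma2_u)
via a spectral decomposition of the projected covariance structure, and
maximized by bounded scalar optimization.  GEBVs for unphenotyped lines
follow from the conditional expectation
u_miss = K_miss,obs (K_obs,obs + lambda I)^-1 (y - 1 beta).

:class:`GBLUP` takes a precomputed relationship kernel (sklearn
"precomputed kernel" convention); :class:`RRBLUP` takes the marker
matrix itself and additionally returns shrunken marker effects.  The
two are the same model in different coordinates and agree on GEBVs, but
they are computed through different decompositions (eigendecomposition
of the kernel vs SVD-backed marker crossproduct), which makes the
equivalence a useful numerical cross-check.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

__all__ = [
    "MixedModelFit",
    "GBLUP",
    "RRBLUP",
    "fit_gblup",
    "fit_rrblup",
    "predict",
    "reml_loglik",
]

_LOG_LAMBDA_BOUNDS = (-10.0, 10.0)
_JITTER = 1e-8


@dataclasses.dataclass
class MixedModelFit:
    """REML variance components, intercept and GEBVs.

    ``u`` covers every line supplied to the fit (phenotyped or not);
    ``marker_effects`` is populated only by the marker-matrix form.
    """

    sigma2_u: float
    sigma2_e: float
    lambda_: float
    beta: float
    u: pd.Series
    loglik: float
    marker_effects: pd.Series | None = None


def _projected_spectrum(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-structure of S G S on the space orthogonal to the intercept.

    Decomposing S (G + I) S isolates the intercept null-space: its
    eigenvalues are xi_s + 1 on the projected space and 0 on span(1).
    Returns (xi, eta) with xi the n-1 projected eigenvalues of G and
    eta the rotated responses.
    """
    n = len(y)
    one = np.ones(n) / np.sqrt(n)
    M = G + np.eye(n)
    M = M - np.outer(one, one @ M)
    M = M - np.outer(M @ one, one)
    M = (M + M.T) / 2.0
    evals, evecs = np.linalg.eigh(M)
    # keep the n-1 largest; the dropped one corresponds to span(1)
    xi = np.clip(evals[1:] - 1.0, 0.0, None)
    eta = evecs[:, 1:].T @ y
    return xi, eta


def reml_loglik(xi: np.ndarray, eta: np.ndarray, log_lambda: float) -> float:
    """Profiled restricted log-likelihood at lambda = exp(log_lambda)."""
    q = len(xi)
    denom = xi + np.exp(log_lambda)
    ss = float(np.sum(eta**2 / denom))
    return 0.5 * (
        q * np.log(q / (2.0 * np.pi)) - q - q * np.log(ss) - float(np.sum(np.log(denom)))
    )


def _reml(
    G: np.ndarray,
    y: np.ndarray,
    bounds: tuple[float, float],
    tol: float,
) -> tuple[float, float, float, float]:
    """Maximize the restricted likelihood in log lambda.

    Returns (lambda, sigma2_u, sigma2_e, loglik).
    """
    xi, eta = _projected_spectrum(G, y)
    res = minimize_scalar(
        lambda t: -reml_loglik(xi, eta, t),
        bounds=bounds,
        method="bounded",
        options={"xatol": tol},
    )
    log_lambda = float(res.x)
    lam = float(np.exp(log_lambda))
    q = len(xi)
    sigma2_u = float(np.sum(eta**2 / (xi + lam)) / q)
    sigma2_e = lam * sigma2_u
    return lam, sigma2_u, sigma2_e, float(-res.fun)


def _blup_solution(
    G: np.ndarray, y: np.ndarray, lam: float
) -> tuple[float, np.ndarray]:
    """GLS intercept and the BLUP dual coefficients alpha.

    u_any = G_any,obs alpha with alpha = (G + lam I)^-1 (y - 1 beta).
    """
    n = len(y)
    H = G + lam * np.eye(n)
    ones = np.ones(n)
    Hinv_y = np.linalg.solve(H, y)
    Hinv_1 = np.linalg.solve(H, ones)
    beta = float(ones @ Hinv_y / (ones @ Hinv_1))
    alpha = Hinv_y - beta * Hinv_1
    return beta, alpha


def _validate_y(y: np.ndarray, min_n: int = 10) -> None:
    if len(y) < min_n:
        raise ValueError(f"need at least {min_n} phenotyped lines, got {len(y)}")
    if len(np.unique(y)) < 2:
        raise ValueError("phenotypes have fewer than 2 distinct values")


def _check_psd(G: np.ndarray) -> np.ndarray:
    ev = np.linalg.eigvalsh((G + G.T) / 2.0)
    if ev[0] < -1e-6 * max(ev[-1], 1.0):
        raise ValueError(
            f"relationship matrix is not positive semidefinite "
            f"(min eigenvalue {ev[0]:.3g})"
        )
    if ev[0] < _JITTER:
        logger.info("near-singular kernel: adding %.0e to the diagonal", _JITTER)
        return G + _JITTER * np.eye(G.shape[0])
    return G


class GBLUP(BaseEstimator, RegressorMixin):
    """GBLUP with a precomputed relationship kernel.

    ``fit(K, y)`` expects the square kernel among the training lines;
    ``predict(K_cross)`` expects the (new x train) cross-kernel block
    and returns intercept + GEBV, in the style of sklearn's
    precomputed-kernel regressors.

    Attributes (after fit): ``sigma2_u_``, ``sigma2_e_``, ``lambda_``,
    ``beta_``, ``u_`` (training GEBVs), ``alpha_`` (dual coefficients),
    ``loglik_`` (restricted log-likelihood at the optimum).
    """

    def __init__(
        self,
        bounds: tuple[float, float] = _LOG_LAMBDA_BOUNDS,
        tol: float = 1e-8,
    ):
        self.bounds = bounds
        self.tol = tol

    def fit(self, K, y):
        K_arr = np.asarray(K, dtype=float)
        y_arr = np.asarray(y, dtype=float)
        if K_arr.shape != (len(y_arr), len(y_arr)):
            raise ValueError(
                f"K must be square over the {len(y_arr)} training lines, "
                f"got shape {K_arr.shape}"
            )
        _validate_y(y_arr)
        G = _check_psd(K_arr)
        lam, s2u, s2e, ll = _reml(G, y_arr, self.bounds, self.tol)
        beta, alpha = _blup_solution(G, y_arr, lam)
        self.lambda_ = lam
        self.sigma2_u_ = s2u
        self.sigma2_e_ = s2e
        self.loglik_ = ll
        self.beta_ = beta
        self.alpha_ = alpha
        self.u_ = G @ alpha
        self.n_features_in_ = K_arr.shape[1]
        return self

    def gebv(self, K_cross) -> np.ndarray:
        """GEBVs for lines given their kernel rows against the training set."""
        return np.asarray(K_cross, dtype=float) @ self.alpha_

    def predict(self, K_cross) -> np.ndarray:
        return self.beta_ + self.gebv(K_cross)


class RRBLUP(BaseEstimator, RegressorMixin):
    """Ridge-regression BLUP on the marker matrix itself.

    Marker columns are centered on their training means; the REML
    shrinkage is found on the marker crossproduct W Wᵀ, normalized to
    mean diagonal 1 exactly as the kinship form normalizes its kernel
    (so the profiled likelihood — and any boundary behaviour of the
    lambda optimizer — coincides between the two forms).  Effects are
    recovered as a = Wᵀ (W Wᵀ + lambda_m I)^-1 (y - 1 beta), the ridge
    solution with the REML-chosen penalty lambda_m = kernel_scale_ *
    lambda_.  GEBV = W a.
    """

    def __init__(
        self,
        bounds: tuple[float, float] = _LOG_LAMBDA_BOUNDS,
        tol: float = 1e-8,
        center: bool = True,
    ):
        self.bounds = bounds
        self.tol = tol
        self.center = center

    def fit(self, X, y):
        W = np.asarray(X, dtype=float)
        y_arr = np.asarray(y, dtype=float)
        if np.isnan(W).any():
            raise ValueError("marker matrix must be complete (impute first)")
        _validate_y(y_arr)
        self.col_means_ = W.mean(axis=0) if self.center else np.zeros(W.shape[1])
        Wc = W - self.col_means_
        G = Wc @ Wc.T
        scale = np.trace(G) / G.shape[0]
        if scale <= 0:
            raise ValueError("all markers are monomorphic")
        Gs = _check_psd(G / scale)  # same near-singularity handling as GBLUP
        lam, s2u, s2e, ll = _reml(Gs, y_arr, self.bounds, self.tol)
        beta, alpha = _blup_solution(Gs, y_arr, lam)
        self.kernel_scale_ = float(scale)
        self.lambda_ = lam  # on the normalized-kernel scale
        self.sigma2_u_ = s2u  # genetic variance on the same scale as GBLUP
        self.sigma2_e_ = s2e
        self.loglik_ = ll
        self.beta_ = beta
        self.effects_ = Wc.T @ alpha / scale
        self.u_ = Wc @ self.effects_
        self.n_features_in_ = W.shape[1]
        return self

    def gebv(self, X) -> np.ndarray:
        W = np.asarray(X, dtype=float) - self.col_means_
        return W @ self.effects_

    def predict(self, X) -> np.ndarray:
        return self.beta_ + self.gebv(X)


# ---------------------------------------------------------------------------
# functional wrappers keyed by line id


def fit_gblup(y: pd.Series, K: pd.DataFrame, tol: float = 1e-8) -> MixedModelFit:
    """REML GBLUP over a labeled kernel; lines with missing phenotype
    are excluded from the likelihood but receive GEBVs."""
    if not y.index.isin(K.index).all():
        unknown = list(y.index[~y.index.isin(K.index)])[:5]
        raise ValueError(f"phenotyped lines absent from the kernel: {unknown}")
    y_full = y.reindex(K.index)
    obs = y_full.notna().to_numpy()
    est = GBLUP(tol=tol).fit(
        K.iloc[obs, obs].to_numpy(), y_full.to_numpy()[obs]
    )
    u_all = est.gebv(K.iloc[:, obs].to_numpy())
    return MixedModelFit(
        sigma2_u=est.sigma2_u_,
        sigma2_e=est.sigma2_e_,
        lambda_=est.lambda_,
        beta=est.beta_,
        u=pd.Series(u_all, index=K.index, name="gebv"),
        loglik=est.loglik_,
    )


def fit_rrblup(y: pd.Series, gm: pd.DataFrame, tol: float = 1e-8) -> MixedModelFit:
    """REML ridge regression on a labeled complete genotype matrix.

    Centering uses the column means over *all* lines in ``gm`` (the
    prediction population), matching how the kinship form centers; the
    training fit then sees pre-centered columns.
    """
    if not y.index.isin(gm.index).all():
        unknown = list(y.index[~y.index.isin(gm.index)])[:5]
        raise ValueError(f"phenotyped lines absent from the genotype matrix: {unknown}")
    y_full = y.reindex(gm.index)
    obs = y_full.notna().to_numpy()
    Wc = gm.to_numpy(dtype=float)
    Wc = Wc - Wc.mean(axis=0, keepdims=True)
    est = RRBLUP(tol=tol, center=False).fit(Wc[obs], y_full.to_numpy()[obs])
    u_all = Wc @ est.effects_
    return MixedModelFit(
        sigma2_u=est.sigma2_u_,
        sigma2_e=est.sigma2_e_,
        lambda_=est.lambda_,
        beta=est.beta_,
        u=pd.Series(u_all, index=gm.index, name="gebv"),
        loglik=est.loglik_,
        marker_effects=pd.Series(est.effects_, index=gm.columns, name="effect"),
    )


def predict(fit: MixedModelFit, lines) -> pd.Series:
    """GEBVs for the requested lines, in request order."""
    lines = list(lines)
    unknown = [l for l in lines if l not in fit.u.index]
    if unknown:
        raise ValueError(f"unknown line ids: {unknown[:5]}")
    return fit.u.loc[lines]
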