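"""Partial distance correlation via the Gaussian-graphical-model route.

The pairwise distance-covariance matrix Σ (Σ_ij = dCov(X_i, X_j), diagonal
dVar) is inverted with the Moore-Penrose pseudo-inverse — identical to the
ordinary inverse when Σ is non-singular — giving the precision matrix ω.
Partial correlations, each pair corrected for the linear contribution of
every other feature, follow the GGM identity

    ρ_ij·rest = -ω_ij / sqrt(ω_ii · ω_jj),

and significance uses the Fisher transform z = arctanh(ρ) with the normal
approximation p = 2·(1 - Φ(|z|·sqrt(N - M - 1))).

The precision route is only trustworthy when features are fewer than
samples (M < N); Σ is otherwise rank-deficient and the pseudo-inverse
projects away directions, so by default the computation refuses M >= N
unless explicitly overridden.  No regularized estimation (graphical lasso,
shrinkage) is attempted.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dcor_core import _centered_per_feature, dcov2, dvar
from .io_validate import FeatureMatrix, SidcorError

logger = logging.getLogger(__name__)


class FeatureGuardError(SidcorError):
    """Feature count is not smaller than sample count (partials unreliable)."""


@dataclass(frozen=True)
class PartialModel:
    """Full partial-correlation model over the usable features.

    sigma: M x M distance-covariance matrix (diagonal = dVar);
    omega: its Moore-Penrose pseudo-inverse (precision matrix);
    rho:   partial correlations, unit diagonal by convention;
    z, p:  Fisher z values and two-sided normal-approximation p-values
           (diagonal entries are NaN — self-partials are not tested).
    """

    features: tuple[str, ...]
    sigma: np.ndarray
    omega: np.ndarray
    rho: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n_samples: int
    n_features: int


def dcov_matrix(fm: FeatureMatrix,
                override_feature_guard: bool = False) -> tuple[np.ndarray, tuple[str, ...]]:
    """Distance-covariance matrix over the usable features.

    Σ_ij = dCov(X_i, X_j) = sqrt(dCov²) with the roundoff clamp applied;
    Σ_ii = dVar(X_i).  Requires at least 3 usable features (a partial needs
    one covariate) and, unless overridden, M < N.
    """
    idx = fm.usable_indices
    M = len(idx)
    N = fm.n_samples
    if M < 3:
        raise SidcorError(
            f"partial correlation needs at least 3 non-constant features, got {M}"
        )
    if M >= N:
        msg = (f"feature count M={M} is not smaller than sample count N={N}: "
               "the distance-covariance matrix is rank-deficient and partial "
               "correlations from its pseudo-inverse are unreliable")
        if not override_feature_guard:
            raise FeatureGuardError(
                msg + "; pass override_feature_guard to proceed anyway")
        warnings.warn(msg, UserWarning, stacklevel=2)
        logger.warning(msg)
    centered = _centered_per_feature(fm)
    sigma = np.zeros((M, M))
    for a in range(M):
        # dVar(X) = dCov(X, X): same square-root scale as the off-diagonals.
        sigma[a, a] = math.sqrt(dvar(centered[int(idx[a])]))
        for b in range(a + 1, M):
            v = dcov2(centered[int(idx[a])], centered[int(idx[b])])
            sigma[a, b] = sigma[b, a] = math.sqrt(v)
    return sigma, fm.usable_features


def precision(sigma: np.ndarray, rcond: float = 1e-12) -> np.ndarray:
    """Moore-Penrose pseudo-inverse of Σ (ordinary inverse when non-singular).

    ``rcond`` is the relative singular-value cutoff (fraction of the largest
    singular value below which components are truncated).  The condition
    number is logged for diagnosis of near-singular input.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise SidcorError(f"covariance matrix must be square, got {sigma.shape}")
    if not np.allclose(sigma, sigma.T, atol=1e-8 * max(1.0, float(np.abs(sigma).max()))):
        raise SidcorError("covariance matrix must be symmetric")
    sv = np.linalg.svd(sigma, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else math.inf
    logger.info("precision: condition number of sigma = %.3e", cond)
    return np.linalg.pinv(sigma, rcond=rcond, hermitian=True)


def partial_rho(omega: np.ndarray) -> np.ndarray:
    """Partial correlations ρ_ij = -ω_ij / sqrt(ω_ii·ω_jj); unit diagonal.

    Features with a non-positive precision diagonal (possible only for a
    degenerate pseudo-inverse) are excluded: their rows/columns become NaN
    and a warning names them.
    """
    omega = np.asarray(omega, dtype=float)
    d = np.diag(omega).copy()
    bad = np.flatnonzero(d <= 0)
    if bad.size:
        warnings.warn(
            "non-positive precision diagonal for feature index(es) "
            f"{bad.tolist()}: excluded from partial correlations",
            UserWarning, stacklevel=2)
        d[bad] = np.nan
    denom = np.sqrt(np.outer(d, d))
    with np.errstate(invalid="ignore"):
        rho = -omega / denom
    np.fill_diagonal(rho, 1.0)
    return rho


def fisher_pvalue(rho_ij, N: int, M: int,
                  count_all_features: bool = True,
                  sqrt_df: bool = True):
    """Fisher z value(s) and p-value(s) for partial correlation(s).

    z = 0.5·ln((1+ρ)/(1−ρ)); p = 2·(1 − Φ(|z|·κ)) where κ = sqrt(N−M−1)
    by default.  ``count_all_features=False`` uses only the controlled
    covariates (M−2) in the degrees of freedom; ``sqrt_df=False`` uses the
    literal un-rooted product N−M−1 as the scale factor (documented
    alternative reading, not recommended).  |ρ| = 1 yields p = 0.
    """
    m_eff = M if count_all_features else M - 2
    df = N - m_eff - 1
    if df < 1:
        raise FeatureGuardError(
            f"N - M - 1 = {df} < 1: too many features for N={N} samples; "
            "reduce features below the sample count")
    rho = np.asarray(rho_ij, dtype=float)
    scalar = rho.ndim == 0
    rho = np.atleast_1d(rho)
    if np.any(np.abs(rho) > 1.0 + 1e-10):
        raise SidcorError("partial correlation magnitude exceeds 1 beyond roundoff")
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        z = np.arctanh(rho)
    kappa = math.sqrt(df) if sqrt_df else float(df)
    p = 2.0 * stats.norm.sf(np.abs(z) * kappa)
    p = np.clip(p, 0.0, 1.0)
    p = np.where(np.isinf(z), 0.0, p)
    if scalar:
        return float(z[0]), float(p[0])
    return z, p


def fit_partial(fm: FeatureMatrix,
                override_feature_guard: bool = False,
                rcond: float = 1e-12,
                count_all_features: bool = True,
                sqrt_df: bool = True,
                use_dcor_matrix: bool = False) -> PartialModel:
    """Run the full GGM partial-correlation pipeline on a feature matrix.

    ``use_dcor_matrix`` inverts the dCor matrix instead of the
    distance-covariance matrix — a sensitivity-analysis variant, not the
    default method.
    """
    sigma, features = dcov_matrix(fm, override_feature_guard=override_feature_guard)
    if use_dcor_matrix:
        d = np.sqrt(np.diag(sigma))
        sigma = sigma / np.outer(d, d)
    omega = precision(sigma, rcond=rcond)
    rho = partial_rho(omega)
    M = len(features)
    off = ~np.eye(M, dtype=bool)
    z = np.full((M, M), np.nan)
    p = np.full((M, M), np.nan)
    z_off, p_off = fisher_pvalue(rho[off], fm.n_samples, M,
                                 count_all_features=count_all_features,
                                 sqrt_df=sqrt_df)
    z[off] = z_off
    p[off] = p_off
    return PartialModel(features=features, sigma=sigma, omega=omega,
                        rho=rho, z=z, p=p,
                        n_samples=fm.n_samples, n_features=M)
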