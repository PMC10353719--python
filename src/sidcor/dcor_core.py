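"""Distance covariance / correlation in one-to-one and one-to-all modes.

Implements the plain V-statistic estimator on doubly centered Euclidean
distance matrices:

    a_jk = |x_j - x_k|                    (univariate feature)
    A_jk = a_jk - abar_j. - abar_.k + abar..
    dCov²(X,Y) = (1/n²) Σ_jk A_jk B_jk
    dVar(X)    = dCov²(X,X)
    dCor²(X,Y) = dCov²(X,Y) / sqrt(dVar(X)·dVar(Y))

dCor lies in [0, 1] and is zero only under full independence, so it detects
non-linear dependence that Pearson/Spearman miss.  One-to-all mode replaces
one side of the pair with the joint Euclidean distance structure of all the
remaining features in (m-1)-dimensional space.

Neither the bias-corrected estimator nor the O(n log n) univariate algorithm
is provided: sample sizes in the target domain (tens of samples) do not
need them, and the V-statistic form is the one the significance formulas
downstream assume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io_validate import FeatureMatrix, SidcorError


class DegenerateFeatureError(SidcorError):
    """A feature has zero distance variance: dCor is undefined for it."""


class InternalConsistencyError(SidcorError):
    """A computed statistic violated an internal invariant (not user error)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CenteredDistance:
    """A doubly centered pairwise-distance matrix with its centering terms.

    Row means, column means and the grand mean of the raw distance matrix
    are retained for audit; every row and column of ``c`` sums to zero.
    """

    c: np.ndarray
    row_means: np.ndarray
    col_means: np.ndarray
    grand_mean: float

    @property
    def n(self) -> int:
        return self.c.shape[0]


@dataclass(frozen=True)
class DcorResult:
    """Distance-correlation statistics for one pair (or one-to-all block).

    ``dcov2`` is the squared distance covariance (clamped to 0 when a tiny
    negative arises from roundoff); ``dvar_x``/``dvar_y`` are the squared
    distance variances of each side; ``dcor`` is on the correlation scale,
    in [0, 1].
    """

    dcov2: float
    dvar_x: float
    dvar_y: float
    dcor: float
    mode: str = "one_to_one"


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

def pairwise_distance(x: np.ndarray) -> np.ndarray:
    """n x n matrix of |x_j - x_k| for a univariate sample vector."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise SidcorError("need at least 2 samples for a distance matrix")
    return np.abs(x[:, None] - x[None, :])


def joint_distance(block: np.ndarray) -> np.ndarray:
    """n x n Euclidean distance matrix between the rows of an n x k block.

    This is the true Euclidean norm in k-space (square root of the summed
    squared per-feature differences); for a single column it reduces exactly
    to :func:`pairwise_distance`.
    """
    block = np.asarray(block, dtype=float)
    if block.ndim == 1:
        block = block[:, None]
    if block.shape[1] < 1:
        raise SidcorError("joint distance needs at least one feature column")
    return squareform(pdist(block, metric="euclidean"))


def double_center(d: np.ndarray) -> CenteredDistance:
    """Doubly center a distance matrix: subtract row/column means, add back
    the grand mean.  Row and column sums of the result vanish."""
    d = np.asarray(d, dtype=float)
    row_means = d.mean(axis=1)
    col_means = d.mean(axis=0)
    grand_mean = float(d.mean())
    c = d - row_means[:, None] - col_means[None, :] + grand_mean
    return CenteredDistance(c, row_means, col_means, grand_mean)


# ---------------------------------------------------------------------------
# Covariance / correlation statistics
# ---------------------------------------------------------------------------

def dcov2(A: CenteredDistance, B: CenteredDistance) -> float:
    """Squared distance covariance: (1/n²) Σ_jk A_jk·B_jk.

    Mathematically non-negative; values in a small negative roundoff band
    are clamped to 0, anything more negative indicates a bug upstream and
    raises :class:`InternalConsistencyError`.
    """
    if A.c.shape != B.c.shape:
        raise SidcorError(
            f"centered matrices have mismatched shapes {A.c.shape} vs {B.c.shape}"
        )
    n = A.n
    val = float(np.sum(A.c * B.c)) / (n * n)
    if val < 0:
        scale = max(1.0, float(np.sum(A.c ** 2)) / (n * n),
                    float(np.sum(B.c ** 2)) / (n * n))
        if val > -1e-12 * scale:
            return 0.0
        raise InternalConsistencyError(
            f"squared distance covariance is negative beyond roundoff: {val}"
        )
    return val


def dvar(A: CenteredDistance) -> float:
    """Squared distance variance: dCov²(X, X) = (1/n²) Σ A_jk²."""
    n = A.n
    return float(np.sum(A.c ** 2)) / (n * n)


def dcor_from_stats(dcov2_xy: float, dvar_x: float, dvar_y: float,
                    mode: str = "one_to_one") -> DcorResult:
    """Assemble dCor from its components and clamp it into [0, 1].

    dcor² = dcov² / sqrt(dvar_x · dvar_y).  A zero distance variance means
    the underlying feature is constant and the correlation undefined.
    """
    if dvar_x <= 0.0 or dvar_y <= 0.0:
        raise DegenerateFeatureError(
            "distance variance is zero (constant feature): dCor undefined"
        )
    dcor2 = dcov2_xy / np.sqrt(dvar_x * dvar_y)
    dcor = float(np.sqrt(max(dcor2, 0.0)))
    if dcor > 1.0:
        if dcor > 1.0 + 1e-10:
            raise InternalConsistencyError(f"dCor exceeds 1 beyond roundoff: {dcor}")
        dcor = 1.0
    return DcorResult(dcov2=dcov2_xy, dvar_x=dvar_x, dvar_y=dvar_y,
                      dcor=dcor, mode=mode)


def dcor_pair(x: np.ndarray, y: np.ndarray) -> DcorResult:
    """Distance correlation between two sample vectors (full pipeline)."""
    A = double_center(pairwise_distance(x))
    B = double_center(pairwise_distance(y))
    return dcor_from_stats(dcov2(A, B), dvar(A), dvar(B))


# ---------------------------------------------------------------------------
# Matrix-level modes
# ---------------------------------------------------------------------------

def _centered_per_feature(fm: FeatureMatrix) -> dict[int, CenteredDistance]:
    """Centered distance matrix for every usable feature, computed once.

    O(m·n²) memory; results are bit-identical to recomputing per pair.
    """
    return {int(i): double_center(pairwise_distance(fm.values[:, i]))
            for i in fm.usable_indices}


@dataclass(frozen=True)
class OneToOneResult:
    """All pairwise dCor statistics over the usable features.

    ``dcor`` is symmetric with unit diagonal (self-correlation is 1 by
    convention and never part of the output edge list); ``dcov2`` holds the
    pairwise squared distance covariances, ``dvar2`` the per-feature squared
    distance variances.
    """

    features: tuple[str, ...]
    dcor: np.ndarray
    dcov2: np.ndarray
    dvar2: np.ndarray

    def pair(self, i: int, j: int) -> DcorResult:
        return DcorResult(dcov2=float(self.dcov2[i, j]),
                          dvar_x=float(self.dvar2[i]),
                          dvar_y=float(self.dvar2[j]),
                          dcor=float(self.dcor[i, j]))


def one_to_one_matrix(fm: FeatureMatrix) -> OneToOneResult:
    """Pairwise dCor over all usable (non-constant) features.

    Each entry runs pairwise_distance -> double_center -> dcov2 -> dcor;
    the centered distance matrix of each feature is computed once and
    reused, and each unordered pair is computed once, so the returned grid
    is symmetric to the bit.
    """
    idx = fm.usable_indices
    m = len(idx)
    if m < 2:
        raise SidcorError(
            f"need at least 2 non-constant features, got {m}"
        )
    centered = _centered_per_feature(fm)
    dvar2 = np.array([dvar(centered[int(i)]) for i in idx])
    for k, i in enumerate(idx):
        if dvar2[k] <= 0.0:
            raise DegenerateFeatureError(
                f"feature '{fm.feature_names[int(i)]}' has zero distance variance"
            )
    dc2 = np.zeros((m, m))
    dcor_mat = np.eye(m)
    for a in range(m):
        dc2[a, a] = dvar2[a]
        for b in range(a + 1, m):
            v = dcov2(centered[int(idx[a])], centered[int(idx[b])])
            dc2[a, b] = dc2[b, a] = v
            r = dcor_from_stats(v, dvar2[a], dvar2[b]).dcor
            dcor_mat[a, b] = dcor_mat[b, a] = r
    return OneToOneResult(features=fm.usable_features, dcor=dcor_mat,
                          dcov2=dc2, dvar2=dvar2)


def one_to_all(fm: FeatureMatrix, i: int) -> DcorResult:
    """dCor between feature ``i`` and the joint distance structure of all
    other usable features in (m-1)-dimensional space.

    ``i`` indexes the original feature columns; it must name a usable
    (non-constant) feature and at least one other usable feature must exist.
    """
    idx = list(fm.usable_indices)
    if i not in idx:
        raise DegenerateFeatureError(
            f"feature '{fm.feature_names[i]}' is constant: one-to-all dCor undefined"
        )
    others = [j for j in idx if j != i]
    if not others:
        raise SidcorError("one-to-all needs at least one other usable feature")
    A = double_center(pairwise_distance(fm.values[:, i]))
    B = double_center(joint_distance(fm.values[:, others]))
    res = dcor_from_stats(dcov2(A, B), dvar(A), dvar(B), mode="one_to_all")
    return res
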