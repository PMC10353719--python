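"""Signs, companion Pearson/Spearman statistics, and p-values for dCor.

Distance correlation is non-negative, so directionality is restored by
borrowing the sign of the Pearson correlation of the same pair ("signed
distance correlation").  The p-value uses the t statistic

    t = dCor · sqrt(n-2) / sqrt(1 - dCor²),   p = 2·(1 - F_t(t; n-2)),

the same transform as the classical Pearson test with the correlation
replaced by dCor.  This is a pragmatic screening p-value, not a calibrated
independence test (the permutation-based energy test would be the rigorous
alternative); it is monotone in dCor and in n, which is what threshold
filtering needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dcor_core import DcorResult
from .io_validate import SidcorError

#: |pearson_r| below this resolves the sign to +1 (deterministic tie-break).
SIGN_TIE_TOL = 1e-15


@dataclass(frozen=True)
class SignedDcor:
    """A distance correlation with sign, p-value and companion statistics."""

    dcor: float
    sign: int
    signed_dcor: float
    t_stat: float
    p_value: float
    n: int
    pearson_r: float = math.nan
    pearson_p: float = math.nan
    spearman_rho: float = math.nan
    spearman_p: float = math.nan
    mode: str = "one_to_one"


def t_pvalue(dcor: float, n: int) -> tuple[float, float]:
    """t statistic and two-sided p-value for a dCor value at n samples.

    dCor = 1 gives t = +inf and p = 0; dCor = 0 gives t = 0 and p = 1.
    """
    if n < 3:
        raise SidcorError(f"p-value needs n >= 3 samples (n-2 df), got n={n}")
    if not 0.0 <= dcor <= 1.0:
        raise SidcorError(f"dcor must be in [0, 1], got {dcor}")
    if dcor == 1.0:
        return math.inf, 0.0
    t = dcor * math.sqrt(n - 2) / math.sqrt(1.0 - dcor * dcor)
    p = 2.0 * float(stats.t.sf(t, df=n - 2))
    return t, min(max(p, 0.0), 1.0)


def pearson_spearman(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, float]:
    """Pearson r and Spearman rho with their two-sided t-based p-values.

    Spearman ranks use the average-tie method (scipy default).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise SidcorError("companion correlations need n >= 3 samples")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise SidcorError("companion correlation undefined for a constant vector")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return (float(pr.statistic), float(pr.pvalue),
            float(sr.statistic), float(sr.pvalue))


def attach_sign(
    dcor_result: DcorResult,
    n: int,
    pearson_r: float,
    pearson_p: float = math.nan,
    spearman_rho: float = math.nan,
    spearman_p: float = math.nan,
) -> SignedDcor:
    """Combine a DcorResult with its sign (from Pearson) and p-value.

    sign = -1 iff pearson_r < -SIGN_TIE_TOL, else +1: a numerically-zero
    Pearson correlation (e.g. y = x² on a symmetric grid) resolves to +1.
    """
    sign = -1 if pearson_r < -SIGN_TIE_TOL else 1
    t, p = t_pvalue(dcor_result.dcor, n)
    return SignedDcor(
        dcor=dcor_result.dcor,
        sign=sign,
        signed_dcor=sign * dcor_result.dcor,
        t_stat=t,
        p_value=p,
        n=n,
        pearson_r=pearson_r,
        pearson_p=pearson_p,
        spearman_rho=spearman_rho,
        spearman_p=spearman_p,
        mode=dcor_result.mode,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise SidcorError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
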