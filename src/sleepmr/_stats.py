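"""Closed-form regression helpers shared across the package.

Per-SNP association scans repeat the same univariable regression many
times (k SNPs x two sample halves x hundreds of simulation replicates),
so the simple linear and the two-parameter logistic cases are
implemented as vectorised column sweeps rather than per-fit calls into a
modelling library.  Both are cross-checked against statsmodels in the
test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from scipy.special import expit

# 95% CI half-width multiplier; the reporting contract throughout is
# estimate +/- 1.96 * SE with two-sided normal p-values.
Z95 = 1.96


def two_sided_p(z: np.ndarray | float) -> np.ndarray | float:
    """Two-sided p-value from the standard normal reference."""
    return 2.0 * sps.norm.sf(np.abs(z))


def normal_ci(beta, se):
    return beta - Z95 * se, beta + Z95 * se


def linear_assoc_each(X, y, chunk: int = 64):
    """Simple (univariable) OLS of ``y`` on each column of ``X``.

    Returns ``(beta, se)`` arrays of length k.  Residual variance uses
    n - 2 degrees of freedom per column.  Columns with zero variance
    yield NaN.  Perfect fits yield se = 0.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.shape[0]
    if n <= 2:
        raise ValueError("need more than 2 observations for per-column OLS")
    X = np.asarray(X)
    k = X.shape[1]
    yc = y - y.mean()
    syy = float(yc @ yc)
    beta = np.empty(k)
    se = np.empty(k)
    for j0 in range(0, k, chunk):
        j1 = min(j0 + chunk, k)
        Xc = np.asarray(X[:, j0:j1], dtype=np.float64)
        Xc = Xc - Xc.mean(axis=0)
        sxx = np.einsum("ij,ij->j", Xc, Xc)
        sxy = Xc.T @ yc
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
            rss = np.maximum(syy - b * sxy, 0.0)
            s2 = rss / (n - 2)
            se[j0:j1] = np.where(sxx > 0, np.sqrt(s2 / np.where(sxx > 0, sxx, 1.0)), np.nan)
        beta[j0:j1] = b
    return beta, se


def logistic_assoc_each(X, y, max_iter: int = 40, tol: float = 1e-10, chunk: int = 32):
    """Univariable logistic regression of binary ``y`` on each column of ``X``.

    Newton/IRLS on the two-parameter model logit(p) = a + b*x, vectorised
    across columns.  Returns ``(beta, se, converged)``; non-converged or
    separated columns are flagged False with NaN estimates.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.shape[0]
    X = np.asarray(X)
    k = X.shape[1]
    beta = np.full(k, np.nan)
    se = np.full(k, np.nan)
    ok = np.zeros(k, dtype=bool)
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        return beta, se, ok
    a0 = float(np.log(ybar / (1.0 - ybar)))
    for j0 in range(0, k, chunk):
        j1 = min(j0 + chunk, k)
        Xc = np.asarray(X[:, j0:j1], dtype=np.float64)
        m = j1 - j0
        a = np.full(m, a0)
        b = np.zeros(m)
        conv = np.zeros(m, dtype=bool)
        for _ in range(max_iter):
            eta = a[None, :] + Xc * b[None, :]
            p = expit(eta)
            w = p * (1.0 - p)
            r = y[:, None] - p
            u1 = r.sum(axis=0)
            u2 = np.einsum("ij,ij->j", Xc, r)
            i11 = w.sum(axis=0)
            i12 = np.einsum("ij,ij->j", Xc, w)
            i22 = np.einsum("ij,ij,ij->j", Xc, Xc, w)
            det = i11 * i22 - i12 * i12
            bad = ~np.isfinite(det) | (det <= 1e-12)
            det = np.where(bad, 1.0, det)
            da = (i22 * u1 - i12 * u2) / det
            db = (-i12 * u1 + i11 * u2) / det
            da = np.where(bad, 0.0, da)
            db = np.where(bad, 0.0, db)
            a += da
            b += db
            step = np.maximum(np.abs(da), np.abs(db))
            conv = (step < tol) & ~bad & (np.abs(b) < 50)
            if conv.all():
                break
        eta = a[None, :] + Xc * b[None, :]
        p = expit(eta)
        w = p * (1.0 - p)
        i11 = w.sum(axis=0)
        i12 = np.einsum("ij,ij->j", Xc, w)
        i22 = np.einsum("ij,ij,ij->j", Xc, Xc, w)
        det = i11 * i22 - i12 * i12
        good = conv & np.isfinite(det) & (det > 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.sqrt(np.where(good, i11 / np.where(good, det, 1.0), np.nan))
        beta[j0:j1] = np.where(good, b, np.nan)
        se[j0:j1] = s
        ok[j0:j1] = good
    return beta, se, ok


def joint_r2(y, X) -> float:
    """R-squared of the multivariable OLS of ``y`` on all columns of ``X``."""
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    tss = float(yc @ yc)
    if tss == 0.0:
        raise ValueError("outcome has zero variance")
    coef, _, _, _ = np.linalg.lstsq(Xc, yc, rcond=None)
    fitted = Xc @ coef
    rss = float(((yc - fitted) ** 2).sum())
    return max(0.0, 1.0 - rss / tss)


def simple_slope(x, y):
    """Slope and SE of the univariable OLS of y on x (n-2 df)."""
    b, s = linear_assoc_each(np.asarray(x, dtype=np.float64)[:, None], y)
    return float(b[0]), float(s[0])
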