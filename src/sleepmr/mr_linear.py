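"""Linear Mendelian-randomization estimators and sensitivity machinery.

All estimators consume allele-aligned per-SNP association pairs
(:class:`sleepmr.instruments.HarmonizedInstruments`) and return
:class:`MREstimate`.  Estimation for binary outcomes happens on the
log-odds scale; exponentiation is a reporting concern
(:func:`sleepmr.pipeline.exponentiate_report`).

Conventions: first-order ratio SEs (no second-order term, no
instrument-exposure uncertainty in the IVW weights), fixed-effect
weighting by 1/se_by^2, two-sided normal p-values, CIs at +/- 1.96 SE.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ._stats import Z95, two_sided_p
from .instruments import HarmonizedInstruments

__all__ = [
    "MREstimate",
    "OverlapBias",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "meta_fixed",
    "rerun_excluding",
    "overlap_bias",
]


@dataclass(frozen=True)
class MREstimate:
    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    note: str = ""

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - Z95 * self.se, self.beta + Z95 * self.se)


@dataclass(frozen=True)
class OverlapBias:
    overlap_fraction: float
    confounded_assoc: float
    f_stat: float
    bias: float
    type1: float | None = None


def _estimate(method, beta, se, n_snps, **kw) -> MREstimate:
    p = float(two_sided_p(beta / se)) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MREstimate(method=method, beta=float(beta), se=float(se), p=p,
                      n_snps=int(n_snps), **kw)


def wald_ratio(bx: float, se_bx: float, by: float, se_by: float) -> MREstimate:
    """Single-instrument ratio estimate: beta = by/bx, se = se_by/|bx|."""
    if bx == 0:
        raise ZeroDivisionError("wald ratio undefined for bx = 0")
    return _estimate("wald", by / bx, se_by / abs(bx), 1)


def ivw(h: HarmonizedInstruments) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate.

    Equivalent to 1/se_by^2-weighted least squares of by on bx through
    the origin: beta = sum(bx*by/se_by^2) / sum(bx^2/se_by^2).
    """
    if len(h) < 1:
        raise ValueError("no instruments")
    w = 1.0 / h.se_by**2
    denom = float((w * h.bx**2).sum())
    if denom == 0:
        raise ValueError("all instrument-exposure associations are zero")
    beta = float((w * h.bx * h.by).sum()) / denom
    se = 1.0 / np.sqrt(denom)
    return _estimate("ivw", beta, se, len(h))


def egger(h: HarmonizedInstruments) -> MREstimate:
    """MR-Egger: weighted regression of by on bx with a free intercept.

    Each instrument is oriented so bx >= 0 (flipping by with it); the
    slope is the causal estimate and the intercept estimates the
    average directional pleiotropic effect.  SEs come from the
    fixed-weight information matrix inv(X'WX).
    """
    if len(h) < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    sign = np.where(h.bx < 0, -1.0, 1.0)
    bx = h.bx * sign
    by = h.by * sign
    if np.allclose(bx, bx[0]):
        raise ValueError("degenerate design: no spread in instrument strengths")
    w = 1.0 / h.se_by**2
    sw = w.sum()
    mx = float((w * bx).sum() / sw)
    my = float((w * by).sum() / sw)
    sxx = float((w * (bx - mx) ** 2).sum())
    sxy = float((w * (bx - mx) * (by - my)).sum())
    slope = sxy / sxx
    intercept = my - slope * mx
    se_slope = 1.0 / np.sqrt(sxx)
    se_int = np.sqrt(1.0 / sw + mx**2 / sxx)
    int_p = float(two_sided_p(intercept / se_int)) if se_int > 0 else 0.0
    return _estimate(
        "egger", slope, se_slope, len(h),
        egger_intercept=float(intercept), intercept_se=float(se_int),
        intercept_p=int_p,
    )


def _wme_point(bx, by, se_by, weights) -> float:
    ratios = by / bx
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    csum = np.cumsum(w)
    total = csum[-1]
    p = (csum - w / 2.0) / total
    return float(np.interp(0.5, p, r))


def weighted_median(
    h: HarmonizedInstruments, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of per-SNP ratio estimates.

    Weights are the inverse first-order ratio variances bx^2/se_by^2;
    the estimate interpolates the 50th weighted percentile of the
    ordered ratios.  The SE comes from a seeded parametric bootstrap
    (bx* ~ N(bx, se_bx), by* ~ N(by, se_by)).  Consistent when at least
    half the weight comes from valid instruments.
    """
    keep = h.bx != 0
    dropped = len(h) - int(keep.sum())
    if keep.sum() < 3:
        raise ValueError("weighted median requires >= 3 instruments with bx != 0")
    bx, se_bx = h.bx[keep], h.se_bx[keep]
    by, se_by = h.by[keep], h.se_by[keep]
    w = bx**2 / se_by**2
    est = _wme_point(bx, by, se_by, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, se_bx)
        bys = rng.normal(by, se_by)
        ok = bxs != 0
        boots[b] = _wme_point(bxs[ok], bys[ok], se_by[ok], bxs[ok] ** 2 / se_by[ok] ** 2)
    se = float(np.std(boots, ddof=1))
    note = f"dropped {dropped} zero-bx instruments" if dropped else ""
    if se == 0:
        return MREstimate("wme", est, 0.0, 0.0 if est != 0 else 1.0, int(keep.sum()), note=note)
    return _estimate("wme", est, se, int(keep.sum()), note=note)


def meta_fixed(estimates: Sequence[MREstimate]) -> MREstimate:
    """Fixed-effect inverse-variance pooling of MR estimates."""
    if len(estimates) == 0:
        raise ValueError("nothing to pool")
    if len(estimates) == 1:
        return replace(estimates[0], method="meta", note="single estimate; returned unchanged")
    w = np.array([1.0 / e.se**2 for e in estimates])
    b = np.array([e.beta for e in estimates])
    beta = float((w * b).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    return _estimate("meta", beta, se, max(e.n_snps for e in estimates))


def rerun_excluding(
    h: HarmonizedInstruments, exclude_ids, method: str = "ivw", **kwargs
) -> MREstimate:
    """Re-run an MR estimator after excluding named instruments."""
    sub = h.drop(list(exclude_ids))
    if len(sub) < 1:
        raise ValueError("all instruments excluded")
    fn = {"ivw": ivw, "egger": egger, "wme": weighted_median}[method]
    est = fn(sub, **kwargs)
    excluded = sorted(set(exclude_ids) & set(h.snps))
    return replace(est, note=(est.note + "; " if est.note else "") + f"excluded={excluded}")


def overlap_bias(
    overlap_fraction: float,
    confounded_assoc: float,
    f_stat: float,
    alpha: float = 0.05,
    se: float | None = None,
) -> OverlapBias:
    """Expected bias of the IV estimate from overlapping samples.

    Uses the first-order approximation bias = overlap * confounded
    observational association / F.  If an estimator SE is supplied, the
    approximate type-I error rate of the biased estimator under the null
    is computed from the normal shift bias/se.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    if f_stat <= 0:
        raise ValueError("f_stat must be positive")
    bias = overlap_fraction * confounded_assoc / f_stat
    type1 = None
    if se is not None:
        from scipy import stats as sps

        z = sps.norm.ppf(1.0 - alpha / 2.0)
        shift = bias / se
        type1 = float(sps.norm.sf(z - shift) + sps.norm.cdf(-z - shift))
    return OverlapBias(
        overlap_fraction=float(overlap_fraction),
        confounded_assoc=float(confounded_assoc),
        f_stat=float(f_stat),
        bias=float(bias),
        type1=type1,
    )
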