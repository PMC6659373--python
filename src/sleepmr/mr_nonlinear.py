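"""Non-linear MR by residual stratification and piecewise-linear fits.

The sample is stratified on the IV-free residual (exposure minus its
genetic prediction), a localized average causal effect (LACE) is
estimated in each stratum as the ratio of the within-stratum
score-outcome and score-exposure regressions, and the LACEs become the
segment slopes of a continuity-constrained piecewise-linear
exposure-outcome curve anchored at a reference exposure.  Non-linearity
is tested with Cochran's Q over the LACEs and a quadratic
(meta-regression) test of LACE against stratum mean exposure.  A
Monte-Carlo de-discretization harness handles exposures reported on a
coarse integer grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from ._stats import two_sided_p, simple_slope

__all__ = [
    "StratumResult",
    "NonlinearResult",
    "iv_free_residuals",
    "stratify",
    "lace_per_stratum",
    "piecewise_curve",
    "cochran_q",
    "quadratic_test",
    "dediscretize",
    "nonlinear_mr",
    "dediscretized_nonlinear",
]


@dataclass(frozen=True)
class StratumResult:
    index: int
    exposure_range: tuple[float, float]
    mean_exposure: float
    lace: float
    se: float
    n: int
    estimable: bool = True


@dataclass
class NonlinearResult:
    strata: list[StratumResult]
    q_stat: float
    q_p: float
    quad_slope: float
    quad_p: float
    curve: list[tuple[float, float]] | None
    x_ref: float
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "strata": [
                {
                    "index": s.index,
                    "exposure_range": list(s.exposure_range),
                    "mean_exposure": s.mean_exposure,
                    "lace": s.lace,
                    "se": s.se,
                    "n": s.n,
                    "estimable": s.estimable,
                }
                for s in self.strata
            ],
            "q_stat": self.q_stat,
            "q_p": self.q_p,
            "quad_slope": self.quad_slope,
            "quad_p": self.quad_p,
            "curve": None if self.curve is None else [list(k) for k in self.curve],
            "x_ref": self.x_ref,
            "note": self.note,
        }


def iv_free_residuals(exposure, score) -> np.ndarray:
    """Residual of the simple regression of exposure on the genetic score."""
    x = np.asarray(exposure, dtype=np.float64)
    s = np.asarray(score, dtype=np.float64)
    if np.var(s) == 0:
        raise ValueError("score is constant")
    slope, _ = simple_slope(s, x)
    intercept = x.mean() - slope * s.mean()
    return x - (intercept + slope * s)


def stratify(residuals, q: int) -> np.ndarray:
    """Quantile-based near-equal strata by residual rank (stable ties)."""
    r = np.asarray(residuals, dtype=np.float64)
    n = r.shape[0]
    if q < 2:
        raise ValueError("q must be >= 2")
    if n < 10 * q:
        raise ValueError(f"need at least {10 * q} individuals for {q} strata")
    order = np.argsort(r, kind="stable")
    labels = np.empty(n, dtype=np.int64)
    bounds = np.linspace(0, n, q + 1).round().astype(int)
    for k in range(q):
        labels[order[bounds[k] : bounds[k + 1]]] = k
    return labels


def lace_per_stratum(
    exposure,
    outcome,
    score,
    labels,
    min_stratum: int = 100,
    ranges: list[tuple[float, float]] | None = None,
    full_sample_bx: float | None = None,
) -> list[StratumResult]:
    """Localized average causal effects, one per stratum.

    LACE_k = (score->outcome slope in stratum k) / (score->exposure
    slope), with the denominator stratum-specific by default or the
    full-sample slope when ``full_sample_bx`` is given.  First-order
    SE = se(score->outcome) / |denominator|.  Strata below
    ``min_stratum`` or with a zero denominator are flagged
    non-estimable.
    """
    x = np.asarray(exposure, dtype=np.float64)
    y = np.asarray(outcome, dtype=np.float64)
    s = np.asarray(score, dtype=np.float64)
    labels = np.asarray(labels)
    out = []
    for k in sorted(np.unique(labels)):
        m = labels == k
        n_k = int(m.sum())
        rng_k = ranges[k] if ranges is not None else (float(x[m].min()), float(x[m].max()))
        mean_x = float(x[m].mean())
        if n_k < max(min_stratum, 3) or np.var(s[m]) == 0:
            out.append(StratumResult(int(k), rng_k, mean_x, np.nan, np.nan, n_k, False))
            continue
        if full_sample_bx is None:
            bx, _ = simple_slope(s[m], x[m])
        else:
            bx = full_sample_bx
        by, se_by = simple_slope(s[m], y[m])
        if bx == 0 or not np.isfinite(bx):
            out.append(StratumResult(int(k), rng_k, mean_x, np.nan, np.nan, n_k, False))
            continue
        out.append(
            StratumResult(int(k), rng_k, mean_x, by / bx, se_by / abs(bx), n_k, True)
        )
    return out


def piecewise_curve(
    strata: list[StratumResult], x_ref: float
) -> list[tuple[float, float]] | None:
    """Continuity-constrained piecewise-linear curve over the stratum
    exposure ranges, shifted so the value at ``x_ref`` is zero.

    Returns None if any stratum is non-estimable (curve gap).
    """
    if len(strata) < 1:
        raise ValueError("no strata")
    if any(not s.estimable for s in strata):
        return None
    strata = sorted(strata, key=lambda s: s.exposure_range[0])
    xs = [strata[0].exposure_range[0]]
    ys = [0.0]
    for s in strata:
        lo, hi = s.exposure_range
        xs.append(hi)
        ys.append(ys[-1] + s.lace * (hi - lo))
    y_ref = float(np.interp(x_ref, xs, ys))
    return [(float(x), float(y - y_ref)) for x, y in zip(xs, ys)]


def cochran_q(strata: list[StratumResult]) -> tuple[float, float]:
    """Cochran's Q heterogeneity test over the stratum LACEs."""
    est = [s for s in strata if s.estimable]
    if len(est) < 2:
        raise ValueError("Cochran's Q requires >= 2 estimable strata")
    laces = np.array([s.lace for s in est])
    ses = np.array([s.se for s in est])
    if np.any(ses == 0):
        if np.allclose(laces, laces[0]):
            return 0.0, 1.0
        return float("inf"), 0.0
    w = 1.0 / ses**2
    pooled = float((w * laces).sum() / w.sum())
    q = float(((laces - pooled) ** 2 * w).sum())
    p = float(sps.chi2.sf(q, len(est) - 1))
    return q, p


def quadratic_test(strata: list[StratumResult]) -> tuple[float, float]:
    """Quadratic (dose-response curvature) test.

    Inverse-variance-weighted meta-regression of LACE on stratum mean
    exposure; under a quadratic exposure-outcome model the LACE gradient
    is linear in exposure, so a non-zero slope indicates curvature.
    Returns (slope, two-sided p).
    """
    est = [s for s in strata if s.estimable]
    if len(est) < 3:
        raise ValueError("quadratic test requires >= 3 estimable strata")
    laces = np.array([s.lace for s in est])
    ses = np.array([s.se for s in est])
    xs = np.array([s.mean_exposure for s in est])
    if np.any(ses == 0):
        ses = np.where(ses == 0, 1e-12, ses)
    w = 1.0 / ses**2
    mx = float((w * xs).sum() / w.sum())
    sxx = float((w * (xs - mx) ** 2).sum())
    if sxx == 0:
        raise ValueError("no spread in stratum mean exposures")
    my = float((w * laces).sum() / w.sum())
    slope = float((w * (xs - mx) * (laces - my)).sum() / sxx)
    se = 1.0 / np.sqrt(sxx)
    return slope, float(two_sided_p(slope / se))


def dediscretize(hours, seed, width: float = 1.0) -> np.ndarray:
    """Add uniform(-width/2, width/2) jitter to an integer-valued exposure."""
    if width <= 0:
        raise ValueError("width must be positive")
    h = np.asarray(hours, dtype=np.float64)
    if not np.allclose(h, np.rint(h)):
        raise ValueError("exposure is not integer-valued")
    rng = np.random.default_rng(seed)
    return h + rng.uniform(-width / 2.0, width / 2.0, size=h.shape)


def nonlinear_mr(
    exposure,
    outcome,
    score,
    q: int = 3,
    min_stratum: int = 100,
    x_ref: float | None = None,
    full_sample_denominator: bool = False,
) -> NonlinearResult:
    """Full residual-stratified non-linear MR fit.

    ``q=1`` is allowed as a degenerate single-stratum fit (then the LACE
    equals the full-sample score-instrumented ratio estimate and the
    non-linearity tests are undefined).
    """
    x = np.asarray(exposure, dtype=np.float64)
    y = np.asarray(outcome, dtype=np.float64)
    s = np.asarray(score, dtype=np.float64)
    resid = iv_free_residuals(x, s)
    if q == 1:
        labels = np.zeros(x.shape[0], dtype=np.int64)
    else:
        labels = stratify(resid, q)
    boundaries = np.quantile(x, np.linspace(0.0, 1.0, q + 1))
    ranges = [(float(boundaries[k]), float(boundaries[k + 1])) for k in range(q)]
    full_bx = simple_slope(s, x)[0] if full_sample_denominator else None
    strata = lace_per_stratum(
        x, y, s, labels, min_stratum=min_stratum, ranges=ranges, full_sample_bx=full_bx
    )
    x_ref = float(np.mean(x)) if x_ref is None else float(x_ref)
    note = ""
    try:
        q_stat, q_p = cochran_q(strata)
    except ValueError as e:
        q_stat, q_p = np.nan, np.nan
        note = str(e)
    try:
        quad_slope, quad_p = quadratic_test(strata)
    except ValueError as e:
        quad_slope, quad_p = np.nan, np.nan
        note = (note + "; " if note else "") + str(e)
    curve = piecewise_curve(strata, x_ref)
    if curve is None:
        note = (note + "; " if note else "") + "curve gap: non-estimable stratum"
    return NonlinearResult(strata, q_stat, q_p, quad_slope, quad_p, curve, x_ref, note)


def dediscretized_nonlinear(
    exposure,
    outcome,
    score,
    q: int = 10,
    reps: int = 100,
    width: float = 1.0,
    seed: int = 0,
    **kwargs,
) -> NonlinearResult:
    """Monte-Carlo de-discretization harness.

    Repeats the full non-linear fit ``reps`` times on jittered copies of
    the integer exposure and aggregates: mean LACE / SE / mean exposure
    per stratum, median Q and quadratic p-values, and a curve rebuilt
    from the averaged strata.
    """
    ss = np.random.SeedSequence(seed)
    fits = []
    for child in ss.spawn(reps):
        x_j = dediscretize(exposure, np.random.default_rng(child), width=width)
        fits.append(nonlinear_mr(x_j, outcome, score, q=q, **kwargs))
    strata = []
    for k in range(q):
        members = [f.strata[k] for f in fits if f.strata[k].estimable]
        if not members:
            proto = fits[0].strata[k]
            strata.append(StratumResult(k, proto.exposure_range, proto.mean_exposure,
                                        np.nan, np.nan, proto.n, False))
            continue
        strata.append(
            StratumResult(
                k,
                (
                    float(np.mean([s.exposure_range[0] for s in members])),
                    float(np.mean([s.exposure_range[1] for s in members])),
                ),
                float(np.mean([s.mean_exposure for s in members])),
                float(np.mean([s.lace for s in members])),
                float(np.mean([s.se for s in members])),
                members[0].n,
                True,
            )
        )
    x_ref = float(np.mean([f.x_ref for f in fits]))
    q_p = float(np.median([f.q_p for f in fits]))
    q_stat = float(np.median([f.q_stat for f in fits]))
    quad_p = float(np.median([f.quad_p for f in fits]))
    quad_slope = float(np.mean([f.quad_slope for f in fits]))
    curve = piecewise_curve(strata, x_ref)
    return NonlinearResult(
        strata, q_stat, q_p, quad_slope, quad_p, curve, x_ref,
        note=f"de-discretized aggregate of {reps} jittered fits (width={width})",
    )
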