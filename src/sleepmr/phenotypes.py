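"""Derived analysis variables and the observational analyses.

Raw cohort columns are turned into the variables the MR machinery and
the descriptive tables consume: natural-log cognitive scores, ordered
categorical sleep bins with 7 h/day as reference, standardized
regression-based (SRB) cognitive-decline flags, ICD-style code-list
dementia flags, and linear/logistic observational fits reported as
exponentiated effects.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from ._stats import Z95, two_sided_p

__all__ = [
    "SLEEP_CATEGORIES",
    "REFERENCE_CATEGORY",
    "DEFAULT_COVARIATES",
    "transform_scores",
    "categorize_sleep",
    "srb_decline",
    "dementia_from_codes",
    "observational_fit",
    "describe_by_category",
    "derive_phenotypes",
]

SLEEP_CATEGORIES = ["<=5", "6", "7", "8", "9", ">=10"]
REFERENCE_CATEGORY = "7"
ANALYSIS_RANGE = (2, 12)
DEFAULT_COVARIATES = ["age", "sex", "deprivation", "bmi", "comorbidity"]


def transform_scores(vm_errors, rt_ms):
    """Natural-log transforms: ln(errors + 1) and ln(milliseconds)."""
    vm = np.asarray(vm_errors, dtype=np.float64)
    rt = np.asarray(rt_ms, dtype=np.float64)
    if np.any(vm[~np.isnan(vm)] < 0):
        raise ValueError("vm_errors must be non-negative")
    if np.any(rt[~np.isnan(rt)] <= 0):
        raise ValueError("rt_ms must be positive")
    return np.log1p(vm), np.log(rt)


def categorize_sleep(hours) -> pd.Categorical:
    """Ordered sleep categories <=5, 6, 7, 8, 9, >=10 hours/day.

    Values outside the analysis range 2-12 are flagged out-of-range and
    returned as missing.
    """
    h = pd.Series(np.asarray(hours, dtype=np.float64))
    lo, hi = ANALYSIS_RANGE
    valid = h.between(lo, hi)
    lab = pd.Series(pd.NA, index=h.index, dtype="object")
    lab[valid & (h <= 5)] = "<=5"
    lab[valid & (h >= 10)] = ">=10"
    for v in (6, 7, 8, 9):
        lab[valid & (h == v)] = str(v)
    return pd.Categorical(lab, categories=SLEEP_CATEGORIES, ordered=True)


def srb_decline(
    baseline,
    followup,
    worse_direction: str = "higher",
    z_threshold: float = 1.645,
    covariates=None,
):
    """Standardized regression-based decline classification.

    Follow-up scores are regressed on baseline (optionally plus
    covariates) over complete pairs; the standardized residual
    z = (observed - predicted) / residual SD (denominator df = n - p)
    defines a case when it falls beyond ``z_threshold`` in the worsening
    direction.  Returns a float array with 0/1 for complete pairs and
    NaN where either assessment is missing.
    """
    if worse_direction not in ("higher", "lower"):
        raise ValueError("worse_direction must be 'higher' or 'lower'")
    b = np.asarray(baseline, dtype=np.float64)
    f = np.asarray(followup, dtype=np.float64)
    mask = np.isfinite(b) & np.isfinite(f)
    if mask.sum() < 3:
        raise ValueError("need at least 3 complete baseline/follow-up pairs")
    X = b[mask][:, None]
    if covariates is not None:
        C = np.asarray(covariates, dtype=np.float64)
        X = np.column_stack([X, C[mask]])
    if np.var(b[mask]) == 0:
        raise ValueError("baseline scores have zero variance (degenerate design)")
    Xd = sm.add_constant(X)
    fit = sm.OLS(f[mask], Xd).fit()
    resid = fit.resid
    df = mask.sum() - Xd.shape[1]
    sd = np.sqrt(float(resid @ resid) / df) if df > 0 else np.nan
    out = np.full(b.shape, np.nan)
    if sd == 0 or not np.isfinite(sd):
        out[mask] = 0.0
        return out
    z = resid / sd
    case = z > z_threshold if worse_direction == "higher" else z < -z_threshold
    out[mask] = case.astype(np.float64)
    return out


def dementia_from_codes(
    records, code_list: Iterable[str], index=None
) -> pd.Series:
    """Flag cases by ICD-style prefix matching of diagnosis codes.

    ``records`` is either a long DataFrame with columns (id, code) or a
    mapping id -> iterable of codes.  ``index`` gives the universe of
    linked individuals; anyone in it without a qualifying code is a
    non-case (individuals without linkage should simply not be passed).
    """
    prefixes = tuple(str(c) for c in code_list)
    if not prefixes:
        raise ValueError("code_list must be non-empty")
    if isinstance(records, pd.DataFrame):
        grouped: Mapping = records.groupby("id")["code"].apply(list).to_dict()
    else:
        grouped = dict(records)
    if index is None:
        index = sorted(grouped)
    flags = pd.Series(0, index=pd.Index(index, name="id"), dtype=np.int64)
    for pid in flags.index:
        codes = grouped.get(pid, ())
        if any(str(c).startswith(prefixes) for c in codes):
            flags.loc[pid] = 1
    return flags


def derive_phenotypes(pheno: pd.DataFrame, z_threshold: float = 1.645) -> pd.DataFrame:
    """Standard derivation pass over a simulated cohort table.

    Adds log scores, the sleep category, and SRB decline flags (on the
    log scale, higher = worse) where repeated assessments exist.
    """
    out = pheno.copy()
    log_vm, log_rt = transform_scores(out["vm_errors"], out["rt_ms"])
    out["log_vm"] = log_vm
    out["log_rt"] = log_rt
    out["sleep_cat"] = categorize_sleep(out["sleep_hours"])
    if "vm_errors_2" in out:
        out["decline_vm"] = srb_decline(
            np.log1p(out["vm_errors"]), np.log1p(out["vm_errors_2"]),
            z_threshold=z_threshold,
        )
    if "rt_ms_2" in out:
        out["decline_rt"] = srb_decline(
            np.log(out["rt_ms"]), np.log(out["rt_ms_2"]), z_threshold=z_threshold
        )
    return out


def _is_binary(y: pd.Series) -> bool:
    vals = set(pd.unique(y.dropna()))
    return vals <= {0, 1, 0.0, 1.0}


def observational_fit(
    data: pd.DataFrame,
    outcome: str,
    exposure_form: str = "categorical",
    adjusted: bool = False,
    covariates: Sequence[str] = tuple(DEFAULT_COVARIATES),
) -> pd.DataFrame:
    """Observational association of sleep duration with one outcome.

    Linear regression for continuous (log-scale) outcomes, logistic for
    binary; complete-case on the outcome, exposure and (if adjusted) the
    covariates.  Effects are reported exponentiated: multiplicative
    effects for log outcomes, odds ratios for binary.  The reference
    category (7 h/day) is included with effect 1 by construction;
    categories that are non-estimable (zero cases for a binary outcome)
    get NaN effects with a note.
    """
    if exposure_form not in ("categorical", "discrete"):
        raise ValueError("exposure_form must be 'categorical' or 'discrete'")
    cols = [outcome]
    if exposure_form == "categorical":
        if "sleep_cat" not in data:
            data = data.assign(sleep_cat=categorize_sleep(data["sleep_hours"]))
        cols.append("sleep_cat")
    else:
        cols.append("sleep_hours")
    covs = [c for c in covariates if c in data.columns] if adjusted else []
    df = data[cols + covs].dropna()
    y = df[outcome].to_numpy(dtype=np.float64)
    binary = _is_binary(df[outcome])
    model_label = "adjusted" if adjusted else "unadjusted"

    rows = []
    bad_terms: list[str] = []
    if exposure_form == "categorical":
        terms = [c for c in SLEEP_CATEGORIES if c != REFERENCE_CATEGORY]
        X = pd.DataFrame(
            {t: (df["sleep_cat"] == t).astype(np.float64) for t in terms},
            index=df.index,
        )
        if binary:
            for t in terms:
                sub = y[X[t].to_numpy() == 1.0]
                if sub.size == 0 or sub.sum() == 0 or sub.sum() == sub.size:
                    bad_terms.append(t)
            X = X.drop(columns=bad_terms)
            terms = [t for t in terms if t not in bad_terms]
    else:
        terms = ["per_hour"]
        X = pd.DataFrame({"per_hour": df["sleep_hours"].astype(np.float64)})
    for c in covs:
        X[c] = df[c].to_numpy(dtype=np.float64)
    Xd = sm.add_constant(X.to_numpy(), has_constant="add")
    if binary:
        fit = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
    else:
        fit = sm.OLS(y, Xd).fit()
    params = fit.params[1 : 1 + len(terms)]
    ses = fit.bse[1 : 1 + len(terms)]

    if exposure_form == "categorical":
        rows.append(
            dict(outcome=outcome, model=model_label, term=REFERENCE_CATEGORY,
                 effect=1.0, lcl=np.nan, ucl=np.nan, p=np.nan, note="reference")
        )
    for t, b, s in zip(terms, params, ses):
        lcl, ucl = b - Z95 * s, b + Z95 * s
        rows.append(
            dict(outcome=outcome, model=model_label, term=t,
                 effect=float(np.exp(b)), lcl=float(np.exp(lcl)),
                 ucl=float(np.exp(ucl)), p=float(two_sided_p(b / s)) if s > 0 else 0.0,
                 note="")
        )
    for t in bad_terms:
        rows.append(
            dict(outcome=outcome, model=model_label, term=t, effect=np.nan,
                 lcl=np.nan, ucl=np.nan, p=np.nan, note="non-estimable")
        )
    out = pd.DataFrame(rows)
    if exposure_form == "categorical":
        order = {c: i for i, c in enumerate(SLEEP_CATEGORIES)}
        out = out.sort_values("term", key=lambda s: s.map(order)).reset_index(drop=True)
    return out


def _fmt_mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.2f} ± {np.std(x, ddof=1):.2f}" if x.size > 1 else "-"


def describe_by_category(
    data: pd.DataFrame,
    continuous: Sequence[str] = (),
    binary: Sequence[str] = (),
    paired: Sequence[tuple[str, str, str]] = (),
    category_col: str = "sleep_cat",
) -> pd.DataFrame:
    """Descriptive table by sleep category with per-row test p-values.

    Continuous rows get per-category mean +/- SD and an ANOVA p-value;
    binary rows get per-category % and a chi-squared p; ``paired`` rows
    are (label, baseline_col, followup_col) triples tested with a paired
    t-test on within-individual differences.  With a single non-empty
    category the test p is missing.
    """
    cats = [c for c in SLEEP_CATEGORIES if (data[category_col] == c).any()]
    rows = []

    def groups_for(col):
        return [
            data.loc[data[category_col] == c, col].dropna().to_numpy(dtype=np.float64)
            for c in cats
        ]

    for col in continuous:
        gs = groups_for(col)
        cells = {c: _fmt_mean_sd(g) for c, g in zip(cats, gs)}
        nz = [g for g in gs if g.size > 1]
        if len(nz) >= 2 and any(np.var(g) > 0 for g in nz):
            _, p = sps.f_oneway(*nz)
        elif len(nz) >= 2:
            p = 1.0  # all-identical groups: F = 0
        else:
            p = np.nan
        rows.append({"variable": col, "type": "continuous", **cells,
                     "n": int(sum(g.size for g in gs)), "p": float(p) if p == p else np.nan})

    for col in binary:
        sub = data[[category_col, col]].dropna()
        tab = pd.crosstab(sub[category_col], sub[col])
        cells = {}
        for c in cats:
            g = sub.loc[sub[category_col] == c, col]
            cells[c] = f"{100.0 * g.mean():.1f}%" if g.size else "-"
        if tab.shape[0] >= 2 and tab.shape[1] >= 2:
            chi2, p, _, _ = sps.chi2_contingency(tab.to_numpy())
        else:
            p = np.nan
        rows.append({"variable": col, "type": "binary", **cells,
                     "n": int(len(sub)), "p": float(p) if p == p else np.nan})

    for label, bcol, fcol in paired:
        sub = data[[bcol, fcol]].dropna()
        d = sub[fcol].to_numpy(dtype=np.float64) - sub[bcol].to_numpy(dtype=np.float64)
        if d.size >= 2 and np.std(d, ddof=1) > 0:
            _, p = sps.ttest_rel(sub[fcol], sub[bcol])
        elif d.size >= 2:
            p = 1.0 if np.allclose(d, 0) else 0.0
        else:
            p = np.nan
        rows.append({"variable": label, "type": "paired",
                     "baseline": _fmt_mean_sd(sub[bcol].to_numpy(dtype=np.float64)),
                     "followup": _fmt_mean_sd(sub[fcol].to_numpy(dtype=np.float64)),
                     "n": int(d.size), "p": float(p) if p == p else np.nan})

    return pd.DataFrame(rows)
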