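"""Genetic scores, per-SNP association scans, instrument strength,
two-sample harmonization and split-sample machinery.

The module consumes/produces the tab-separated summary-statistic
dialect defined in :mod:`sleepmr.simdata` (columns SNP, effect_allele,
other_allele, eaf, beta, se, n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _stats
from .simdata import COMPLEMENT, read_summary_stats, write_summary_stats

__all__ = [
    "StrengthReport",
    "HarmonizedInstruments",
    "HarmonizationError",
    "genetic_score",
    "snp_associations",
    "strength",
    "harmonize",
    "split_sample",
    "confounder_screen",
    "read_summary_stats",
    "write_summary_stats",
]


class HarmonizationError(ValueError):
    pass


@dataclass(frozen=True)
class StrengthReport:
    """Joint instrument strength: R^2 from the multivariable regression
    of the exposure on all dosage columns and the approximation
    F = ((n - k - 1) / k) * R^2 / (1 - R^2)."""

    r2: float
    f_stat: float
    k: int
    n: int

    @property
    def r2_percent(self) -> float:
        return 100.0 * self.r2


@dataclass
class HarmonizedInstruments:
    """Allele-aligned per-SNP association pairs ready for MR.

    ``table`` has columns snp, bx, se_bx, by, se_by; every input SNP
    not present in the table appears in ``exclusions`` with a reason.
    """

    table: pd.DataFrame
    exclusions: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def bx(self) -> np.ndarray:
        return self.table["bx"].to_numpy(dtype=np.float64)

    @property
    def se_bx(self) -> np.ndarray:
        return self.table["se_bx"].to_numpy(dtype=np.float64)

    @property
    def by(self) -> np.ndarray:
        return self.table["by"].to_numpy(dtype=np.float64)

    @property
    def se_by(self) -> np.ndarray:
        return self.table["se_by"].to_numpy(dtype=np.float64)

    @property
    def snps(self) -> list[str]:
        return self.table["snp"].tolist()

    def drop(self, ids: Sequence[str]) -> "HarmonizedInstruments":
        ids = set(ids)
        keep = ~self.table["snp"].isin(ids)
        dropped = pd.DataFrame(
            {"snp": self.table.loc[~keep, "snp"], "reason": "excluded-by-user"}
        )
        return HarmonizedInstruments(
            self.table.loc[keep].reset_index(drop=True),
            pd.concat([self.exclusions, dropped], ignore_index=True),
        )


def genetic_score(dosages, weights=None) -> np.ndarray:
    """Genetic score: (optionally weighted) sum of dosages across SNPs.

    The default is the unweighted allele count sum.  Missing dosages are
    mean-imputed per SNP before summing.
    """
    D = pd.DataFrame(dosages)
    if D.shape[1] < 1:
        raise ValueError("dosage matrix must have at least one column")
    X = D.to_numpy(dtype=np.float64)
    if np.isnan(X).any():
        col_means = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = np.take(col_means, idx[1])
    if weights is None:
        return X.sum(axis=1)
    w = np.asarray(weights, dtype=np.float64)
    if w.shape[0] != X.shape[1]:
        raise ValueError("weights length must match SNP count")
    return X @ w


def snp_associations(
    dosages,
    phenotype,
    family: str = "linear",
    snp_info: Sequence | None = None,
) -> pd.DataFrame:
    """One univariable regression per SNP; returns summary statistics.

    ``family='linear'`` uses closed-form simple OLS; ``'logistic'``
    returns per-allele log-odds.  Rows with separation / non-convergence
    are dropped (flagged non-estimable).  ``snp_info`` optionally
    provides SnpSpec-like objects supplying SNP ids and allele labels
    (recommended when ``dosages`` is a bare matrix); without it, ids
    fall back to column names and alleles to A/G placeholder labels.
    """
    D = pd.DataFrame(dosages)
    y = np.asarray(phenotype, dtype=np.float64)
    mask = np.isfinite(y)
    X = D.to_numpy()[mask]
    y = y[mask]
    if y.size <= 2:
        raise ValueError("need n > 2 non-missing phenotype values")
    if np.var(y) == 0:
        raise ValueError("phenotype is constant")
    if family == "linear":
        beta, se = _stats.linear_assoc_each(X, y)
        keep = np.isfinite(beta)
    elif family == "logistic":
        beta, se, keep = _stats.logistic_assoc_each(X, y)
    else:
        raise ValueError("family must be 'linear' or 'logistic'")
    if snp_info is not None:
        if len(snp_info) != D.shape[1]:
            raise ValueError("snp_info length must match dosage columns")
        ids = [s.id for s in snp_info]
        ea = [s.effect_allele for s in snp_info]
        oa = [s.other_allele for s in snp_info]
    else:
        ids = [str(c) for c in D.columns]
        ea = ["A"] * D.shape[1]
        oa = ["G"] * D.shape[1]
    df = pd.DataFrame(
        {
            "SNP": ids,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": X.mean(axis=0) / 2.0,
            "beta": beta,
            "se": se,
            "n": y.size,
        }
    )
    return df.loc[keep].reset_index(drop=True)


def strength(exposure, dosages) -> StrengthReport:
    """Instrument strength from the joint multivariable regression."""
    X = pd.DataFrame(dosages).to_numpy(dtype=np.float64)
    y = np.asarray(exposure, dtype=np.float64)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need n > k + 1 for the joint F approximation")
    r2 = _stats.joint_r2(y, X)
    f = ((n - k - 1) / k) * r2 / (1.0 - r2)
    return StrengthReport(r2=float(r2), f_stat=float(f), k=k, n=n)


def _is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT.get(ea) == oa


def harmonize(
    gx: pd.DataFrame,
    gy: pd.DataFrame,
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedInstruments:
    """Align outcome-side alleles to the exposure side.

    Rules, per SNP present in both tables:
      * exposure-side palindromic (A/T or C/G) SNP with exposure EAF in
        the ambiguity window -> excluded ``palindromic-ambiguous``;
      * same allele pair, same orientation -> kept as-is;
      * swapped orientation -> outcome beta sign flipped (and EAF
        complemented);
      * strand-complement codings are matched the same way;
      * anything else -> excluded ``incompatible-alleles``.

    SNPs present on only one side are logged as missing.
    """
    gx = gx.set_index("SNP", drop=False)
    gy = gy.set_index("SNP", drop=False)
    if gx.index.has_duplicates or gy.index.has_duplicates:
        raise HarmonizationError("duplicate SNP ids in summary statistics")
    common = gx.index.intersection(gy.index)
    if len(common) == 0:
        raise HarmonizationError("no SNPs shared between the two tables")
    lo, hi = palindromic_eaf_window

    rows, excl = [], []
    for snp in gx.index:
        if snp not in gy.index:
            excl.append((snp, "missing-in-outcome-table"))
    for snp in gy.index:
        if snp not in gx.index:
            excl.append((snp, "missing-in-exposure-table"))

    for snp in common:
        rx, ry = gx.loc[snp], gy.loc[snp]
        ax = (rx["effect_allele"], rx["other_allele"])
        ay = (ry["effect_allele"], ry["other_allele"])
        if _is_palindromic(*ax):
            if lo <= float(rx["eaf"]) <= hi:
                excl.append((snp, "palindromic-ambiguous"))
                continue
            # resolvable palindromic SNP: orientation from allele
            # frequency (same side of 0.5 -> aligned)
            if ay in (ax, (ax[1], ax[0])):
                same_side = (float(rx["eaf"]) - 0.5) * (float(ry["eaf"]) - 0.5) >= 0
                flip = not same_side
            else:
                excl.append((snp, "incompatible-alleles"))
                continue
        else:
            comp = (COMPLEMENT[ax[0]], COMPLEMENT[ax[1]])
            if ay == ax or ay == comp:
                flip = False
            elif ay == (ax[1], ax[0]) or ay == (comp[1], comp[0]):
                flip = True
            else:
                excl.append((snp, "incompatible-alleles"))
                continue
        by = -float(ry["beta"]) if flip else float(ry["beta"])
        rows.append(
            dict(
                snp=snp,
                bx=float(rx["beta"]),
                se_bx=float(rx["se"]),
                by=by,
                se_by=float(ry["se"]),
            )
        )
    table = pd.DataFrame(rows, columns=["snp", "bx", "se_bx", "by", "se_by"])
    exclusions = pd.DataFrame(excl, columns=["snp", "reason"])
    if (table[["se_bx", "se_by"]].to_numpy() <= 0).any():
        raise HarmonizationError("non-positive SEs in harmonized table")
    return HarmonizedInstruments(table.reset_index(drop=True), exclusions)


def split_sample(cohort_or_n, seed) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint exhaustive halves (sizes differ by at most 1)."""
    if hasattr(cohort_or_n, "n"):
        n = int(cohort_or_n.n)
    elif hasattr(cohort_or_n, "__len__"):
        n = len(cohort_or_n)
    else:
        n = int(cohort_or_n)
    if n < 4:
        raise ValueError("need n >= 4 to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = n // 2
    return np.sort(perm[:half]), np.sort(perm[half:])


def confounder_screen(
    score, covariates: pd.DataFrame, threshold: float = 0.003
) -> pd.DataFrame:
    """Simple regression of each covariate on the genetic score.

    A covariate is flagged when its association p-value falls below the
    multiple-testing threshold (default 0.003, i.e. ~0.05/16 Bonferroni).
    Constant covariates are skipped with a note.
    """
    s = np.asarray(score, dtype=np.float64)
    if np.var(s) == 0:
        raise ValueError("genetic score is constant")
    rows = []
    for name in covariates.columns:
        c = covariates[name].to_numpy(dtype=np.float64)
        mask = np.isfinite(c)
        if np.var(c[mask]) == 0:
            rows.append(dict(covariate=name, beta=np.nan, se=np.nan, p=np.nan,
                             flagged=False, note="constant-covariate"))
            continue
        b, se = _stats.simple_slope(s[mask], c[mask])
        p = float(_stats.two_sided_p(b / se)) if se > 0 else 0.0
        rows.append(dict(covariate=name, beta=b, se=se, p=p,
                         flagged=bool(p < threshold), note=""))
    return pd.DataFrame(rows)
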