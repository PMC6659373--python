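"""End-to-end study orchestration.

Runs the full replica flow on a synthetic cohort: simulate -> derive
phenotypes -> descriptive and observational tables -> split-sample
linear MR (A-on-B, B-on-A, fixed-effect meta, single-sample All) ->
external two-sample MR -> residual-stratified non-linear MR.  All
randomness flows from one master seed through deterministic child-seed
derivation, and report tables are flat DataFrames suitable for CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import instruments, mr_linear, mr_nonlinear, phenotypes, simdata
from .mr_linear import MREstimate

__all__ = [
    "RunConfig",
    "ReportBundle",
    "run_study",
    "exponentiate_report",
    "load_run_config",
]

MR_ANALYSES = ("A-on-B", "B-on-A", "meta", "all")


@dataclass
class RunConfig:
    sim: simdata.SimParams
    seed: int = 0
    methods: tuple[str, ...] = ("ivw", "egger", "wme")
    linear_outcomes: tuple[str, ...] = (
        "log_vm", "log_rt", "decline_vm", "decline_rt", "dementia"
    )
    nonlinear_outcomes: tuple[str, ...] = ("log_vm", "log_rt")
    strata: int = 3
    min_stratum: int = 100
    boot: int = 500
    external: bool = True
    external_outcome: str = "dementia"
    dediscretize: bool = False
    dedisc_strata: int = 10
    dedisc_reps: int = 50
    write_cohort: bool = False
    outdir: str | None = None


@dataclass
class ReportBundle:
    table1: pd.DataFrame
    table2: pd.DataFrame
    fig2_table: pd.DataFrame
    fig3: dict
    strength: instruments.StrengthReport
    screen: pd.DataFrame
    counts: dict
    config: RunConfig

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.table1.to_csv(out / "table1.csv", index=False)
        self.table2.to_csv(out / "table2.csv", index=False)
        self.fig2_table.to_csv(out / "fig2_table.csv", index=False)
        with open(out / "fig3.json", "w") as fh:
            json.dump(self.fig3, fh, indent=2, sort_keys=True, allow_nan=True)
        log = {
            "seed": self.config.seed,
            "counts": self.counts,
            "strength": {
                "r2": self.strength.r2,
                "r2_percent": self.strength.r2_percent,
                "f_stat": self.strength.f_stat,
                "k": self.strength.k,
                "n": self.strength.n,
            },
        }
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
        self.screen.to_csv(out / "confounder_screen.csv", index=False)


def exponentiate_report(est: MREstimate) -> dict:
    """Reporting-scale view of a log/log-odds estimate.

    Returns exponentiated point estimate and CI plus a percent phrase
    ((exp(beta) - 1) as %), e.g. exp(beta) = 1.03 reads as a 3% increase
    (3% slower for reaction time, 3% more errors for visual memory).
    """
    lcl, ucl = est.ci95
    exp_beta = float(np.exp(est.beta))
    pct = (exp_beta - 1.0) * 100.0
    return {
        "exp_beta": exp_beta,
        "exp_lcl": float(np.exp(lcl)),
        "exp_ucl": float(np.exp(ucl)),
        "percent_text": f"{pct:.0f}%",
    }


def _outcome_family(df: pd.DataFrame, col: str) -> str:
    vals = set(pd.unique(df[col].dropna()))
    return "logistic" if vals <= {0, 1, 0.0, 1.0} else "linear"


def _mr_row(outcome: str, analysis: str, est: MREstimate | None, error: str = "") -> dict:
    if est is None:
        return dict(
            outcome=outcome, analysis=analysis, method="", beta=np.nan, se=np.nan,
            lcl=np.nan, ucl=np.nan, p=np.nan, exp_beta=np.nan, exp_lcl=np.nan,
            exp_ucl=np.nan, intercept=np.nan, intercept_p=np.nan, n_snps=0,
            error=error,
        )
    rep = exponentiate_report(est)
    lcl, ucl = est.ci95
    return dict(
        outcome=outcome, analysis=analysis, method=est.method, beta=est.beta,
        se=est.se, lcl=lcl, ucl=ucl, p=est.p, exp_beta=rep["exp_beta"],
        exp_lcl=rep["exp_lcl"], exp_ucl=rep["exp_ucl"],
        intercept=np.nan if est.egger_intercept is None else est.egger_intercept,
        intercept_p=np.nan if est.intercept_p is None else est.intercept_p,
        n_snps=est.n_snps, error=error,
    )


def _run_methods(h, methods, boot, seed) -> dict[str, MREstimate]:
    out = {}
    for m in methods:
        if m == "ivw":
            out[m] = mr_linear.ivw(h)
        elif m == "egger":
            out[m] = mr_linear.egger(h)
        elif m == "wme":
            out[m] = mr_linear.weighted_median(h, n_boot=boot, seed=seed)
        else:
            raise ValueError(f"unknown MR method {m!r}")
    return out


def run_study(config: RunConfig) -> ReportBundle:
    ss = np.random.SeedSequence(config.seed)
    s_sim, s_split, s_wme, s_ext, s_dedisc = (
        int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(5)
    )
    sim = replace(config.sim, seed=s_sim)
    cohort = simdata.simulate_cohort(sim)
    derived = phenotypes.derive_phenotypes(cohort.pheno)
    G = cohort.dosages.to_numpy()
    sleep = cohort.sleep_hours.astype(np.float64)
    counts: dict = {"n": cohort.n}

    # --- descriptive and observational layers ---------------------------
    table1 = phenotypes.describe_by_category(
        derived,
        continuous=["age", "deprivation", "bmi", "vm_errors", "rt_ms"],
        binary=[c for c in ("sex", "comorbidity", "decline_vm", "decline_rt", "dementia")
                if c in derived.columns],
        paired=[("vm_repeat", "vm_errors", "vm_errors_2"),
                ("rt_repeat", "rt_ms", "rt_ms_2")]
        if "vm_errors_2" in derived.columns else (),
    )
    t2_parts = []
    for col in config.linear_outcomes:
        if col not in derived.columns:
            continue
        for adj in (False, True):
            try:
                t2_parts.append(
                    phenotypes.observational_fit(derived, col, "categorical", adjusted=adj)
                )
            except Exception as e:  # pragma: no cover - defensive
                t2_parts.append(pd.DataFrame([dict(
                    outcome=col, model="adjusted" if adj else "unadjusted",
                    term="", effect=np.nan, lcl=np.nan, ucl=np.nan, p=np.nan,
                    note=f"failed: {e}")]))
    table2 = pd.concat(t2_parts, ignore_index=True) if t2_parts else pd.DataFrame()

    for col in ("decline_vm", "decline_rt", "dementia"):
        if col in derived.columns:
            v = derived[col].dropna()
            counts[col] = {"cases": int(v.sum()), "total": int(len(v))}

    # --- instruments -----------------------------------------------------
    strength = instruments.strength(sleep, G)
    score = instruments.genetic_score(cohort.dosages)
    screen = instruments.confounder_screen(
        score, derived[[c for c in phenotypes.DEFAULT_COVARIATES if c in derived.columns]]
    )

    idx_a, idx_b = instruments.split_sample(cohort, s_split)
    counts["split"] = {"A": int(idx_a.size), "B": int(idx_b.size)}
    gx = {
        "A": instruments.snp_associations(G[idx_a], sleep[idx_a], "linear", cohort.specs),
        "B": instruments.snp_associations(G[idx_b], sleep[idx_b], "linear", cohort.specs),
        "all": instruments.snp_associations(G, sleep, "linear", cohort.specs),
    }

    rows = []
    wme_seed = s_wme
    exclusion_log: dict = {}
    for col in config.linear_outcomes:
        if col not in derived.columns:
            rows.append(_mr_row(col, "missing", None, error="outcome column not present"))
            continue
        fam = _outcome_family(derived, col)
        y = derived[col].to_numpy(dtype=np.float64)
        for adj in (False, True):
            try:
                obs = phenotypes.observational_fit(derived, col, "discrete", adjusted=adj)
                r = obs.loc[obs["term"] == "per_hour"].iloc[0]
                rows.append(dict(
                    outcome=col, analysis="obs-adjusted" if adj else "obs-unadjusted",
                    method="regression", beta=float(np.log(r["effect"])),
                    se=np.nan, lcl=float(np.log(r["lcl"])), ucl=float(np.log(r["ucl"])),
                    p=float(r["p"]), exp_beta=float(r["effect"]), exp_lcl=float(r["lcl"]),
                    exp_ucl=float(r["ucl"]), intercept=np.nan, intercept_p=np.nan,
                    n_snps=0, error="",
                ))
            except Exception as e:
                rows.append(_mr_row(col, "obs-adjusted" if adj else "obs-unadjusted",
                                    None, error=str(e)))

        gy = {}
        for part, idx in (("A", idx_a), ("B", idx_b), ("all", slice(None))):
            try:
                gy[part] = instruments.snp_associations(G[idx], y[idx], fam, cohort.specs)
            except Exception as e:
                gy[part] = e
        split_results: dict[str, dict[str, MREstimate]] = {}
        for analysis, xpart, ypart in (
            ("A-on-B", "A", "B"), ("B-on-A", "B", "A"), ("all", "all", "all")
        ):
            try:
                if isinstance(gy[ypart], Exception):
                    raise gy[ypart]
                h = instruments.harmonize(gx[xpart], gy[ypart])
                exclusion_log[f"{col}:{analysis}"] = len(h.exclusions)
                ests = _run_methods(h, config.methods, config.boot, wme_seed)
                wme_seed += 1
                split_results[analysis] = ests
                for m, est in ests.items():
                    rows.append(_mr_row(col, analysis, est))
            except Exception as e:
                for m in config.methods:
                    rows.append(_mr_row(col, analysis, None, error=f"{m}: {e}"))
        try:
            if "A-on-B" not in split_results or "B-on-A" not in split_results:
                raise ValueError("both split estimates required for meta")
            for m in config.methods:
                pooled = mr_linear.meta_fixed(
                    [split_results["A-on-B"][m], split_results["B-on-A"][m]]
                )
                pooled = replace(pooled, method=m, note=f"meta of A-on-B and B-on-A ({m})")
                rows.append(_mr_row(col, "meta", pooled))
        except Exception as e:
            for m in config.methods:
                rows.append(_mr_row(col, "meta", None, error=f"{m}: {e}"))

    # --- external two-sample arm (consortium-style G-Y) ------------------
    if config.external:
        try:
            gy_ext = simdata.simulate_summary_stats(
                sim, "outcome", seed=s_ext, outcome=config.external_outcome
            )
            h = instruments.harmonize(gx["all"], gy_ext)
            ests = _run_methods(h, config.methods, config.boot, wme_seed)
            for m, est in ests.items():
                rows.append(_mr_row(f"{config.external_outcome}_external", "external", est))
        except Exception as e:
            for m in config.methods:
                rows.append(_mr_row(f"{config.external_outcome}_external", "external",
                                    None, error=f"{m}: {e}"))

    fig2 = pd.DataFrame(rows)

    # --- non-linear MR ----------------------------------------------------
    weights = gx["all"].set_index("SNP")["beta"].reindex(cohort.snp_ids).to_numpy()
    wscore = instruments.genetic_score(cohort.dosages, weights=weights)
    fig3: dict = {}
    for col in config.nonlinear_outcomes:
        if col not in derived.columns:
            fig3[col] = {"error": "outcome column not present"}
            continue
        y = derived[col].to_numpy(dtype=np.float64)
        try:
            res = mr_nonlinear.nonlinear_mr(
                sleep, y, wscore, q=config.strata, min_stratum=config.min_stratum
            )
            fig3[col] = res.to_dict()
            if config.dediscretize:
                ded = mr_nonlinear.dediscretized_nonlinear(
                    sleep, y, wscore, q=config.dedisc_strata,
                    reps=config.dedisc_reps, seed=s_dedisc,
                    min_stratum=config.min_stratum,
                )
                fig3[f"{col}_dediscretized"] = ded.to_dict()
        except Exception as e:
            fig3[col] = {"error": str(e)}

    counts["harmonization_exclusions"] = exclusion_log
    bundle = ReportBundle(table1, table2, fig2, fig3, strength, screen, counts, config)
    if config.outdir:
        bundle.write(config.outdir)
        if config.write_cohort:
            cohort.to_csv(Path(config.outdir) / "cohort.csv")
    return bundle


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file with a ``sim`` block plus
    top-level pipeline keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sim = simdata.sim_params_from_dict(raw.pop("sim"))
    for key in ("methods", "linear_outcomes", "nonlinear_outcomes"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(sim=sim, **raw)
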