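"""Synthetic biobank-style cohort and summary-statistic generator.

The generator emulates the data structure required by the downstream
Mendelian-randomization (MR) machinery: near-independent biallelic SNP
dosages under an additive model, a discrete self-reported exposure
(sleep duration in whole hours/day), a latent confounder driving both
exposure and outcomes, continuous cognitive scores analysed on the
natural-log scale (visual-memory errors, reaction time in ms), rare
binary outcomes (hospital-diagnosed dementia), and repeated assessments
with practice effects and a declining subgroup.

Default parameter values mirror published cohort summaries collected in
:data:`EMULATION_TARGETS`: mean sleep 7.17 h/day (SD 1.07) on the range
2-12, ~77 instruments jointly explaining ~0.65% of exposure variance,
and outcome prevalences of roughly 0.4-4%.

Everything is deterministic under a fixed master seed; sub-streams are
derived with :class:`numpy.random.SeedSequence` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import _stats

__all__ = [
    "BASES",
    "COMPLEMENT",
    "EMULATION_TARGETS",
    "SUMMARY_COLUMNS",
    "ParameterError",
    "SnpSpec",
    "CausalShape",
    "OutcomeSpec",
    "FollowupParams",
    "SimParams",
    "Cohort",
    "default_snp_panel",
    "default_sim_params",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_summary_stats",
    "read_summary_stats",
    "write_summary_stats",
    "sim_params_to_dict",
    "sim_params_from_dict",
    "load_sim_params",
    "dump_sim_params",
]

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Published cohort summaries the generator emulates and the reporting
#: layer can recompute proportions from.  Counts are (cases, total).
EMULATION_TARGETS = {
    "n_cohort": 395_803,
    "n_split_a": 197_902,
    "n_split_b": 197_901,
    "n_snps": 77,
    "sleep_mean": 7.17,
    "sleep_sd": 1.07,
    "sleep_range": (2, 12),
    "instrument_r2": 0.0065,
    "instrument_f": 33.86,
    "decline_vm_counts": (4089, 98_072),
    "decline_rt_counts": (622, 17_090),
    "dementia_counts": (1343, 311_903),
    "rt_baseline_ms": 549.0,
    "vm_baseline_errors": 4.0,
}

SUMMARY_COLUMNS = ["SNP", "effect_allele", "other_allele", "eaf", "beta", "se", "n"]


class ParameterError(ValueError):
    """Raised for infeasible or invalid simulation parameters."""


@dataclass(frozen=True)
class SnpSpec:
    """A biallelic instrument: alleles, frequency and true effects.

    ``beta_x`` is the per-allele effect on the exposure (hours/day,
    before the variance-targeting rescaling applied by
    :func:`simulate_cohort`); ``beta_pleio`` is a direct per-allele
    effect on outcomes, i.e. a horizontal-pleiotropy pathway.
    """

    id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta_x: float = 0.0
    beta_pleio: float = 0.0

    def __post_init__(self):
        if self.effect_allele not in BASES or self.other_allele not in BASES:
            raise ParameterError(f"{self.id}: alleles must be one of {BASES}")
        if self.effect_allele == self.other_allele:
            raise ParameterError(f"{self.id}: effect and other allele must differ")
        if not 0.0 < self.eaf < 1.0:
            raise ParameterError(f"{self.id}: eaf must be in (0, 1), got {self.eaf}")

    @property
    def palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class CausalShape:
    """Exposure-outcome dose-response on the (log/log-odds) link scale.

    ``linear``: f(x) = beta1 * (x - x0).
    ``quadratic``: f(x) = beta1*(x - x0) + beta2_side*(x - x0)^2 with an
    optionally different curvature ``beta2_high`` above the vertex
    ``x0``, giving the asymmetric J-shape (steeper long-sleep arm).
    """

    kind: str = "quadratic"
    beta1: float = 0.01
    beta2: float = 0.006
    beta2_high: float | None = 0.012
    x0: float = 7.0

    def __post_init__(self):
        if self.kind not in ("linear", "quadratic"):
            raise ParameterError(f"unknown causal shape kind {self.kind!r}")

    def value(self, x):
        d = np.asarray(x, dtype=np.float64) - self.x0
        if self.kind == "linear":
            return self.beta1 * d
        b2hi = self.beta2 if self.beta2_high is None else self.beta2_high
        b2 = np.where(d > 0, b2hi, self.beta2)
        return self.beta1 * d + b2 * d * d

    def derivative(self, x):
        d = np.asarray(x, dtype=np.float64) - self.x0
        if self.kind == "linear":
            return np.full_like(d, self.beta1)
        b2hi = self.beta2 if self.beta2_high is None else self.beta2_high
        b2 = np.where(d > 0, b2hi, self.beta2)
        return self.beta1 + 2.0 * b2 * d


@dataclass(frozen=True)
class OutcomeSpec:
    """One generated outcome column.

    family:
      * ``lognormal`` -- positive continuous, log-link (reaction time);
        ``baseline`` is the median at the reference exposure.
      * ``poisson`` -- non-negative count with log-link rate and
        lognormal overdispersion (visual-memory errors); ``baseline`` is
        the rate at the reference exposure.
      * ``bernoulli`` -- binary via logistic link with the intercept
        calibrated so the sample prevalence matches ``baseline``.

    ``effect_scale`` multiplies the shared linear predictor
    (dose-response + confounder) for this outcome; ``repeat`` adds a
    follow-up assessment column ``<name>_2``.
    """

    name: str
    family: str
    baseline: float
    noise_sd: float = 0.2
    effect_scale: float = 1.0
    repeat: bool = False

    def __post_init__(self):
        if self.family not in ("lognormal", "poisson", "bernoulli"):
            raise ParameterError(f"unknown outcome family {self.family!r}")
        if self.family == "bernoulli" and not 0.0 < self.baseline < 1.0:
            raise ParameterError(f"{self.name}: prevalence must be in (0, 1)")
        if self.family != "bernoulli" and self.baseline <= 0:
            raise ParameterError(f"{self.name}: baseline must be positive")
        if self.noise_sd < 0:
            raise ParameterError(f"{self.name}: noise_sd must be >= 0")


@dataclass(frozen=True)
class FollowupParams:
    """Repeated-assessment model: fresh noise, a practice/ageing shift
    applied to everyone, and an extra shift for a declining fraction."""

    noise_sd: float = 0.25
    practice_shift: float = 0.10
    decline_fraction: float = 0.04
    decline_shift: float = 0.9

    def __post_init__(self):
        if not 0.0 <= self.decline_fraction <= 1.0:
            raise ParameterError("decline_fraction must be in [0, 1]")


def _default_outcomes() -> tuple[OutcomeSpec, ...]:
    return (
        OutcomeSpec("vm_errors", "poisson", EMULATION_TARGETS["vm_baseline_errors"],
                    noise_sd=0.5, effect_scale=1.0, repeat=True),
        OutcomeSpec("rt_ms", "lognormal", EMULATION_TARGETS["rt_baseline_ms"],
                    noise_sd=0.2, effect_scale=0.4, repeat=True),
        OutcomeSpec("dementia", "bernoulli", 0.0043, noise_sd=0.0, effect_scale=3.0),
    )


@dataclass(frozen=True)
class SimParams:
    n: int
    snps: tuple[SnpSpec, ...]
    target_r2: float = EMULATION_TARGETS["instrument_r2"]
    exposure_mean: float = EMULATION_TARGETS["sleep_mean"]
    exposure_sd: float = EMULATION_TARGETS["sleep_sd"]
    exposure_range: tuple[int, int] = EMULATION_TARGETS["sleep_range"]
    causal_shape: CausalShape = field(default_factory=CausalShape)
    confounder_effect_x: float = 0.3
    confounder_effect_y: float = 0.04
    outcomes: tuple[OutcomeSpec, ...] = field(default_factory=_default_outcomes)
    followup: FollowupParams = field(default_factory=FollowupParams)
    seed: int = 0

    def __post_init__(self):
        if self.n <= 0:
            raise ParameterError("n must be positive")
        if not self.snps:
            raise ParameterError("at least one SNP is required")
        if not 0.0 <= self.target_r2 < 1.0:
            raise ParameterError("target_r2 must be in [0, 1)")
        lo, hi = self.exposure_range
        if not lo < hi:
            raise ParameterError("exposure_range must satisfy min < max")
        if self.exposure_sd <= 0:
            raise ParameterError("exposure_sd must be positive")
        names = [o.name for o in self.outcomes]
        if len(names) != len(set(names)):
            raise ParameterError("outcome names must be unique")
        object.__setattr__(self, "snps", tuple(self.snps))
        object.__setattr__(self, "outcomes", tuple(self.outcomes))


def default_snp_panel(
    k: int = EMULATION_TARGETS["n_snps"],
    seed: int = 0,
    eaf_range: tuple[float, float] = (0.1, 0.9),
    effect_dist: str = "exponential",
    beta_pleio_mean: float = 0.0,
    beta_pleio_sd: float = 0.0,
) -> tuple[SnpSpec, ...]:
    """Build a panel of k independent instruments.

    Effect magnitudes are exponential by default (a heavy-tailed,
    GWAS-like distribution of per-allele effects) and oriented so the
    effect allele increases the exposure; ``effect_dist='constant'``
    gives homogeneous effects.  Absolute scale is irrelevant because
    :func:`simulate_cohort` rescales effects to hit ``target_r2``.
    """
    rng = np.random.default_rng(seed)
    eafs = rng.uniform(*eaf_range, size=k)
    if effect_dist == "exponential":
        betas = rng.exponential(1.0, size=k)
    elif effect_dist == "shifted_exponential":
        # heavy-tailed but bounded away from zero: every instrument's
        # orientation is unambiguous even when estimated with noise
        betas = 1.0 + rng.exponential(1.0, size=k)
    elif effect_dist == "constant":
        betas = np.ones(k)
    else:
        raise ParameterError(f"unknown effect_dist {effect_dist!r}")
    pleio = beta_pleio_mean + beta_pleio_sd * rng.standard_normal(k)
    specs = []
    for i in range(k):
        ea, oa = rng.choice(BASES, size=2, replace=False)
        specs.append(SnpSpec(f"rs{i + 1:06d}", str(ea), str(oa),
                             float(eafs[i]), float(betas[i]), float(pleio[i])))
    return tuple(specs)


def default_sim_params(n: int, seed: int = 0, k: int = EMULATION_TARGETS["n_snps"],
                       panel_seed: int = 0, **overrides) -> SimParams:
    """SimParams with the emulation-target defaults and a stable panel."""
    snps = overrides.pop("snps", None) or default_snp_panel(k, seed=panel_seed)
    return SimParams(n=n, snps=tuple(snps), seed=seed, **overrides)


def _rng_of(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genotypes(specs: Sequence[SnpSpec], n: int, seed) -> pd.DataFrame:
    """Additive dosages: one binomial(2, eaf) column per SNP."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not specs:
        raise ParameterError("specs must be non-empty")
    rng = _rng_of(seed)
    mat = np.empty((n, len(specs)), dtype=np.int8)
    for j, s in enumerate(specs):
        mat[:, j] = rng.binomial(2, s.eaf, size=n)
    return pd.DataFrame(mat, columns=[s.id for s in specs])


@dataclass
class Cohort:
    """Individual-level synthetic cohort.

    ``dosages`` holds the n x k SNP matrix, ``pheno`` the exposure,
    covariates, outcomes and repeats; ``truth`` records the generating
    quantities (scaled per-SNP effects, confounder draw, latent
    exposure, decliner flags) for recovery tests.
    """

    dosages: pd.DataFrame
    pheno: pd.DataFrame
    specs: tuple[SnpSpec, ...]
    truth: dict

    @property
    def n(self) -> int:
        return len(self.pheno)

    @property
    def sleep_hours(self) -> np.ndarray:
        return self.pheno["sleep_hours"].to_numpy()

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def to_csv(self, path) -> None:
        df = self.pheno.copy()
        df.insert(0, "id", np.arange(len(df)))
        df = pd.concat([df, self.dosages.reset_index(drop=True)], axis=1)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, snp_prefix: str = "rs") -> "Cohort":
        df = pd.read_csv(path)
        snp_cols = [c for c in df.columns if c.startswith(snp_prefix)]
        pheno_cols = [c for c in df.columns if c not in snp_cols and c != "id"]
        return cls(df[snp_cols].copy(), df[pheno_cols].copy(), (), {})


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Logistic intercept so that mean(expit(b0 + eta)) == prevalence."""
    from scipy.optimize import brentq
    from scipy.special import expit

    def f(b0):
        return float(np.mean(expit(b0 + eta))) - prevalence

    return float(brentq(f, -40.0, 40.0, xtol=1e-10))


def simulate_cohort(params: SimParams) -> Cohort:
    """Generate a full cohort under ``params``.

    The latent exposure is a sum of the (rescaled) genetic component,
    the confounder contribution and Gaussian noise; per-SNP effects are
    rescaled so the theoretical SNP-explained variance equals
    ``target_r2 * exposure_sd**2``.  The latent value is rounded and
    clamped to integer hours *before* outcome generation, so the
    measured, self-report-granular exposure drives the outcomes.
    """
    ss = np.random.SeedSequence(params.seed)
    (s_geno, s_conf, s_noise, s_cov, s_out, s_follow) = ss.spawn(6)
    rng_conf = np.random.default_rng(s_conf)
    rng_noise = np.random.default_rng(s_noise)
    rng_cov = np.random.default_rng(s_cov)
    rng_follow = np.random.default_rng(s_follow)

    n = params.n
    specs = params.snps
    dosages = simulate_genotypes(specs, n, np.random.default_rng(s_geno))
    G = dosages.to_numpy()

    beta_raw = np.array([s.beta_x for s in specs])
    eaf = np.array([s.eaf for s in specs])
    vg = 2.0 * eaf * (1.0 - eaf)
    var_g = float((beta_raw ** 2 * vg).sum())
    var_x = params.exposure_sd ** 2
    if params.target_r2 > 0:
        if var_g <= 0:
            raise ParameterError("target_r2 > 0 but all SNP effects are zero")
        scale = np.sqrt(params.target_r2 * var_x / var_g)
    else:
        scale = 0.0
    bx_true = scale * beta_raw

    resid_var = var_x * (1.0 - params.target_r2) - params.confounder_effect_x ** 2
    if resid_var < 0:
        raise ParameterError(
            "infeasible variance budget: target_r2 and confounder_effect_x "
            "exceed exposure variance"
        )

    U = rng_conf.standard_normal(n)
    genetic = (G @ bx_true) - float((bx_true * 2.0 * eaf).sum())
    latent = (
        params.exposure_mean
        + genetic
        + params.confounder_effect_x * U
        + np.sqrt(resid_var) * rng_noise.standard_normal(n)
    )
    lo, hi = params.exposure_range
    sleep = np.clip(np.rint(latent), lo, hi).astype(np.int64)

    # Covariates as noisy functions of the shared confounder (plus sex,
    # independent), so adjustment and the score-confounder screen have
    # realistic structure to work against.
    from scipy.special import expit, logit
    age = 56.9 + 8.0 * (0.25 * U + np.sqrt(1 - 0.25 ** 2) * rng_cov.standard_normal(n))
    sex = (rng_cov.random(n) < 0.54).astype(np.int64)  # 1 = female
    deprivation = -1.6 + 2.9 * (0.2 * U + np.sqrt(1 - 0.2 ** 2) * rng_cov.standard_normal(n))
    bmi = 27.4 + 4.7 * (0.3 * U + np.sqrt(1 - 0.3 ** 2) * rng_cov.standard_normal(n))
    comorbidity = (rng_cov.random(n) < expit(logit(0.387) + 0.5 * U)).astype(np.int64)

    pheno = pd.DataFrame(
        {
            "sleep_hours": sleep,
            "age": age,
            "sex": sex,
            "deprivation": deprivation,
            "bmi": bmi,
            "comorbidity": comorbidity,
        }
    )

    pleio = np.array([s.beta_pleio for s in specs])
    direct = G @ pleio if np.any(pleio != 0) else 0.0
    shape_val = params.causal_shape.value(sleep)
    shared = shape_val + params.confounder_effect_y * U

    decliners = rng_follow.random(n) < params.followup.decline_fraction
    truth: dict = {
        "params": params,
        "beta_x_scaled": bx_true,
        "beta_pleio": pleio,
        "confounder": U,
        "latent_exposure": latent,
        "decliners": decliners,
        "intercepts": {},
    }

    for spec in params.outcomes:
        rng_o = np.random.default_rng(s_out.spawn(1)[0])
        eta = spec.effect_scale * shared + direct
        if spec.family == "lognormal":
            y = np.exp(np.log(spec.baseline) + eta + spec.noise_sd * rng_o.standard_normal(n))
        elif spec.family == "poisson":
            lam = spec.baseline * np.exp(eta + spec.noise_sd * rng_o.standard_normal(n))
            y = rng_o.poisson(lam).astype(np.int64)
        else:  # bernoulli
            b0 = _calibrate_intercept(eta, spec.baseline)
            truth["intercepts"][spec.name] = b0
            y = (rng_o.random(n) < expit(b0 + eta)).astype(np.int64)
        pheno[spec.name] = y
        if spec.repeat and spec.family != "bernoulli":
            fu = params.followup
            # follow-up shifts scale with the outcome's sensitivity so a
            # single global FollowupParams yields realistic per-outcome
            # drift (memory errors drift proportionally more than RT)
            eta2 = eta + spec.effect_scale * (
                fu.practice_shift
                + fu.decline_shift * decliners
                + fu.noise_sd * rng_o.standard_normal(n)
            )
            if spec.family == "lognormal":
                y2 = np.exp(np.log(spec.baseline) + eta2 + spec.noise_sd * rng_o.standard_normal(n))
            else:
                lam2 = spec.baseline * np.exp(eta2 + spec.noise_sd * rng_o.standard_normal(n))
                y2 = rng_o.poisson(lam2).astype(np.int64)
            pheno[f"{spec.name}_2"] = y2

    return Cohort(dosages, pheno, specs, truth)


def simulate_summary_stats(
    params: SimParams, side: str, seed: int, outcome: str | None = None
) -> pd.DataFrame:
    """Per-SNP univariable association estimates from a fresh pseudo-sample.

    ``side='exposure'`` regresses the discrete exposure on each SNP;
    ``side='outcome'`` regresses the named outcome (log-transformed for
    the continuous families, log-odds via logistic regression for
    binary).  Different seeds give non-overlapping pseudo-samples, which
    is how a two-sample design is emulated.
    """
    if side not in ("exposure", "outcome"):
        raise ParameterError("side must be 'exposure' or 'outcome'")
    cohort = simulate_cohort(replace(params, seed=int(seed)))
    G = cohort.dosages.to_numpy()
    if side == "exposure":
        y = cohort.sleep_hours.astype(np.float64)
        beta, se = _stats.linear_assoc_each(G, y)
        keep = np.isfinite(beta)
    else:
        spec = _find_outcome(params, outcome)
        y = cohort.pheno[spec.name].to_numpy().astype(np.float64)
        if spec.family == "bernoulli":
            beta, se, keep = _stats.logistic_assoc_each(G, y)
        else:
            ylog = np.log1p(y) if spec.family == "poisson" else np.log(y)
            beta, se = _stats.linear_assoc_each(G, ylog)
            keep = np.isfinite(beta)
    eaf_emp = G.mean(axis=0) / 2.0
    df = pd.DataFrame(
        {
            "SNP": [s.id for s in cohort.specs],
            "effect_allele": [s.effect_allele for s in cohort.specs],
            "other_allele": [s.other_allele for s in cohort.specs],
            "eaf": eaf_emp,
            "beta": beta,
            "se": se,
            "n": cohort.n,
        }
    )
    return df.loc[keep].reset_index(drop=True)


def _find_outcome(params: SimParams, name: str | None) -> OutcomeSpec:
    if name is None:
        return params.outcomes[0]
    for o in params.outcomes:
        if o.name == name:
            return o
    raise ParameterError(f"no outcome named {name!r}")


def write_summary_stats(df: pd.DataFrame, path) -> None:
    df.loc[:, SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary-stat file missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Flat config (YAML) round-trip

def sim_params_to_dict(params: SimParams) -> dict:
    d = {
        "n": params.n,
        "target_r2": params.target_r2,
        "exposure_mean": params.exposure_mean,
        "exposure_sd": params.exposure_sd,
        "exposure_range": list(params.exposure_range),
        "causal_shape": asdict(params.causal_shape),
        "confounder_effect_x": params.confounder_effect_x,
        "confounder_effect_y": params.confounder_effect_y,
        "outcomes": [asdict(o) for o in params.outcomes],
        "followup": asdict(params.followup),
        "seed": params.seed,
        "snps": [asdict(s) for s in params.snps],
    }
    return d


def sim_params_from_dict(d: dict) -> SimParams:
    d = dict(d)
    if "snps" in d:
        snps = tuple(SnpSpec(**s) for s in d.pop("snps"))
    else:
        panel = d.pop("panel", {})
        snps = default_snp_panel(**panel)
    kwargs = {}
    if "causal_shape" in d:
        kwargs["causal_shape"] = CausalShape(**d.pop("causal_shape"))
    if "outcomes" in d:
        kwargs["outcomes"] = tuple(OutcomeSpec(**o) for o in d.pop("outcomes"))
    if "followup" in d:
        kwargs["followup"] = FollowupParams(**d.pop("followup"))
    if "exposure_range" in d:
        d["exposure_range"] = tuple(d["exposure_range"])
    return SimParams(snps=snps, **d, **kwargs)


def dump_sim_params(params: SimParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(sim_params_to_dict(params), fh, sort_keys=False)


def load_sim_params(path) -> SimParams:
    with open(path) as fh:
        return sim_params_from_dict(yaml.safe_load(fh))
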