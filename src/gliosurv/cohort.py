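"""Synthetic glioblastoma cohort generator.

Real per-patient imaging cohorts of this kind are not publicly
distributable, so every pipeline stage here is exercised against
synthetic cohorts that emulate the published summary structure:

* covariate marginals per sex — age and T1Gd radius as range-truncated
  normals (means 57.58 / 58.41 years and 19.52 / 19.27 mm for males /
  females), kinetic rates D and rho as range-truncated log-normals
  (medians 28.99 / 23.03 mm^2/year and 18.25 / 18.25 per year), the
  contrast-enhancing rim as a truncated normal;
* a 60.5% male cohort;
* overall survival from a Weibull proportional-hazards model with
  sex-specific linear predictors carrying the published multivariate
  hazard ratios — males: age (HR 1.030/year) and T1Gd radius
  (HR 1.027/mm); females: age (HR 1.021/year) and invasion rate D
  (HR 1.011 per mm^2/year).

Spreads not published are set so the untruncated +/-3 SD span matches the
published range (SD = range/6).  In parametric mode the T2/FLAIR radius
is the T1Gd radius plus the traveling-wave mismatch at the subject's
D/rho, closing the loop with the invasiveness estimator; in mechanistic
mode the three radii come from a full five-species simulation sampled at
the subject's detection size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import pi_model, pihna
from .geometry import PatientRecord, records_to_frame
from .survstats import CoxFit, fit_cox

logger = logging.getLogger("gliosurv")


@dataclass
class TruncatedNormal:
    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo < self.hi and self.sd > 0):
            raise ValueError("require lo < hi and sd > 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n,
                                   random_state=rng)


@dataclass
class TruncatedLogNormal:
    """Parametrized by the median and the printed range; SD(log) = log-range/6."""

    median: float
    lo: float
    hi: float
    log_sd: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError("require 0 < lo < hi")
        if self.log_sd is None:
            self.log_sd = (math.log(self.hi) - math.log(self.lo)) / 6.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        mu = math.log(self.median)
        a = (math.log(self.lo) - mu) / self.log_sd
        b = (math.log(self.hi) - mu) / self.log_sd
        return np.exp(
            stats.truncnorm.rvs(a, b, loc=mu, scale=self.log_sd, size=n, random_state=rng)
        )


@dataclass
class HazardTerm:
    """One proportional-hazards covariate: log-HR per unit, centered."""

    variable: str
    hazard_ratio: float
    center: float

    @property
    def log_hr(self) -> float:
        return math.log(self.hazard_ratio)


@dataclass
class SexDistributions:
    age: TruncatedNormal
    t1gd: TruncatedNormal
    ce: TruncatedNormal
    D: TruncatedLogNormal
    rho: TruncatedLogNormal
    hazard_terms: list[HazardTerm]


def default_male_distributions() -> SexDistributions:
    return SexDistributions(
        age=TruncatedNormal(57.58, (95 - 12) / 6, 12.0, 95.0),
        t1gd=TruncatedNormal(19.52, (33.61 - 3.04) / 6, 3.04, 33.61),
        ce=TruncatedNormal(8.16, (18.94 - 2.55) / 6, 0.32, 18.94),
        D=TruncatedLogNormal(28.99, 1.45, 145.3),
        rho=TruncatedLogNormal(18.25, 1.83, 1825.0),
        hazard_terms=[
            HazardTerm("age_years", 1.030, 58.0),
            HazardTerm("t1gd_radius_mm", 1.027, 19.5),
        ],
    )


def default_female_distributions() -> SexDistributions:
    return SexDistributions(
        age=TruncatedNormal(58.41, (96 - 9) / 6, 9.0, 96.0),
        t1gd=TruncatedNormal(19.27, (35.08 - 4.61) / 6, 4.61, 35.08),
        ce=TruncatedNormal(7.89, (23.26 - 0.32) / 6, 0.32, 23.26),
        D=TruncatedLogNormal(23.03, 0.37, 289.9),
        rho=TruncatedLogNormal(18.25, 1.83, 1825.0),
        hazard_terms=[
            HazardTerm("age_years", 1.021, 58.0),
            HazardTerm("pihna_D", 1.011, 30.0),
        ],
    )


DEFAULT_CATEGORY_PREVALENCES = {
    "laterality": {"left": 0.43, "right": 0.51, "bilateral": 0.04, "unknown": 0.02},
    "eor": {"GTR": 0.28, "STR": 0.28, "biopsy": 0.15, "unknown": 0.29},
    "idh1": {"mut": 0.024, "wt": 0.219, "unknown": 0.757},
    "mgmt": {"methylated": 0.061, "unmethylated": 0.121, "unknown": 0.818},
}


@dataclass
class CohortDistributions:
    male: SexDistributions = field(default_factory=default_male_distributions)
    female: SexDistributions = field(default_factory=default_female_distributions)
    male_fraction: float = 0.605
    weibull_shape: float = 1.2
    baseline_median_os_days: float = 450.0
    ratio_bounds: tuple[float, float] = (0.0034, 10.7)
    category_prevalences: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_CATEGORY_PREVALENCES.items()
    })

    def __post_init__(self) -> None:
        if not 0 < self.male_fraction < 1:
            raise ValueError("male_fraction must be in (0, 1)")
        if self.ratio_bounds[0] >= self.ratio_bounds[1]:
            raise ValueError("invalid D/rho bounds")


@dataclass
class GeneratorConfig:
    n: int = 494
    seed: int = 0
    mode: str = "parametric"  # or "mechanistic"
    distributions: CohortDistributions = field(default_factory=CohortDistributions)
    #: optional per-variable shifts applied to subjects destined for a
    #: survival group, e.g. {"age_years": {"EXS": -10.0}} — used to plant
    #: detectable effects for power checks
    planted_effects: dict = field(default_factory=dict)
    #: optional (variable, level) -> log hazard contributions for
    #: categorical covariates, e.g. {("mgmt", "methylated"): -0.7}
    categorical_log_hazards: dict = field(default_factory=dict)
    censor_horizon_days: float | None = None
    detection_radius_from_t1gd: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.mode not in ("parametric", "mechanistic"):
            raise ValueError("mode must be 'parametric' or 'mechanistic'")


def _sample_kinetics(
    sd: SexDistributions, bounds: tuple[float, float], rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Joint (D, rho) draws rejection-sampled into the observed D/rho span."""
    lo, hi = bounds
    D = np.empty(n)
    rho = np.empty(n)
    filled = 0
    while filled < n:
        d = sd.D.sample(rng, n - filled)
        r = sd.rho.sample(rng, n - filled)
        ok = (d / r >= lo) & (d / r <= hi)
        k = int(ok.sum())
        D[filled:filled + k] = d[ok]
        rho[filled:filled + k] = r[ok]
        filled += k
    return D, rho


def _weibull_ph_sample(
    rng: np.random.Generator, lp: np.ndarray, shape: float, median_days: float
) -> np.ndarray:
    scale = median_days / math.log(2.0) ** (1.0 / shape)
    u = rng.uniform(size=len(lp))
    return scale * (-np.log(u) / np.exp(lp)) ** (1.0 / shape)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a synthetic cohort; fully deterministic given the seed.

    Returns a cohort DataFrame in the canonical column layout (the same
    schema the loader produces), satisfying every record invariant:
    necrosis radius <= T1Gd radius <= T2/FLAIR radius.
    """
    rng = np.random.default_rng(config.seed)
    dist = config.distributions
    n = config.n
    male = rng.uniform(size=n) < dist.male_fraction
    sexes = np.where(male, "male", "female")

    age = np.empty(n)
    t1gd = np.empty(n)
    ce = np.empty(n)
    D = np.empty(n)
    rho = np.empty(n)
    for sex, sd in (("male", dist.male), ("female", dist.female)):
        m = sexes == sex
        k = int(m.sum())
        if k == 0:
            continue
        age[m] = sd.age.sample(rng, k)
        t1gd[m] = sd.t1gd.sample(rng, k)
        ce[m] = sd.ce.sample(rng, k)
        D[m], rho[m] = _sample_kinetics(sd, dist.ratio_bounds, rng, k)

    ratio = D / rho
    necrosis = np.maximum(0.0, t1gd - ce)

    if config.mode == "parametric":
        inverter = pi_model._default_inverter(0.80, 0.16)
        t2flair = t1gd + inverter.forward(ratio)
    else:
        t2flair = np.empty(n)
        for i in range(n):
            times, radii = pihna.simulate_observables(D[i], rho[i])
            obs = pihna.observables_at_detection(
                times, radii,
                detection_radius_mm=t1gd[i] if config.detection_radius_from_t1gd else 20.0,
            )
            t1gd[i] = max(obs.t1gd_radius_mm, 0.1)
            t2flair[i] = max(obs.t2flair_radius_mm, t1gd[i])
            necrosis[i] = min(obs.necrosis_radius_mm, t1gd[i])
        ce = t1gd - necrosis

    # categorical covariates, assigned independently
    cats: dict[str, np.ndarray] = {}
    for var, prev in dist.category_prevalences.items():
        levels = list(prev.keys())
        probs = np.array([prev[l] for l in levels], dtype=float)
        probs = probs / probs.sum()
        cats[var] = rng.choice(levels, size=n, p=probs)

    # proportional-hazards survival with sex-specific linear predictors
    values = {
        "age_years": age, "t1gd_radius_mm": t1gd, "necrosis_radius_mm": necrosis,
        "ce_thickness_mm": ce, "t2flair_radius_mm": t2flair,
        "pihna_D": D, "pihna_rho": rho, "pi_D_over_rho": ratio,
    }
    lp = np.zeros(n)
    for sex, sd in (("male", dist.male), ("female", dist.female)):
        m = sexes == sex
        for term in sd.hazard_terms:
            lp[m] += term.log_hr * (values[term.variable][m] - term.center)
    for (var, level), loghr in config.categorical_log_hazards.items():
        lp += np.where(cats[var] == level, loghr, 0.0)

    os_days = _weibull_ph_sample(rng, lp, dist.weibull_shape, dist.baseline_median_os_days)
    os_days = np.maximum(os_days, 1.0)
    event = np.ones(n, dtype=int)
    if config.censor_horizon_days is not None:
        censored = os_days > config.censor_horizon_days
        os_days = np.where(censored, config.censor_horizon_days, os_days)
        event = np.where(censored, 0, 1)

    group = np.where(os_days >= 1825.0, "EXS", np.where(os_days <= 210.0, "STS", "neither"))

    # planted survival-group effects (shift a variable for destined members)
    for var, shifts in config.planted_effects.items():
        for label, shift in shifts.items():
            values[var] = values[var] + np.where(group == label, shift, 0.0)
    age, t1gd = values["age_years"], values["t1gd_radius_mm"]
    necrosis, ce = values["necrosis_radius_mm"], values["ce_thickness_mm"]
    t2flair, D, rho, ratio = (
        values["t2flair_radius_mm"], values["pihna_D"],
        values["pihna_rho"], values["pi_D_over_rho"],
    )

    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                id=f"SYN{i:05d}",
                sex=str(sexes[i]),
                age_years=float(max(age[i], 0.0)),
                os_days=float(os_days[i]),
                event=int(event[i]),
                t1gd_radius_mm=float(t1gd[i]),
                t2flair_radius_mm=float(t2flair[i]),
                necrosis_radius_mm=float(min(necrosis[i], t1gd[i])),
                pihna_D=float(D[i]),
                pihna_rho=float(rho[i]),
                pi_D_over_rho=float(ratio[i]),
                laterality=str(cats["laterality"][i]),
                eor=str(cats["eor"][i]),
                idh1=str(cats["idh1"][i]),
                mgmt=str(cats["mgmt"][i]),
            )
        )
    return records_to_frame(records)


@dataclass
class RecoveryReport:
    """Did per-sex Cox fits recover the generating hazard ratios?"""

    fits: dict[str, CoxFit]
    coverage: dict[tuple[str, str], bool]

    @property
    def all_covered(self) -> bool:
        return all(self.coverage.values())


def recover_parameters(cohort: pd.DataFrame, config: GeneratorConfig) -> RecoveryReport:
    """Refit the generating proportional-hazards structure per sex.

    For each sex, a Cox model on that sex's generating covariates; the
    report records whether each generating hazard ratio lies inside the
    fitted 95% confidence interval.
    """
    dist = config.distributions
    fits: dict[str, CoxFit] = {}
    coverage: dict[tuple[str, str], bool] = {}
    for sex, sd in (("male", dist.male), ("female", dist.female)):
        sub = cohort[cohort["sex"] == sex]
        covs = [t.variable for t in sd.hazard_terms]
        fit = fit_cox(sub, covs)
        fits[sex] = fit
        for term in sd.hazard_terms:
            lo, hi = fit.ci(term.variable)
            coverage[(sex, term.variable)] = bool(lo <= term.hazard_ratio <= hi)
    return RecoveryReport(fits=fits, coverage=coverage)
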