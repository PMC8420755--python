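"""Synthetic mouse cohorts for single-dose antibody PK in cancer cachexia.

The generator emulates a two-strain study (C57BL/6 carrying Lewis lung
carcinoma, CD2F1 carrying C26 colon carcinoma), each strain split into
tumour-free and tumour-bearing arms receiving a single IV bolus of vehicle,
2 mg/kg or 10 mg/kg of a humanized IgG that does not bind its murine target,
so only catabolic clearance is in play. Sampling is sparse: 1, 48 and 96 h
plus a terminal sample at 144 or 168 h.

Covariates are drawn from configurable distributions. Total endogenous IgG
is calibrated to the strain-specific means/SDs measured in the study
(CD2F1 37.328 ± 15.914 μg/mL; C57BL/6 6.610 ± 2.451 μg/mL); the remaining
covariates (muscle, fat, albumin, body-weight change, hepatic Fcgrt
expression) are calibrated in *direction* only — tumour-bearing animals lose
muscle, fat, weight and albumin and down-regulate Fcgrt — with magnitudes
that are plausible defaults, not measured ground truth.

Individual PK parameters follow the standard population-PK construction:

    P_i = theta_P * prod_c (cov_c / median_c)^beta_c        (continuous)
              * prod_d (1 + beta_d * I_d)                   (dichotomous)
              * exp(eta_P),   eta_P ~ N(0, omega_P^2)

and observed concentrations carry additive Gaussian noise on the log scale
(equivalently, proportional error to first order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .compartmental import PKParams, concentration

__all__ = [
    "CovariateVector",
    "DoseEvent",
    "ObsRecord",
    "SubjectProfile",
    "CovariateEffect",
    "PopulationModelSpec",
    "CovariateGeneratorConfig",
    "StudyDesign",
    "ETA_PARAMS",
    "simulate_covariates",
    "individual_parameters",
    "simulate_profile",
    "inject_absorption_artifact",
    "tumour_volume",
    "generate_cohort",
    "structural_model_spec",
    "final_covariate_model_spec",
    "HOURS_PER_DAY",
]

HOURS_PER_DAY = 24.0

#: parameters carrying interindividual variability, in eta-vector order.
#: Q carries none (its IIV was not estimable in this design).
ETA_PARAMS = ("CL", "V1", "V2")

CONTINUOUS_COVARIATES = (
    "muscle_weight",
    "fat_weight",
    "pct_bw_change",
    "igg_total",
    "albumin",
    "fcgrt_expr",
)
DICHOTOMOUS_COVARIATES = ("tumour", "strain")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateVector:
    """One animal's covariates at end of study.

    tumour/strain are 0/1 indicators (strain 0 = C57BL/6, 1 = CD2F1);
    dose_group is 'vehicle', '2' or '10' (mg/kg); weights in grams; albumin
    in g/dL; igg_total in μg/mL; fcgrt_expr is the hepatic Fcgrt expression
    ratio relative to the tumour-free mean; pct_bw_change in percent (may be
    negative).
    """

    tumour: int
    strain: int
    dose_group: str
    muscle_weight: float
    fat_weight: float
    pct_bw_change: float
    igg_total: float
    albumin: float
    fcgrt_expr: float

    def __post_init__(self) -> None:
        if self.tumour not in (0, 1) or self.strain not in (0, 1):
            raise ValueError("tumour and strain must be 0/1 indicators")
        for name in ("muscle_weight", "fat_weight", "igg_total", "albumin", "fcgrt_expr"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")

    def value(self, name: str) -> float:
        return float(getattr(self, name))


@dataclass(frozen=True)
class DoseEvent:
    """Single IV bolus at t = 0; amount in μg per kg body weight."""

    amount: float
    time: float = 0.0
    route: str = "iv_bolus"

    def __post_init__(self) -> None:
        if self.amount < 0.0:
            raise ValueError("dose amount must be non-negative")
        if self.time != 0.0:
            raise ValueError("only t=0 bolus dosing is supported")


@dataclass(frozen=True)
class ObsRecord:
    """One plasma observation: time in hours, concentration in μg/mL."""

    time_h: float
    conc: float
    bql: bool = False


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    dose: DoseEvent
    covariates: CovariateVector
    records: tuple[ObsRecord, ...]
    true_params: PKParams | None = None

    def __post_init__(self) -> None:
        times = [r.time_h for r in self.records]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("record times must be strictly increasing")
        if any(r.conc < 0.0 for r in self.records):
            raise ValueError("concentrations must be non-negative")

    @property
    def times_h(self) -> np.ndarray:
        return np.array([r.time_h for r in self.records], dtype=float)

    @property
    def concs(self) -> np.ndarray:
        return np.array([r.conc for r in self.records], dtype=float)


EffectForm = Literal["power", "proportional", "exponential"]


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate–parameter relationship.

    ``power``: multiplier (cov/median)^coefficient (continuous covariates,
    median-normalized). ``proportional``: multiplier 1 + coefficient * I
    (dichotomous). ``exponential``: exp(coefficient * I) (dichotomous,
    alternative form).
    """

    parameter: str
    covariate: str
    coefficient: float
    form: EffectForm = "power"

    def __post_init__(self) -> None:
        if self.parameter not in ("CL", "V1", "Q", "V2"):
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.covariate not in CONTINUOUS_COVARIATES + DICHOTOMOUS_COVARIATES:
            raise ValueError(f"unknown covariate {self.covariate!r}")
        if self.form == "power" and self.covariate in DICHOTOMOUS_COVARIATES:
            raise ValueError("power form requires a continuous covariate")
        if self.form in ("proportional", "exponential") and self.covariate in CONTINUOUS_COVARIATES:
            raise ValueError(f"{self.form} form requires a dichotomous covariate")

    @property
    def label(self) -> str:
        names = {
            "tumour": "TUM", "strain": "STR", "muscle_weight": "MWT",
            "fat_weight": "FWT", "pct_bw_change": "PBWT", "igg_total": "IGG",
            "albumin": "ALB", "fcgrt_expr": "FCRNTFM",
        }
        return f"{names[self.covariate]} on {self.parameter}"


@dataclass(frozen=True)
class PopulationModelSpec:
    """Fixed effects, covariate model, IIV variances and residual SD.

    ``omega2`` maps the parameters in ``ETA_PARAMS`` to the variances of
    their exponential random effects; ``sigma_log`` is the SD of the
    additive residual on log-concentration; ``covariate_medians`` holds the
    population medians used to normalize continuous covariates.
    """

    theta: PKParams
    covariate_effects: tuple[CovariateEffect, ...] = ()
    omega2: dict = field(default_factory=lambda: {"CL": 0.0, "V1": 0.0, "V2": 0.0})
    sigma_log: float = 0.1
    covariate_medians: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.omega2) != set(ETA_PARAMS):
            raise ValueError(f"omega2 must have keys {ETA_PARAMS}")
        if any(v < 0.0 for v in self.omega2.values()):
            raise ValueError("omega2 entries must be non-negative")
        if self.sigma_log <= 0.0:
            raise ValueError("sigma_log must be strictly positive")
        # medians for power effects may be installed later (population
        # medians are computed from the cohort at generation or fit time)

    def with_effect(self, effect: CovariateEffect) -> "PopulationModelSpec":
        return replace(self, covariate_effects=self.covariate_effects + (effect,))

    def without_effect(self, effect: CovariateEffect) -> "PopulationModelSpec":
        kept = tuple(e for e in self.covariate_effects if e != effect)
        if len(kept) == len(self.covariate_effects):
            raise ValueError(f"effect {effect.label} not in model")
        return replace(self, covariate_effects=kept)

    def iiv_cv_pct(self) -> dict:
        """IIV reported as CV% = 100*sqrt(exp(omega^2)-1)."""
        return {p: 100.0 * math.sqrt(math.expm1(v)) for p, v in self.omega2.items()}


# ---------------------------------------------------------------------------
# covariate generator
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    if mean <= 0.0 or sd <= 0.0:
        raise ValueError("mean and sd must be strictly positive")
    s2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - 0.5 * s2, math.sqrt(s2)


@dataclass(frozen=True)
class CovariateGeneratorConfig:
    """Distribution settings for terminal covariates.

    Log-normal for strictly positive covariates, normal for percent
    body-weight change. IgG is strain-specific and calibrated to the
    measured strain means/SDs; tumour multipliers below 1 encode the
    cachectic phenotype (muscle/fat/albumin/Fcgrt loss). Only the IgG
    settings are measured ground truth.
    """

    igg_mean_sd_by_strain: dict = field(
        default_factory=lambda: {0: (6.610, 2.451), 1: (37.328, 15.914)}
    )
    igg_tumour_multiplier: float = 1.0
    muscle_mean_sd: tuple = (0.15, 0.018)
    muscle_tumour_multiplier: float = 0.75
    fat_mean_sd: tuple = (0.35, 0.10)
    fat_tumour_multiplier: float = 0.50
    albumin_mean_sd: tuple = (3.0, 0.24)
    albumin_tumour_multiplier: float = 0.85
    fcgrt_mean_sd: tuple = (1.0, 0.25)
    fcgrt_tumour_multiplier: float = 0.85
    pbwt_tumour_free_mean_sd: tuple = (3.0, 3.0)
    pbwt_tumour_mean_sd: tuple = (-10.0, 5.0)


def simulate_covariates(
    n: int,
    strain: int,
    tumour: int,
    config: CovariateGeneratorConfig | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    dose_group: str = "vehicle",
) -> list[CovariateVector]:
    """Draw ``n`` covariate vectors for one strain × tumour-status cell."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if strain not in (0, 1) or tumour not in (0, 1):
        raise ValueError("strain and tumour must be 0/1")
    cfg = config or CovariateGeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(seed)

    def draw_lognormal(mean_sd: tuple, mult: float) -> np.ndarray:
        mean, sd = mean_sd
        if tumour:
            mean = mean * mult
            sd = sd * mult  # scale shift preserves CV
        mu, sig = _lognormal_params(mean, sd)
        return rng.lognormal(mu, sig, size=n)

    igg = draw_lognormal(cfg.igg_mean_sd_by_strain[strain], cfg.igg_tumour_multiplier)
    mwt = draw_lognormal(cfg.muscle_mean_sd, cfg.muscle_tumour_multiplier)
    fwt = draw_lognormal(cfg.fat_mean_sd, cfg.fat_tumour_multiplier)
    alb = draw_lognormal(cfg.albumin_mean_sd, cfg.albumin_tumour_multiplier)
    fcrn = draw_lognormal(cfg.fcgrt_mean_sd, cfg.fcgrt_tumour_multiplier)
    pb_mean, pb_sd = cfg.pbwt_tumour_mean_sd if tumour else cfg.pbwt_tumour_free_mean_sd
    pbwt = rng.normal(pb_mean, pb_sd, size=n)

    return [
        CovariateVector(
            tumour=tumour, strain=strain, dose_group=dose_group,
            muscle_weight=float(mwt[i]), fat_weight=float(fwt[i]),
            pct_bw_change=float(pbwt[i]), igg_total=float(igg[i]),
            albumin=float(alb[i]), fcgrt_expr=float(fcrn[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# individual parameters and profile simulation
# ---------------------------------------------------------------------------

def covariate_multipliers(spec: PopulationModelSpec, cov: CovariateVector) -> dict:
    """Multiplicative covariate factor per PK parameter for one subject."""
    mult = {"CL": 1.0, "V1": 1.0, "Q": 1.0, "V2": 1.0}
    for e in spec.covariate_effects:
        x = cov.value(e.covariate)
        if e.form == "power":
            if x <= 0.0:
                raise ValueError(
                    f"covariate {e.covariate!r} must be positive for a power effect"
                )
            med = spec.covariate_medians.get(e.covariate)
            if med is None or med <= 0.0:
                raise ValueError(f"no positive median for covariate {e.covariate!r}")
            m = (x / med) ** e.coefficient
        elif e.form == "proportional":
            m = 1.0 + e.coefficient * x
            if m <= 0.0:
                raise ValueError(f"effect {e.label}: 1 + coef*indicator <= 0")
        else:  # exponential
            m = math.exp(e.coefficient * x)
        mult[e.parameter] *= m
    return mult


def individual_parameters(
    spec: PopulationModelSpec, cov: CovariateVector, eta: Sequence[float]
) -> PKParams:
    """Individual PK parameters from typical values, covariates and eta.

    ``eta`` has one entry per parameter in ``ETA_PARAMS`` (CL, V1, V2);
    Q carries no random effect.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (len(ETA_PARAMS),):
        raise ValueError(f"eta must have {len(ETA_PARAMS)} entries {ETA_PARAMS}")
    mult = covariate_multipliers(spec, cov)
    ev = dict(zip(ETA_PARAMS, eta))
    th = spec.theta
    return PKParams(
        CL=th.CL * mult["CL"] * math.exp(ev["CL"]),
        V1=th.V1 * mult["V1"] * math.exp(ev["V1"]),
        Q=th.Q * mult["Q"],
        V2=th.V2 * mult["V2"] * math.exp(ev["V2"]),
    )


def simulate_profile(
    params: PKParams,
    dose: DoseEvent,
    schedule_h: Sequence[float],
    sigma_log: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ObsRecord, ...]:
    """Sample one subject's concentration records on ``schedule_h`` (hours).

    Observed concentration = model concentration × exp(eps) with
    eps ~ N(0, sigma_log²); sigma_log = 0 returns the noise-free curve.
    C(0) is a model quantity, not a sample, so all schedule times must be
    strictly positive.
    """
    sched = np.asarray(schedule_h, dtype=float)
    if sched.size == 0:
        raise ValueError("schedule must be non-empty")
    if np.any(sched <= 0.0):
        raise ValueError("schedule times must be strictly positive hours")
    if np.any(np.diff(sched) <= 0.0):
        raise ValueError("schedule times must be strictly increasing")
    if sigma_log < 0.0:
        raise ValueError("sigma_log must be non-negative")
    t_days = sched / HOURS_PER_DAY
    c = np.asarray(concentration(params, dose.amount, t_days), dtype=float)
    if sigma_log > 0.0:
        if rng is None:
            rng = np.random.default_rng(seed)
        c = c * np.exp(rng.normal(0.0, sigma_log, size=c.shape))
    return tuple(ObsRecord(float(t), float(ci)) for t, ci in zip(sched, c))


def inject_absorption_artifact(
    profile: SubjectProfile,
    dose_fraction_iv: float,
    ka: float,
    seed: int | None = None,
) -> SubjectProfile:
    """Superpose a partial-dose absorption artifact on a profile.

    Fraction ``dose_fraction_iv`` of the dose is an IV bolus; the remaining
    1−f enters a first-order depot with rate ``ka`` (1/day), producing the
    rising early segment seen in mice that received only a partial
    intravenous dose. The subject's residual noise is preserved: each record
    is rescaled by the ratio of the mixed-input to pure-IV model curve.
    ``seed`` is accepted for interface symmetry; no new noise is drawn.
    """
    if not (0.0 <= dose_fraction_iv < 1.0):
        raise ValueError("dose_fraction_iv must be in [0, 1)")
    if ka <= 0.0:
        raise ValueError("ka must be strictly positive")
    if profile.true_params is None:
        raise ValueError("profile lacks true_params; cannot evaluate model curves")
    p = profile.true_params
    t = profile.times_h / HOURS_PER_DAY
    c_iv = np.asarray(concentration(p, profile.dose.amount, t), dtype=float)

    from .compartmental import hybrid_constants, micro_constants

    h = hybrid_constants(micro_constants(p), p.V1)
    f = dose_fraction_iv
    d = profile.dose.amount
    # first-order input convolved with the biexponential disposition
    depot = np.zeros_like(t)
    for coef, lam in ((h.coefA, h.alpha), (h.coefB, h.beta)):
        depot += coef * ka / (ka - lam) * (np.exp(-lam * t) - np.exp(-ka * t))
    c_mixed = f * c_iv + (1.0 - f) * d * depot
    ratio = np.where(c_iv > 0.0, c_mixed / c_iv, 0.0)
    records = tuple(
        ObsRecord(r.time_h, float(r.conc * ratio[i]), r.bql)
        for i, r in enumerate(profile.records)
    )
    return replace(profile, records=records)


def tumour_volume(length: float, width: float) -> float:
    """Calliper tumour volume in mm³: length × width² × π/6."""
    if width <= 0.0 or length <= 0.0:
        raise ValueError("dimensions must be strictly positive")
    if length < width:
        raise ValueError("length must be >= width")
    return length * width * width * math.pi / 6.0


# ---------------------------------------------------------------------------
# study design and cohort generation
# ---------------------------------------------------------------------------

def _default_arms() -> tuple:
    """Default cell sizes: 135 mice, 28 vehicle, 107 dosed (53 at 2 mg/kg,
    54 at 10 mg/kg), split over strain (1 = CD2F1, 0 = C57BL/6) and tumour
    status roughly evenly, matching the study scale."""
    return (
        # (strain, tumour, dose_group, n)
        (1, 0, "vehicle", 7), (1, 1, "vehicle", 7),
        (1, 0, "2", 12), (1, 1, "2", 12),
        (1, 0, "10", 12), (1, 1, "10", 13),
        (0, 0, "vehicle", 7), (0, 1, "vehicle", 7),
        (0, 0, "2", 14), (0, 1, "2", 15),
        (0, 0, "10", 15), (0, 1, "10", 14),
    )


@dataclass(frozen=True)
class StudyDesign:
    """Cohort-level settings for :func:`generate_cohort`.

    ``arms`` lists (strain, tumour, dose_group, n) cells. ``artifact_rate``
    is the per-dosed-subject probability of a partial-dose absorption
    artifact (default 28/107, reproducing the study's exclusion count in
    expectation). The terminal sample is drawn 50/50 between 144 and 168 h
    unless ``terminal_h`` pins it.
    """

    arms: tuple = field(default_factory=_default_arms)
    sample_times_h: tuple = (1.0, 48.0, 96.0)
    terminal_choices_h: tuple = (144.0, 168.0)
    terminal_h: float | None = None
    artifact_rate: float = 28.0 / 107.0
    artifact_iv_fraction_range: tuple = (0.0, 0.2)
    artifact_ka_per_day: float = 0.5
    covariates: CovariateGeneratorConfig = field(default_factory=CovariateGeneratorConfig)
    model: PopulationModelSpec | None = None
    lloq: float = 0.0

    def __post_init__(self) -> None:
        if any(n < 0 for *_cell, n in self.arms):
            raise ValueError("arm sizes must be non-negative")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise ValueError("artifact_rate must be in [0, 1]")


def _dose_amount(dose_group: str) -> float:
    # mg/kg → μg/kg
    return {"vehicle": 0.0, "2": 2000.0, "10": 10000.0}[dose_group]


def generate_cohort(
    design: StudyDesign | None = None, seed: int = 0
) -> list[SubjectProfile]:
    """Generate a full study-shaped cohort of subject profiles.

    Covariates are drawn first for all animals; continuous-covariate
    medians are then computed over the cohort and installed in the model
    spec (population-median normalization), after which concentrations are
    simulated for the dosed animals. Vehicle animals carry covariates but
    no concentration records. A deterministic per-subject RNG stream is
    spawned from ``seed``.
    """
    design = design or StudyDesign()
    model = design.model if design.model is not None else final_covariate_model_spec()

    root = np.random.SeedSequence(seed)
    cov_rng = np.random.default_rng(root.spawn(1)[0])

    cells: list[tuple[int, int, str, CovariateVector]] = []
    for strain, tumour, dose_group, n in design.arms:
        if n == 0:
            continue
        covs = simulate_covariates(
            n, strain, tumour, design.covariates, rng=cov_rng, dose_group=dose_group
        )
        cells.extend((strain, tumour, dose_group, c) for c in covs)

    medians = {
        name: float(np.median([c.value(name) for *_ig, c in cells]))
        for name in CONTINUOUS_COVARIATES
    }
    model = replace(model, covariate_medians={**medians, **model.covariate_medians})

    omega_sd = np.array([math.sqrt(model.omega2[p]) for p in ETA_PARAMS])
    subjects: list[SubjectProfile] = []
    for i, (_strain, _tumour, dose_group, cov) in enumerate(cells):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, i)))
        sid = f"M{i + 1:03d}"
        dose = DoseEvent(amount=_dose_amount(dose_group))
        eta = rng.normal(0.0, 1.0, size=len(ETA_PARAMS)) * omega_sd
        params = individual_parameters(model, cov, eta)
        if dose.amount == 0.0:
            subjects.append(SubjectProfile(sid, dose, cov, (), true_params=params))
            continue
        terminal = (
            design.terminal_h
            if design.terminal_h is not None
            else design.terminal_choices_h[int(rng.integers(len(design.terminal_choices_h)))]
        )
        schedule = tuple(design.sample_times_h) + (float(terminal),)
        records = simulate_profile(params, dose, schedule, model.sigma_log, rng=rng)
        if design.lloq > 0.0:
            records = tuple(
                replace(r, bql=r.conc < design.lloq) for r in records
            )
        prof = SubjectProfile(sid, dose, cov, records, true_params=params)
        if design.artifact_rate > 0.0 and rng.random() < design.artifact_rate:
            lo, hi = design.artifact_iv_fraction_range
            f = float(rng.uniform(lo, hi))
            prof = inject_absorption_artifact(prof, f, design.artifact_ka_per_day)
        subjects.append(prof)
    return subjects


# ---------------------------------------------------------------------------
# reference model specifications (study estimates as generative defaults)
# ---------------------------------------------------------------------------

def _omega2_from_cv_pct(cv_pct: float) -> float:
    return math.log1p((cv_pct / 100.0) ** 2)


def structural_model_spec() -> PopulationModelSpec:
    """Covariate-free two-compartment population model at the study's
    structural-model estimates (CL 11.9 mL/day/kg, V1 61.8 mL/kg,
    Q 62.3 mL/day/kg, V2 62.3 mL/kg; IIV CV% 55.0/30.2/50.7 on CL/V1/V2;
    residual log-SD 0.110)."""
    return PopulationModelSpec(
        theta=PKParams(CL=11.9, V1=61.8, Q=62.3, V2=62.3),
        covariate_effects=(),
        omega2={
            "CL": _omega2_from_cv_pct(55.0),
            "V1": _omega2_from_cv_pct(30.2),
            "V2": _omega2_from_cv_pct(50.7),
        },
        sigma_log=0.110,
    )


def final_covariate_model_spec(covariate_medians: dict | None = None) -> PopulationModelSpec:
    """The study's final covariate model: tumour (+0.65, proportional),
    muscle weight (power −1.04), total IgG (power 0.286) and Fcgrt
    expression (power −0.227) on CL; IgG on V1 (0.116) and on Q (0.415).
    Medians default to empty and are filled at cohort-generation or fit
    time from the population."""
    return PopulationModelSpec(
        theta=PKParams(CL=8.35, V1=61.6, Q=61.1, V2=66.1),
        covariate_effects=(
            CovariateEffect("CL", "tumour", 0.65, "proportional"),
            CovariateEffect("CL", "muscle_weight", -1.04, "power"),
            CovariateEffect("CL", "igg_total", 0.286, "power"),
            CovariateEffect("CL", "fcgrt_expr", -0.227, "power"),
            CovariateEffect("V1", "igg_total", 0.116, "power"),
            CovariateEffect("Q", "igg_total", 0.415, "power"),
        ),
        omega2={
            "CL": _omega2_from_cv_pct(29.6),
            "V1": _omega2_from_cv_pct(27.6),
            "V2": _omega2_from_cv_pct(51.9),
        },
        sigma_log=0.110,
        covariate_medians=dict(covariate_medians or {}),
    )
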