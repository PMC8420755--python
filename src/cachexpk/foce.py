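"""Nonlinear mixed-effects estimation by FOCE with interaction.

The marginal likelihood of each subject's log-concentrations is
approximated by linearizing the structural model in the random effects
about the subject's conditional mode (empirical Bayes estimate):

    eta_hat_i = argmin_eta  ||y_i - f_i(eta)||^2 / sigma^2 + eta' Omega^-1 eta
    C_i  = G_i Omega G_i' + sigma^2 I,   G_i = df_i/deta at eta_hat_i
    r_i  = y_i - f_i(eta_hat_i) + G_i eta_hat_i
    OFV  = sum_i [ log det C_i + r_i' C_i^-1 r_i ]

Because the residual error is additive on the log scale with constant SD,
the residual variance does not depend on eta and the "with interaction"
variant coincides with plain FOCE here. The additive n*log(2*pi) constant
is dropped (NONMEM convention), so only OFV differences are meaningful.

The outer problem maximizes the approximate marginal likelihood over
(log theta, covariate coefficients, log omega^2, log sigma) by
quasi-Newton search with finite-difference gradients and a configurable
number of jittered restarts. Omega is diagonal with random effects on CL,
V1 and V2 only; Q carries none (not estimable under this sparse design).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .cohort import (
    CONTINUOUS_COVARIATES,
    ETA_PARAMS,
    HOURS_PER_DAY,
    CovariateEffect,
    PopulationModelSpec,
    SubjectProfile,
)
from .compartmental import PKParams, concentration_batch

__all__ = [
    "PKDataset",
    "FoceSettings",
    "FitResult",
    "predict_log_concentrations",
    "map_eta",
    "foce_ofv",
    "fit",
    "standard_errors",
    "eta_shrinkage",
    "conditional_modes",
    "foce_ofv_terms",
]

_OMEGA2_FLOOR = 1e-12
_INVALID_OFV = 1e10


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

@dataclass
class PKDataset:
    """Padded, batched view of the analysis population.

    One row per subject: dose (μg/kg), observation times (days) and
    log-concentrations padded to the longest schedule with ``mask`` marking
    real observations; covariates as a column dict of float arrays.
    """

    ids: list
    dose: np.ndarray        # (n,)
    times_d: np.ndarray     # (n, m)
    y: np.ndarray           # (n, m) log concentrations
    mask: np.ndarray        # (n, m) bool
    covariates: dict        # name -> (n,) array

    @classmethod
    def from_profiles(cls, profiles: Sequence[SubjectProfile]) -> "PKDataset":
        """Build from dosed subjects with observations; BQL records are
        excluded from the likelihood."""
        usable = []
        for p in profiles:
            if p.dose.amount <= 0.0:
                continue
            recs = [r for r in p.records if not r.bql and r.conc > 0.0]
            if recs:
                usable.append((p, recs))
        if not usable:
            raise ValueError("no dosed subjects with quantifiable observations")
        n = len(usable)
        m = max(len(recs) for _p, recs in usable)
        dose = np.zeros(n)
        times = np.ones((n, m))
        y = np.zeros((n, m))
        mask = np.zeros((n, m), dtype=bool)
        ids = []
        cov_names = CONTINUOUS_COVARIATES + ("tumour", "strain")
        cov = {name: np.zeros(n) for name in cov_names}
        for i, (p, recs) in enumerate(usable):
            ids.append(p.subject_id)
            dose[i] = p.dose.amount
            for j, r in enumerate(recs):
                times[i, j] = r.time_h / HOURS_PER_DAY
                y[i, j] = math.log(r.conc)
                mask[i, j] = True
            for name in cov_names:
                cov[name][i] = p.covariates.value(name)
        return cls(ids=ids, dose=dose, times_d=times, y=y, mask=mask, covariates=cov)

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())

    def medians(self) -> dict:
        return {name: float(np.median(v)) for name, v in self.covariates.items()
                if name in CONTINUOUS_COVARIATES}


# ---------------------------------------------------------------------------
# generic FOCE core (used by the PK layer and directly testable on toys)
# ---------------------------------------------------------------------------

def _fd_jacobian(predict: Callable, etas: np.ndarray, mask: np.ndarray,
                 h: float = 1e-5, stacked: bool = False) -> np.ndarray:
    """Central-difference Jacobian of predict wrt eta: (n, m, k).

    With ``stacked=True`` the 2k perturbed eta matrices are evaluated in a
    single predict call on a (2k*n, k) stack (the PK predict supports
    arbitrary row multiples of the dataset); the fallback loops.
    """
    n, k = etas.shape
    m = mask.shape[1]
    G = np.empty((n, m, k))
    if stacked:
        blocks = []
        for j in range(k):
            e = np.zeros_like(etas)
            e[:, j] = h
            blocks.append(etas + e)
            blocks.append(etas - e)
        out = predict(np.concatenate(blocks, axis=0))
        for j in range(k):
            G[:, :, j] = (out[2 * j * n:(2 * j + 1) * n]
                          - out[(2 * j + 1) * n:(2 * j + 2) * n]) / (2.0 * h)
    else:
        for j in range(k):
            e = np.zeros_like(etas)
            e[:, j] = h
            G[:, :, j] = (predict(etas + e) - predict(etas - e)) / (2.0 * h)
    return G * mask[:, :, None]


def conditional_modes(
    predict: Callable[[np.ndarray], np.ndarray],
    y: np.ndarray,
    mask: np.ndarray,
    omega2: np.ndarray,
    sigma: float,
    eta0: np.ndarray | None = None,
    gtol: float = 1e-6,
    maxiter: int = 100,
    stacked: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Conditional modes of the random effects for all subjects at once.

    ``predict`` maps an (n, k) eta matrix to (n, m) predicted
    log-concentrations. Returns (eta_hat, f_hat, G) where G is the
    Jacobian of predict at the mode. Damped Gauss–Newton iterations; the
    gradient max-norm at return is below ``gtol`` for every subject that
    converged within ``maxiter`` iterations. The solve always starts from
    eta = 0 unless ``eta0`` is given, and is a pure function of its inputs
    (no state), so the outer objective built on it is deterministic.
    """
    y = np.asarray(y, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    omega2 = np.asarray(omega2, dtype=float)
    n = y.shape[0]
    k = omega2.size
    inv_w2 = 1.0 / np.maximum(omega2, _OMEGA2_FLOOR)
    sig2 = sigma * sigma
    eye = np.eye(k)

    def objective(et):
        f = predict(et)
        r = np.where(mask, y - f, 0.0)
        return (r * r).sum(axis=1) / sig2 + (et * et * inv_w2).sum(axis=1), f, r

    def gauss_newton(eta):
        val, f, r = objective(eta)
        for _ in range(maxiter):
            G = _fd_jacobian(predict, eta, mask, stacked=stacked)
            grad = -2.0 * np.einsum("nmk,nm->nk", G, r) / sig2 + 2.0 * eta * inv_w2
            active = np.abs(grad).max(axis=1) > gtol
            if not active.any():
                break
            H = 2.0 * np.einsum("nmk,nml->nkl", G, G) / sig2 + 2.0 * inv_w2[None] * eye
            # small ridge keeps the batched solve well-posed far from the mode
            H = H + 1e-10 * eye
            delta = np.linalg.solve(H, -grad[:, :, None])[:, :, 0]
            alpha = np.ones(n)
            trial = eta
            val_t, f_t, r_t = val, f, r
            for _bt in range(30):
                trial = eta + (alpha * active)[:, None] * delta
                val_t, f_t, r_t = objective(trial)
                worse = active & (val_t > val + 1e-12)
                if not worse.any():
                    break
                alpha = np.where(worse, alpha * 0.5, alpha)
            improved = active & (val_t <= val + 1e-12)
            eta = np.where(improved[:, None], trial, eta)
            val = np.where(improved, val_t, val)
            f = np.where(improved[:, None], f_t, f)
            r = np.where(improved[:, None], r_t, r)
            if not improved.any():
                break
        return eta, val

    eta, _val = gauss_newton(
        np.zeros((n, k)) if eta0 is None else np.array(eta0, dtype=float)
    )
    G = _fd_jacobian(predict, eta, mask, stacked=stacked)
    return eta, predict(eta), G


def foce_ofv_terms(
    y: np.ndarray,
    mask: np.ndarray,
    f_hat: np.ndarray,
    G: np.ndarray,
    eta_hat: np.ndarray,
    omega2: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Per-subject FOCE objective terms log det C_i + r_i' C_i^-1 r_i."""
    sig2 = sigma * sigma
    w2 = np.asarray(omega2, dtype=float)
    n, m = y.shape
    C = np.einsum("nmk,k,nlk->nml", G, w2, G)
    idx = np.arange(m)
    C[:, idx, idx] += sig2
    outer = mask[:, :, None] & mask[:, None, :]
    C = np.where(outer, C, 0.0)
    C[:, idx, idx] = np.where(mask, C[:, idx, idx], 1.0)
    rt = np.where(mask, y - f_hat + np.einsum("nmk,nk->nm", G, eta_hat), 0.0)
    sign, logdet = np.linalg.slogdet(C)
    if np.any(sign <= 0):
        raise np.linalg.LinAlgError("singular marginal covariance")
    quad = np.einsum("nm,nm->n", rt, np.linalg.solve(C, rt[:, :, None])[:, :, 0])
    return logdet + quad


# ---------------------------------------------------------------------------
# PK model layer
# ---------------------------------------------------------------------------

def _effect_design(spec: PopulationModelSpec, dataset: PKDataset) -> list:
    """Per-effect per-subject design values: for a power effect the log
    covariate ratio, for indicator effects the 0/1 value."""
    design = []
    for e in spec.covariate_effects:
        x = dataset.covariates[e.covariate]
        if e.form == "power":
            med = spec.covariate_medians.get(e.covariate)
            if med is None or med <= 0.0:
                raise ValueError(f"no positive median for covariate {e.covariate!r}")
            if np.any(x <= 0.0):
                raise ValueError(
                    f"covariate {e.covariate!r} must be positive for a power effect"
                )
            design.append((e.parameter, "log", np.log(x / med)))
        else:
            design.append((e.parameter, e.form, x.astype(float)))
    return design


_PK_ORDER = ("CL", "V1", "Q", "V2")


def _log_param_multipliers(design: list, coefs: np.ndarray, n: int):
    """Log covariate multiplier per PK parameter; None if any subject's
    proportional multiplier is non-positive (invalid point)."""
    logm = {p: np.zeros(n) for p in _PK_ORDER}
    for (param, kind, xv), c in zip(design, coefs):
        if kind == "log":
            logm[param] += c * xv
        elif kind == "proportional":
            mult = 1.0 + c * xv
            if np.any(mult <= 0.0):
                return None
            logm[param] += np.log(mult)
        else:  # exponential indicator
            logm[param] += c * xv
    return logm


def _make_predict(theta: np.ndarray, logm: dict, dataset: PKDataset) -> Callable:
    """Batched log-concentration prediction as a function of eta.

    The returned callable accepts (r*n, k) eta stacks for any integer r
    (rows taken modulo the dataset) so finite-difference Jacobians can be
    evaluated in one call.
    """
    log_base = {
        p: math.log(theta[i]) + logm[p] for i, p in enumerate(_PK_ORDER)
    }
    n = dataset.n_subjects
    times = dataset.times_d
    dose = dataset.dose
    ei = {p: j for j, p in enumerate(ETA_PARAMS)}

    tiled: dict = {1: (log_base, times, dose)}

    def predict(etas: np.ndarray) -> np.ndarray:
        r = etas.shape[0] // n
        if r not in tiled:
            tiled[r] = (
                {p: np.tile(log_base[p], r) for p in _PK_ORDER},
                np.tile(times, (r, 1)),
                np.tile(dose, r),
            )
        base, tt, dd = tiled[r]
        cl = np.exp(np.clip(base["CL"] + etas[:, ei["CL"]], -50, 50))
        v1 = np.exp(np.clip(base["V1"] + etas[:, ei["V1"]], -50, 50))
        q = np.exp(np.clip(base["Q"], -50, 50)) * np.ones_like(cl)
        v2 = np.exp(np.clip(base["V2"] + etas[:, ei["V2"]], -50, 50))
        c = concentration_batch(cl, v1, q, v2, dd, tt)
        return np.log(np.maximum(c, 1e-300))

    return predict


def predict_log_concentrations(
    spec: PopulationModelSpec, subject: SubjectProfile, eta: Sequence[float]
) -> np.ndarray:
    """Predicted log-concentrations at the subject's observation times for
    a given eta vector (model quantity; no residual noise)."""
    if len(subject.records) == 0:
        raise ValueError("subject has no observations")
    ds = PKDataset.from_profiles([subject])
    spec = _ensure_medians(spec, ds)
    design = _effect_design(spec, ds)
    logm = _log_param_multipliers(
        design, np.array([e.coefficient for e in spec.covariate_effects]), 1
    )
    if logm is None:
        raise ValueError("covariate model yields non-positive parameter multiplier")
    predict = _make_predict(spec.theta.as_array(), logm, ds)
    return predict(np.asarray(eta, dtype=float)[None, :])[0][ds.mask[0]]


def _ensure_medians(spec: PopulationModelSpec, dataset: PKDataset) -> PopulationModelSpec:
    need = {e.covariate for e in spec.covariate_effects if e.form == "power"}
    missing = need - set(spec.covariate_medians)
    if missing:
        med = dataset.medians()
        spec = replace(
            spec,
            covariate_medians={**{c: med[c] for c in missing}, **spec.covariate_medians},
        )
    return spec


def _spec_predict(spec: PopulationModelSpec, dataset: PKDataset) -> Callable:
    design = _effect_design(spec, dataset)
    coefs = np.array([e.coefficient for e in spec.covariate_effects])
    logm = _log_param_multipliers(design, coefs, dataset.n_subjects)
    if logm is None:
        raise ValueError("covariate model yields non-positive parameter multiplier")
    return _make_predict(spec.theta.as_array(), logm, dataset)


def _omega2_vector(spec: PopulationModelSpec) -> np.ndarray:
    return np.array([spec.omega2[p] for p in ETA_PARAMS], dtype=float)


def map_eta(
    spec: PopulationModelSpec,
    subject: SubjectProfile,
    gtol: float = 1e-6,
) -> np.ndarray:
    """Empirical Bayes estimate (conditional mode) of one subject's eta."""
    ds = PKDataset.from_profiles([subject])
    spec = _ensure_medians(spec, ds)
    predict = _spec_predict(spec, ds)
    eta, _f, _G = conditional_modes(
        predict, ds.y, ds.mask, _omega2_vector(spec), spec.sigma_log,
        gtol=gtol, stacked=True,
    )
    return eta[0]


def foce_ofv(
    spec: PopulationModelSpec,
    dataset: PKDataset | Sequence[SubjectProfile],
    eta0: np.ndarray | None = None,
    return_etas: bool = False,
):
    """FOCE objective function value of ``spec`` on ``dataset``."""
    if not isinstance(dataset, PKDataset):
        dataset = PKDataset.from_profiles(dataset)
    spec = _ensure_medians(spec, dataset)
    predict = _spec_predict(spec, dataset)
    w2 = _omega2_vector(spec)
    eta, f, G = conditional_modes(
        predict, dataset.y, dataset.mask, w2, spec.sigma_log, eta0=eta0,
        stacked=True,
    )
    terms = foce_ofv_terms(dataset.y, dataset.mask, f, G, eta, w2, spec.sigma_log)
    ofv = float(terms.sum())
    return (ofv, eta) if return_etas else ofv


# ---------------------------------------------------------------------------
# outer estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoceSettings:
    """Estimation settings: inner-mode tolerance, outer optimizer budget,
    and the multi-start policy (jittered restarts with fixed seeds)."""

    #: inner (conditional-mode) gradient tolerance during estimation; the
    #: final EBEs/OFV are recomputed at 1e-6
    inner_gtol: float = 1e-4
    outer_maxiter: int = 400
    outer_ftol: float = 1e-11
    outer_gtol: float = 1e-5
    fd_step: float = 1e-4
    n_starts: int = 3
    jitter_sd: float = 0.15
    jitter_seed: int = 2021
    #: a quasi-Newton run can stagnate on the mildly non-smooth FOCE
    #: surface; each start is re-launched from its end point until the OFV
    #: stops improving by restart_tol (bounded by max_restarts rounds)
    max_restarts: int = 3
    restart_tol: float = 0.02


@dataclass
class FitResult:
    """Converged population estimates with empirical Bayes etas."""

    spec: PopulationModelSpec           # fitted model (estimates installed)
    theta_hat: PKParams
    coef_hat: dict                      # effect label -> coefficient
    omega2_hat: dict                    # eta param -> variance
    sigma_hat: float
    ofv: float
    ebes: np.ndarray                    # (n_subjects, n_eta)
    shrinkage_pct: dict                 # eta param -> percent
    converged: bool
    n_subjects: int
    n_obs: int
    se_pct: dict | None = None          # label -> SE%, if computed
    subject_ids: list = field(default_factory=list)

    def iiv_cv_pct(self) -> dict:
        return {p: 100.0 * math.sqrt(math.expm1(v)) for p, v in self.omega2_hat.items()}


def _pack(spec: PopulationModelSpec) -> np.ndarray:
    th = spec.theta.as_array()
    coefs = [e.coefficient for e in spec.covariate_effects]
    w2 = _omega2_vector(spec)
    return np.concatenate([
        np.log(th),
        np.asarray(coefs, dtype=float),
        np.log(np.maximum(w2, _OMEGA2_FLOOR)),
        [math.log(spec.sigma_log)],
    ])


def _unpack(x: np.ndarray, template: PopulationModelSpec) -> PopulationModelSpec:
    c = len(template.covariate_effects)
    th = np.exp(x[:4])
    coefs = x[4:4 + c]
    w2 = np.exp(x[4 + c:4 + c + len(ETA_PARAMS)])
    sigma = math.exp(x[4 + c + len(ETA_PARAMS)])
    effects = tuple(
        replace(e, coefficient=float(cc))
        for e, cc in zip(template.covariate_effects, coefs)
    )
    return replace(
        template,
        theta=PKParams(*th),
        covariate_effects=effects,
        omega2=dict(zip(ETA_PARAMS, w2)),
        sigma_log=sigma,
    )


def _param_labels(template: PopulationModelSpec) -> list:
    labels = list(_PK_ORDER)
    labels += [e.label for e in template.covariate_effects]
    labels += [f"omega2_{p}" for p in ETA_PARAMS]
    labels += ["sigma"]
    return labels


def _bounds(template: PopulationModelSpec) -> list:
    """Plausibility box for the outer search. The box is deliberately wide
    but finite: clearances/volumes within a factor ~500 of physiological
    scale, IIV up to ~200 CV%, residual SD down to 0.5% — extreme corners
    stay numerically benign so the quasi-Newton line search can recover
    from an over-ambitious step."""
    c = len(template.covariate_effects)
    b = [(math.log(0.1), math.log(5e3))] * 4
    b += [(-5.0, 5.0)] * c
    b += [(math.log(1e-6), math.log(4.0))] * len(ETA_PARAMS)
    b += [(math.log(5e-3), math.log(2.0))]
    return b


def _make_objective(template: PopulationModelSpec, dataset: PKDataset,
                    settings: FoceSettings):
    """Stateless outer objective: packed parameters -> FOCE OFV.

    The conditional modes are re-solved from eta = 0 at every evaluation,
    so the objective is a pure (deterministic) function of x — important
    for finite-difference gradients and line searches.
    """
    design = _effect_design(template, dataset)
    w_idx = slice(4 + len(template.covariate_effects),
                  4 + len(template.covariate_effects) + len(ETA_PARAMS))
    s_idx = 4 + len(template.covariate_effects) + len(ETA_PARAMS)

    def objective(x: np.ndarray) -> float:
        theta = np.exp(x[:4])
        coefs = x[4:4 + len(template.covariate_effects)]
        w2 = np.exp(x[w_idx])
        sigma = math.exp(x[s_idx])
        logm = _log_param_multipliers(design, coefs, dataset.n_subjects)
        if logm is None:
            return _INVALID_OFV
        predict = _make_predict(theta, logm, dataset)
        try:
            eta, f, G = conditional_modes(
                predict, dataset.y, dataset.mask, w2, sigma,
                gtol=settings.inner_gtol, stacked=True,
            )
            terms = foce_ofv_terms(dataset.y, dataset.mask, f, G, eta, w2, sigma)
        except np.linalg.LinAlgError:
            return _INVALID_OFV
        val = float(terms.sum())
        return val if np.isfinite(val) else _INVALID_OFV

    return objective


def fit(
    dataset: PKDataset | Sequence[SubjectProfile],
    initial_spec: PopulationModelSpec,
    settings: FoceSettings | None = None,
    compute_se: bool = False,
) -> FitResult:
    """Maximum (approximate) likelihood estimation of the population model.

    Starts from ``initial_spec`` (which also fixes the covariate-model
    structure) plus jittered restarts; requires at least two subjects with
    at least two observations each for the variance components to be
    estimable. Returns best-so-far estimates with ``converged=False`` when
    the optimizer does not report success.
    """
    settings = settings or FoceSettings()
    if not isinstance(dataset, PKDataset):
        dataset = PKDataset.from_profiles(dataset)
    if dataset.n_subjects < 2 or int((dataset.mask.sum(axis=1) >= 2).sum()) < 2:
        raise ValueError("need >= 2 subjects with >= 2 observations each")
    template = _ensure_medians(initial_spec, dataset)
    objective = _make_objective(template, dataset, settings)
    x0 = _pack(template)
    starts = [x0]
    jrng = np.random.default_rng(settings.jitter_seed)
    for _ in range(max(0, settings.n_starts - 1)):
        starts.append(x0 + jrng.normal(0.0, settings.jitter_sd, size=x0.size))

    options = {
        "maxiter": settings.outer_maxiter,
        "ftol": settings.outer_ftol,
        "gtol": settings.outer_gtol,
        "eps": settings.fd_step,
        "maxls": 40,
    }
    best = None
    for x_start in starts:
        res = minimize(objective, x_start, method="L-BFGS-B",
                       bounds=_bounds(template), options=options)
        for _ in range(settings.max_restarts):
            res2 = minimize(objective, res.x, method="L-BFGS-B",
                            bounds=_bounds(template), options=options)
            if res2.fun < res.fun - settings.restart_tol:
                res = res2
            else:
                if res2.fun < res.fun:
                    res = res2
                break
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    fitted = _unpack(best.x, template)
    ofv, etas = foce_ofv(fitted, dataset, return_etas=True)
    shr = eta_shrinkage(etas, _omega2_vector(fitted))
    result = FitResult(
        spec=fitted,
        theta_hat=fitted.theta,
        coef_hat={e.label: e.coefficient for e in fitted.covariate_effects},
        omega2_hat=dict(fitted.omega2),
        sigma_hat=fitted.sigma_log,
        ofv=ofv,
        ebes=etas,
        shrinkage_pct=dict(zip(ETA_PARAMS, shr)),
        converged=bool(best.success),
        n_subjects=dataset.n_subjects,
        n_obs=dataset.n_obs,
        subject_ids=list(dataset.ids),
    )
    if compute_se:
        result.se_pct = standard_errors(result, dataset, settings)
    return result


def standard_errors(
    fit_result: FitResult,
    dataset: PKDataset | Sequence[SubjectProfile],
    settings: FoceSettings | None = None,
    step: float = 1e-3,
) -> dict | None:
    """Percent standard errors from the central-difference Hessian of the
    OFV at the optimum: covariance = 2 H^-1, delta method to the natural
    scale (for log-parameterized entries SE% = 100*SE_log). Returns None
    with a warning entry when the Hessian is not positive definite.
    """
    settings = settings or FoceSettings()
    if not isinstance(dataset, PKDataset):
        dataset = PKDataset.from_profiles(dataset)
    template = fit_result.spec
    objective = _make_objective(template, dataset, settings)
    x = _pack(template)
    p = x.size
    H = np.empty((p, p))
    f0 = objective(x)
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        xe = x.copy(); xe[i] += step
        fp[i] = objective(xe)
        xe = x.copy(); xe[i] -= step
        fm[i] = objective(xe)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / step**2
    for i in range(p):
        for j in range(i + 1, p):
            xe = x.copy(); xe[i] += step; xe[j] += step
            fpp = objective(xe)
            xe = x.copy(); xe[i] += step; xe[j] -= step
            fpm = objective(xe)
            xe = x.copy(); xe[i] -= step; xe[j] += step
            fmp = objective(xe)
            xe = x.copy(); xe[i] -= step; xe[j] -= step
            fmm = objective(xe)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step**2)
    # parameters at a variance floor (or otherwise curvature-free, e.g. a
    # variance component estimated at zero) make H singular; their SEs are
    # reported missing and the remaining block is inverted
    diag = np.diag(H)
    keep = diag > 1e-6 * max(diag.max(), 1.0)
    Hk = H[np.ix_(keep, keep)]
    ev, V = np.linalg.eigh(Hk)
    if ev.size == 0 or ev.min() < -1e-4 * ev.max():
        return None  # genuinely indefinite: no usable covariance
    # eigenvalues at the finite-difference noise floor are treated as
    # curvature-free directions and dropped from the inverse
    pos = ev > 1e-8 * ev.max()
    cov = 2.0 * (V[:, pos] / ev[pos]) @ V[:, pos].T
    se_k = np.sqrt(np.maximum(np.diag(cov), 0.0))
    se = np.full(p, math.nan)
    se[keep] = se_k
    labels = _param_labels(template)
    c = len(template.covariate_effects)
    out = {}
    for i, lab in enumerate(labels):
        if 4 <= i < 4 + c:  # natural-scale coefficient
            est = template.covariate_effects[i - 4].coefficient
            out[lab] = 100.0 * se[i] / abs(est) if est != 0.0 else math.inf
        else:               # log-scale parameter: SE% = 100 * SE_log
            out[lab] = 100.0 * se[i]
    return out


def eta_shrinkage(ebes: np.ndarray, omega2: np.ndarray) -> np.ndarray:
    """Per-eta shrinkage: 100 * (1 - SD(eta_hat)/sqrt(omega2))."""
    ebes = np.atleast_2d(np.asarray(ebes, dtype=float))
    omega2 = np.asarray(omega2, dtype=float)
    if np.any(omega2 <= 0.0):
        raise ValueError("omega2 must be strictly positive for shrinkage")
    sd = ebes.std(axis=0, ddof=1) if ebes.shape[0] > 1 else np.zeros(ebes.shape[1])
    return 100.0 * (1.0 - sd / np.sqrt(omega2))
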