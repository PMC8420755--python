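"""Closed-form linear two-compartment IV-bolus kinetics.

The disposition model is parameterized in clearance terms — CL (mL/day/kg),
central volume V1 (mL/kg), intercompartmental clearance Q (mL/day/kg) and
peripheral volume V2 (mL/kg) — with all quantities expressed per kg body
weight so that body weight cancels throughout. Time is in days internally.

For an IV bolus of ``dose`` μg/kg the plasma concentration is the
biexponential

    C(t) = dose * (A * exp(-alpha*t) + B * exp(-beta*t)),

where alpha > beta are the hybrid rate constants (roots of
``s^2 - (k10+k12+k21)*s + k10*k21``) and A + B = 1/V1, so C(0) = dose/V1.
The analytic area under the curve from zero to infinity is dose/CL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PKParams",
    "MicroConstants",
    "HybridConstants",
    "micro_constants",
    "hybrid_constants",
    "concentration",
    "analytic_auc_inf",
]

#: relative separation below which the two hybrid roots are treated as
#: degenerate (repeated-root profiles are out of scope and rejected).
ALPHA_BETA_MIN_SEPARATION = 1e-10


@dataclass(frozen=True)
class PKParams:
    """Structural disposition parameters, per kg body weight.

    CL : clearance, mL/day/kg
    V1 : central volume of distribution, mL/kg
    Q  : intercompartmental clearance, mL/day/kg
    V2 : peripheral volume of distribution, mL/kg
    """

    CL: float
    V1: float
    Q: float
    V2: float

    def __post_init__(self) -> None:
        for name in ("CL", "V1", "Q", "V2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0.0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.CL, self.V1, self.Q, self.V2], dtype=float)


@dataclass(frozen=True)
class MicroConstants:
    """First-order micro rate constants (1/day)."""

    k10: float
    k12: float
    k21: float


@dataclass(frozen=True)
class HybridConstants:
    """Biexponential macro constants: rates alpha > beta (1/day) and
    coefficients A, B (kg/mL) with A + B = 1/V1."""

    alpha: float
    beta: float
    coefA: float
    coefB: float


def micro_constants(params: PKParams) -> MicroConstants:
    """Convert clearance parameters to micro constants.

    k10 = CL/V1 (elimination), k12 = Q/V1, k21 = Q/V2.
    """
    return MicroConstants(
        k10=params.CL / params.V1,
        k12=params.Q / params.V1,
        k21=params.Q / params.V2,
    )


def hybrid_constants(k: MicroConstants, V1: float) -> HybridConstants:
    """Hybrid (macro) constants of the biexponential solution.

    alpha and beta are the roots of s^2 - (k10+k12+k21) s + k10*k21;
    coefA = (alpha - k21) / (V1 (alpha - beta)),
    coefB = (k21 - beta) / (V1 (alpha - beta)).

    Raises
    ------
    ValueError
        if the roots are degenerate (relative separation below
        ``ALPHA_BETA_MIN_SEPARATION``); repeated-root kinetics are
        unsupported input here.
    """
    if min(k.k10, k.k12, k.k21) <= 0.0 or V1 <= 0.0:
        raise ValueError("micro constants and V1 must be strictly positive")
    s = k.k10 + k.k12 + k.k21
    p = k.k10 * k.k21
    disc = s * s - 4.0 * p
    if disc <= 0.0:
        raise ValueError("degenerate hybrid roots (alpha == beta) unsupported")
    root = np.sqrt(disc)
    alpha = 0.5 * (s + root)
    beta = p / alpha  # stable form: (s - root)/2 cancels when p << s^2
    if (alpha - beta) <= ALPHA_BETA_MIN_SEPARATION * alpha:
        raise ValueError("degenerate hybrid roots (alpha ~= beta) unsupported")
    coefA = (alpha - k.k21) / (V1 * (alpha - beta))
    coefB = (k.k21 - beta) / (V1 * (alpha - beta))
    return HybridConstants(alpha=alpha, beta=beta, coefA=coefA, coefB=coefB)


def concentration(params: PKParams, dose: float, t):
    """Plasma concentration (μg/mL) at time ``t`` (days) after an IV bolus.

    ``t`` may be a scalar or array; all entries must be >= 0. ``dose`` is in
    μg/kg. Linear kinetics: the result is proportional to dose.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("time must be non-negative")
    if dose < 0.0:
        raise ValueError("dose must be non-negative")
    h = hybrid_constants(micro_constants(params), params.V1)
    c = dose * (h.coefA * np.exp(-h.alpha * t) + h.coefB * np.exp(-h.beta * t))
    return c if c.ndim else float(c)


def analytic_auc_inf(params: PKParams, dose: float) -> float:
    """AUC from zero to infinity, day·μg/mL: exactly dose/CL."""
    if dose < 0.0:
        raise ValueError("dose must be non-negative")
    return dose / params.CL


# ---------------------------------------------------------------------------
# Vectorized kernel used by the simulator and the FOCE engine.
# ---------------------------------------------------------------------------

def concentration_batch(
    cl: np.ndarray,
    v1: np.ndarray,
    q: np.ndarray,
    v2: np.ndarray,
    dose: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Concentrations for a batch of subjects.

    Parameters are 1-D arrays of length n; ``times`` is (n, m) in days.
    Returns an (n, m) array. No positivity validation beyond what the
    arithmetic requires — callers guarantee positive parameters.
    """
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = s * s - 4.0 * k10 * k21
    root = np.sqrt(np.maximum(disc, 0.0))
    alpha = 0.5 * (s + root)
    beta = k10 * k21 / alpha
    denom = v1 * (alpha - beta)
    coefA = (alpha - k21) / denom
    coefB = (k21 - beta) / denom
    return dose[:, None] * (
        coefA[:, None] * np.exp(-alpha[:, None] * times)
        + coefB[:, None] * np.exp(-beta[:, None] * times)
    )
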