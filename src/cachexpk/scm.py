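"""Stepwise covariate modelling by likelihood-ratio testing.

Candidate covariate–parameter effects are screened one at a time against
the base model, added forward (re-screening all remaining candidates
against the growing model each round, so the ΔOFV trace is sequential),
and pruned by backward elimination at the same significance level. Each
added effect contributes one coefficient, so the likelihood-ratio test
uses χ²(1) on −ΔOFV. Effects can be forced into the model (kept regardless
of the elimination test), mirroring the study's choice to retain total IgG
on Q despite no estimable IIV on that parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd
from scipy import stats

from .cohort import CovariateEffect, PopulationModelSpec
from .foce import FitResult, FoceSettings, PKDataset, fit

__all__ = [
    "ScmRecord",
    "ScmSettings",
    "lrt_p",
    "univariate_screen",
    "forward_addition",
    "backward_elimination",
    "records_to_frame",
]


@dataclass(frozen=True)
class ScmRecord:
    """One screening/addition/elimination step of the selection trace."""

    model_label: str
    parameter: str
    covariate: str
    ofv: float
    delta_ofv: float
    p_value: float
    action: Literal["screened", "added", "removed", "retained", "failed"]


@dataclass(frozen=True)
class ScmSettings:
    """SCM configuration: significance levels and per-fit settings.

    Forward and backward use the same alpha = 0.05 by default (the study's
    choice; stricter backward thresholds are common elsewhere and can be
    set independently). SCM refits use a single optimizer start warm-
    started from the current model; the final reported model can be
    re-fitted with the full multi-start policy afterwards.
    """

    alpha_forward: float = 0.05
    alpha_backward: float = 0.05
    forced_effects: tuple = ()
    fit_settings: FoceSettings = field(default_factory=lambda: FoceSettings(n_starts=1))


def lrt_p(delta_ofv: float, df: int = 1) -> float:
    """Upper-tail χ²(df) probability of an OFV drop.

    ``delta_ofv`` follows the extended-minus-reference convention (<= 0 for
    an improvement); a non-negative delta returns p = 1.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if delta_ofv >= 0.0:
        return 1.0
    return float(stats.chi2.sf(-delta_ofv, df))


def _fit_spec(dataset, spec, settings: ScmSettings) -> FitResult:
    return fit(dataset, spec, settings.fit_settings)


def univariate_screen(
    dataset: PKDataset | Sequence,
    base_spec: PopulationModelSpec,
    candidates: Sequence[CovariateEffect],
    settings: ScmSettings | None = None,
    base_fit: FitResult | None = None,
) -> list[ScmRecord]:
    """Fit base + one candidate effect for every candidate.

    Records are sorted by ΔOFV ascending (most significant first). A fit
    failure yields a record with action='failed' and p = 1.
    """
    settings = settings or ScmSettings()
    if not isinstance(dataset, PKDataset):
        dataset = PKDataset.from_profiles(dataset)
    if base_fit is None:
        base_fit = _fit_spec(dataset, base_spec, settings)
    records = []
    for eff in candidates:
        label = f"base + {eff.label}"
        try:
            ext = _fit_spec(dataset, base_fit.spec.with_effect(eff), settings)
            d = ext.ofv - base_fit.ofv
            records.append(ScmRecord(label, eff.parameter, eff.covariate,
                                     ext.ofv, d, lrt_p(d), "screened"))
        except (ValueError, FloatingPointError):
            records.append(ScmRecord(label, eff.parameter, eff.covariate,
                                     float("nan"), float("nan"), 1.0, "failed"))
    records.sort(key=lambda r: (r.delta_ofv if r.delta_ofv == r.delta_ofv else 1e9))
    return records


def forward_addition(
    dataset: PKDataset | Sequence,
    base_spec: PopulationModelSpec,
    candidates: Sequence[CovariateEffect],
    settings: ScmSettings | None = None,
) -> tuple[PopulationModelSpec, list[ScmRecord], FitResult]:
    """Forward stepwise addition at ``alpha_forward``.

    Each round refits every remaining candidate against the growing model
    and adds the one with the smallest p-value below alpha; stops when no
    candidate passes. Returns (final spec, trace, final fit). The trace
    holds one 'added' record per round (sequential ΔOFVs against the
    growing model, the shape of a forward-addition table).
    """
    settings = settings or ScmSettings()
    if not isinstance(dataset, PKDataset):
        dataset = PKDataset.from_profiles(dataset)
    current = _fit_spec(dataset, base_spec, settings)
    remaining = list(candidates)
    trace: list[ScmRecord] = []
    label_chain = "base"
    while remaining:
        screened = univariate_screen(dataset, current.spec, remaining,
                                     settings, base_fit=current)
        best = screened[0]
        if not (best.p_value < settings.alpha_forward) or best.action == "failed":
            break
        eff = next(
            e for e in remaining
            if e.parameter == best.parameter and e.covariate == best.covariate
        )
        label_chain = f"{label_chain} + {eff.label}"
        current = _fit_spec(dataset, current.spec.with_effect(eff), settings)
        trace.append(ScmRecord(label_chain, eff.parameter, eff.covariate,
                               current.ofv, best.delta_ofv, best.p_value, "added"))
        remaining.remove(eff)
    return current.spec, trace, current


def backward_elimination(
    dataset: PKDataset | Sequence,
    full_spec: PopulationModelSpec,
    settings: ScmSettings | None = None,
) -> tuple[PopulationModelSpec, list[ScmRecord], FitResult]:
    """Backward elimination at ``alpha_backward``.

    Repeatedly removes the effect whose removal is least harmful (largest
    removal p-value >= alpha, strict inequality required for removal, so a
    removal sitting exactly at the χ² threshold is retained). Effects
    listed in ``settings.forced_effects`` (by label) are never removed.
    Returns (final spec, trace, final fit); retained effects get one
    'retained' record each.
    """
    settings = settings or ScmSettings()
    if not isinstance(dataset, PKDataset):
        dataset = PKDataset.from_profiles(dataset)
    current = _fit_spec(dataset, full_spec, settings)
    forced = set(settings.forced_effects)
    trace: list[ScmRecord] = []
    while True:
        removable = [e for e in current.spec.covariate_effects if e.label not in forced]
        if not removable:
            break
        best_eff = None
        best_rec = None
        for eff in removable:
            reduced = _fit_spec(dataset, current.spec.without_effect(eff), settings)
            d = reduced.ofv - current.ofv  # >= 0: removal worsens the fit
            p = lrt_p(-d)  # p of the effect's contribution
            rec = ScmRecord(f"drop {eff.label}", eff.parameter, eff.covariate,
                            reduced.ofv, d, p, "removed")
            if best_rec is None or rec.p_value > best_rec.p_value:
                best_rec, best_eff = rec, eff
        # removal requires the effect to be non-significant: p >= alpha,
        # with the boundary itself retained (strict > would drop it)
        if best_rec is None or best_rec.p_value < settings.alpha_backward or (
            abs(best_rec.p_value - settings.alpha_backward) < 1e-12
        ):
            break
        trace.append(best_rec)
        current = _fit_spec(dataset, current.spec.without_effect(best_eff), settings)
    for eff in current.spec.covariate_effects:
        trace.append(ScmRecord(f"retain {eff.label}", eff.parameter, eff.covariate,
                               current.ofv, 0.0, float("nan"), "retained"))
    return current.spec, trace, current


def records_to_frame(records: Sequence[ScmRecord]) -> pd.DataFrame:
    """Selection-trace records as a DataFrame (model, OFV, dOFV, p)."""
    return pd.DataFrame(
        [
            {"model": r.model_label, "parameter": r.parameter,
             "covariate": r.covariate, "OFV": r.ofv, "dOFV": r.delta_ofv,
             "p_value": r.p_value, "action": r.action}
            for r in records
        ]
    )
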