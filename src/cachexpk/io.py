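"""Dataset and configuration I/O.

The pipeline dataset is a NONMEM-like rectangular CSV: one row per dose
event (EVID=1, AMT in μg/kg) or observation (EVID=0, DV in μg/mL), TIME in
hours, a '.' missing marker, and constant per-subject covariate columns
(TUM, STR, DOSEGRP, MWT, FWT, PBWT, IGG, ALB, FCRN, plus BQL per
observation). Vehicle animals appear as a single AMT=0 dose row so their
covariates survive the round trip.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    CovariateEffect,
    CovariateGeneratorConfig,
    CovariateVector,
    DoseEvent,
    ObsRecord,
    PopulationModelSpec,
    StudyDesign,
    SubjectProfile,
    final_covariate_model_spec,
    structural_model_spec,
)
from .compartmental import PKParams

__all__ = [
    "cohort_to_frame",
    "profiles_from_frame",
    "write_dataset",
    "read_dataset",
    "load_config",
    "design_from_config",
    "model_from_config",
    "file_sha256",
]

REQUIRED_COLUMNS = [
    "ID", "TIME", "DV", "AMT", "EVID", "BQL",
    "TUM", "STR", "DOSEGRP", "MWT", "FWT", "PBWT", "IGG", "ALB", "FCRN",
]
MISSING = "."

_COV_MAP = [
    ("TUM", "tumour"), ("STR", "strain"), ("MWT", "muscle_weight"),
    ("FWT", "fat_weight"), ("PBWT", "pct_bw_change"), ("IGG", "igg_total"),
    ("ALB", "albumin"), ("FCRN", "fcgrt_expr"),
]


def cohort_to_frame(profiles: Sequence[SubjectProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        cov = {col: getattr(p.covariates, attr) for col, attr in _COV_MAP}
        cov["DOSEGRP"] = p.covariates.dose_group
        rows.append({"ID": p.subject_id, "TIME": 0.0, "DV": np.nan,
                     "AMT": p.dose.amount, "EVID": 1, "BQL": np.nan, **cov})
        for r in p.records:
            rows.append({"ID": p.subject_id, "TIME": r.time_h, "DV": r.conc,
                         "AMT": np.nan, "EVID": 0, "BQL": int(r.bql), **cov})
    return pd.DataFrame(rows, columns=REQUIRED_COLUMNS)


def profiles_from_frame(frame: pd.DataFrame) -> list[SubjectProfile]:
    """Reconstruct subject profiles from a validated dataset frame."""
    profiles = []
    for sid, g in frame.groupby("ID", sort=False):
        doses = g[g["EVID"] == 1]
        amt = float(doses["AMT"].iloc[0]) if len(doses) else 0.0
        first = g.iloc[0]
        cov = CovariateVector(
            tumour=int(first["TUM"]), strain=int(first["STR"]),
            dose_group=str(first["DOSEGRP"]),
            muscle_weight=float(first["MWT"]), fat_weight=float(first["FWT"]),
            pct_bw_change=float(first["PBWT"]), igg_total=float(first["IGG"]),
            albumin=float(first["ALB"]), fcgrt_expr=float(first["FCRN"]),
        )
        obs = g[g["EVID"] == 0].sort_values("TIME")
        records = tuple(
            ObsRecord(float(r["TIME"]), float(r["DV"]), bool(int(r["BQL"])))
            for _, r in obs.iterrows()
        )
        profiles.append(SubjectProfile(str(sid), DoseEvent(amount=amt), cov, records))
    return profiles


def write_dataset(frame_or_profiles, path) -> Path:
    frame = (
        frame_or_profiles
        if isinstance(frame_or_profiles, pd.DataFrame)
        else cohort_to_frame(frame_or_profiles)
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, na_rep=MISSING, float_format="%.10g")
    return path


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a pipeline dataset CSV.

    Raises ValueError naming the offending column/rows for: missing
    columns, non-numeric fields, duplicate (ID, TIME, EVID) keys, DV
    present on dose rows or missing on observation rows, or negative times.
    """
    frame = pd.read_csv(path, na_values=[MISSING], dtype={"ID": str, "DOSEGRP": str})
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"dataset missing required column(s): {missing_cols}")
    for col in [c for c in REQUIRED_COLUMNS if c not in ("ID", "DOSEGRP")]:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            raise ValueError(f"column {col} contains non-numeric values")
    dup = frame.duplicated(subset=["ID", "TIME", "EVID"])
    if dup.any():
        raise ValueError(
            f"duplicate (ID, TIME, EVID) keys at rows {list(frame.index[dup])}"
        )
    if (frame["TIME"] < 0).any():
        raise ValueError("negative TIME values")
    obs = frame["EVID"] == 0
    if frame.loc[obs, "DV"].isna().any():
        bad = list(frame.index[obs & frame["DV"].isna()])
        raise ValueError(f"observation rows missing DV at rows {bad}")
    if frame.loc[~obs, "DV"].notna().any():
        bad = list(frame.index[(~obs) & frame["DV"].notna()])
        raise ValueError(f"dose rows carry DV at rows {bad}")
    if frame.loc[~obs, "AMT"].isna().any():
        raise ValueError("dose rows missing AMT")
    return frame


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    return cfg


def model_from_config(cfg: dict) -> PopulationModelSpec:
    """Model spec from the ``model`` config section.

    ``model.reference`` picks a named reference model ('structural' or
    'final_covariate'); otherwise theta/omega2/sigma/effects are read
    explicitly. Omitted entirely, the final covariate model is used.
    """
    section = cfg.get("model") or {}
    ref = section.get("reference")
    if ref == "structural":
        spec = structural_model_spec()
    elif ref in (None, "final_covariate"):
        spec = final_covariate_model_spec()
    else:
        raise ValueError(f"unknown model.reference {ref!r}")
    if "theta" in section:
        spec = PopulationModelSpec(
            theta=PKParams(**section["theta"]),
            covariate_effects=tuple(
                CovariateEffect(**e) for e in section.get("effects", [])
            ),
            omega2=section.get("omega2", dict(spec.omega2)),
            sigma_log=section.get("sigma_log", spec.sigma_log),
            covariate_medians=section.get("covariate_medians", {}),
        )
    return spec


def design_from_config(cfg: dict) -> StudyDesign:
    section = cfg.get("design") or {}
    kwargs = {}
    for key in ("sample_times_h", "terminal_choices_h", "arms"):
        if key in section:
            kwargs[key] = tuple(
                tuple(v) if isinstance(v, list) else v for v in section[key]
            ) if key == "arms" else tuple(section[key])
    for key in ("terminal_h", "artifact_rate", "artifact_ka_per_day", "lloq"):
        if key in section:
            kwargs[key] = section[key]
    if "artifact_iv_fraction_range" in section:
        kwargs["artifact_iv_fraction_range"] = tuple(section["artifact_iv_fraction_range"])
    if "covariates" in cfg:
        kwargs["covariates"] = CovariateGeneratorConfig(**cfg["covariates"])
    kwargs["model"] = model_from_config(cfg)
    return StudyDesign(**kwargs)


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
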