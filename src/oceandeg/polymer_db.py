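"""Curated polymer property / degradation tables.

One row per polymer (bulk thermal properties, molecular-composition
descriptors, the LogP/SA hydrophobicity index) plus a separate observation
table of exposure experiments keyed by polymer id.  Units are fixed at the
schema level and embedded in the CSV header (°C, kg mol⁻¹, g cm⁻³, J g⁻¹,
Å⁻², mg cm⁻² day⁻¹); a reader confronted with different unit annotations
rejects the file rather than converting silently.

Missing values stay missing: analyses select complete cases explicitly
(``select_complete``), and any literature supplementation is an upstream
curation step, not something this module does implicitly.
"""

from __future__ import annotations

import json
import logging
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

RECORD_COLUMNS = [
    "id", "name", "polymer_class", "source",
    "tg_C", "tm_C", "mn_kg_mol", "mw_kg_mol", "dispersity",
    "density_g_cm3", "crystallinity_pct", "enthalpy_melting_J_g",
    "logp_per_sa_A2",
    "pct_sp3_carbons", "pct_n_atoms", "ch3_per_monomer", "ch2_per_monomer",
    "ch_per_monomer", "ring_count",
    "provenance", "schema_version",
]

OBSERVATION_COLUMNS = [
    "polymer_id", "condition", "t_water_C", "depth_m", "days",
    "mass_loss_mg", "sa_bulk_cm2", "erosion_rate_mg_cm2_day", "bod_rate_pct_day",
    "reference", "schema_version",
]

#: numeric feature names usable in analyses (mapped to record attributes)
FEATURES = {
    "Tg": "tg_C",
    "Tm": "tm_C",
    "Mn": "mn_kg_mol",
    "Mw": "mw_kg_mol",
    "dispersity": "dispersity",
    "density": "density_g_cm3",
    "crystallinity": "crystallinity_pct",
    "enthalpy": "enthalpy_melting_J_g",
    "logp_per_sa": "logp_per_sa_A2",
    "pct_sp3_carbons": "pct_sp3_carbons",
    "pct_n_atoms": "pct_n_atoms",
}


class PolymerRecord(BaseModel):
    """One polymer's identity, bulk properties and descriptors (nullable fields)."""

    id: str
    name: str
    polymer_class: str = "unknown"
    source: Literal["commercial", "laboratory", "unknown"] = "unknown"
    tg_C: Optional[float] = None
    tm_C: Optional[float] = None
    mn_kg_mol: Optional[float] = None
    mw_kg_mol: Optional[float] = None
    dispersity: Optional[float] = None
    density_g_cm3: Optional[float] = Field(default=None, gt=0)
    crystallinity_pct: Optional[float] = Field(default=None, ge=0, le=100)
    enthalpy_melting_J_g: Optional[float] = Field(default=None, ge=0)
    logp_per_sa_A2: Optional[float] = None
    pct_sp3_carbons: Optional[float] = Field(default=None, ge=0, le=100)
    pct_n_atoms: Optional[float] = Field(default=None, ge=0, le=100)
    ch3_per_monomer: Optional[int] = Field(default=None, ge=0)
    ch2_per_monomer: Optional[int] = Field(default=None, ge=0)
    ch_per_monomer: Optional[int] = Field(default=None, ge=0)
    ring_count: Optional[int] = Field(default=None, ge=0)
    provenance: str = ""
    schema_version: int = SCHEMA_VERSION

    @model_validator(mode="after")
    def _dispersity_consistent(self) -> "PolymerRecord":
        if self.dispersity is not None and self.dispersity < 1:
            raise ValueError(f"dispersity must be >= 1, got {self.dispersity}")
        if None not in (self.dispersity, self.mw_kg_mol, self.mn_kg_mol):
            implied = self.mw_kg_mol / self.mn_kg_mol
            if abs(self.dispersity - implied) > 0.05 * max(implied, 1.0):
                raise ValueError(
                    f"dispersity {self.dispersity} inconsistent with Mw/Mn = {implied:.3f}"
                )
        return self

    def feature(self, name: str) -> Optional[float]:
        if name not in FEATURES:
            raise KeyError(f"unknown feature {name!r}; known: {sorted(FEATURES)}")
        return getattr(self, FEATURES[name])


class DegradationObservation(BaseModel):
    """One exposure experiment for a polymer."""

    polymer_id: str
    condition: Literal["abiotic", "biotic", "ocean", "enzyme"]
    t_water_C: Optional[float] = None
    depth_m: Optional[float] = Field(default=None, ge=0)
    days: float = Field(gt=0)
    mass_loss_mg: Optional[float] = Field(default=None, ge=0)
    sa_bulk_cm2: Optional[float] = Field(default=None, gt=0)
    erosion_rate_mg_cm2_day: Optional[float] = Field(default=None, ge=0)
    bod_rate_pct_day: Optional[float] = Field(default=None, ge=0)
    reference: str = ""
    schema_version: int = SCHEMA_VERSION

    @model_validator(mode="after")
    def _has_a_measure(self) -> "DegradationObservation":
        direct = self.erosion_rate_mg_cm2_day is not None
        derivable = self.mass_loss_mg is not None and self.sa_bulk_cm2 is not None
        if not (direct or derivable or self.bod_rate_pct_day is not None):
            raise ValueError(
                "observation needs erosion_rate, (mass_loss and SA_bulk), or bod_rate"
            )
        return self


class LoadReport:
    """Validated records plus per-row violations (row numbers are 1-based data rows)."""

    def __init__(self, records: list, errors: list[tuple[int, str]]):
        self.records = records
        self.errors = errors

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _load_table(path, columns, model) -> LoadReport:
    try:
        frame = pd.read_csv(path, dtype={"id": str, "polymer_id": str})
    except pd.errors.EmptyDataError:
        logger.warning("empty table at %s", path)
        return LoadReport([], [])
    missing = [c for c in columns if c not in frame.columns]
    extra = [c for c in frame.columns if c not in columns]
    if missing or extra:
        raise ValueError(
            f"schema mismatch in {path}: missing columns {missing}, unexpected columns {extra} "
            "(unit annotations are part of the column names and are not converted)"
        )
    records, errors = [], []
    for row_no, row in enumerate(frame.to_dict(orient="records"), start=1):
        clean = {k: (None if pd.isna(v) else v) for k, v in row.items()}
        try:
            records.append(model(**clean))
        except Exception as exc:  # pydantic ValidationError
            errors.append((row_no, str(exc)))
    if errors:
        logger.warning("%d of %d rows failed validation", len(errors), len(frame))
    return LoadReport(records, errors)


def load_records(path) -> LoadReport:
    """Read and validate a polymer-record CSV; invalid rows are collected, not raised."""
    return _load_table(path, RECORD_COLUMNS, PolymerRecord)


def load_observations(path) -> LoadReport:
    """Read and validate a degradation-observation CSV."""
    return _load_table(path, OBSERVATION_COLUMNS, DegradationObservation)


def records_to_frame(records) -> pd.DataFrame:
    columns = RECORD_COLUMNS if records and isinstance(records[0], PolymerRecord) else None
    frame = pd.DataFrame([r.model_dump() for r in records])
    return frame[columns] if columns else frame


def write_records(records, path) -> None:
    records_to_frame(list(records)).to_csv(path, index=False)


def write_observations(observations, path) -> None:
    frame = pd.DataFrame([o.model_dump() for o in observations])
    frame[OBSERVATION_COLUMNS].to_csv(path, index=False)


def to_json(records, **kwargs) -> str:
    return json.dumps([r.model_dump() for r in records], **kwargs)


def select_complete(records, features: list[str]) -> list[PolymerRecord]:
    """Records non-null in every requested feature (no imputation).

    An empty feature list is the vacuous condition and returns all records.
    The number of excluded records is logged.
    """
    for name in features:
        if name not in FEATURES:
            raise KeyError(f"unknown feature {name!r}; known: {sorted(FEATURES)}")
    records = list(records)
    kept = [r for r in records if all(r.feature(f) is not None for f in features)]
    if len(kept) < len(records):
        logger.info(
            "select_complete: excluded %d of %d records missing %s",
            len(records) - len(kept), len(records), features,
        )
    return kept


def fit_density_calibration(pairs) -> tuple[float, float, float]:
    """OLS line density = slope·x + intercept; returns (slope, intercept, R²).

    Used to fill missing densities (for mass/surface-area bookkeeping) from a
    correlated predictor, mirroring per-class calibration curves.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise ValueError("need >= 2 (predictor, density) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("degenerate calibration input: all predictor values equal")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(slope), float(intercept), r2


def correlation_matrix(records, features: list[str], min_cases: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between features.

    Entries backed by fewer than ``min_cases`` complete cases are NaN rather
    than fabricated.  The result is symmetric with a unit diagonal wherever
    a feature has enough observations.
    """
    data = {}
    for name in features:
        if name not in FEATURES:
            raise KeyError(f"unknown feature {name!r}; known: {sorted(FEATURES)}")
        data[name] = [r.feature(name) for r in records]
    frame = pd.DataFrame(data, dtype=float)
    corr = frame.corr(method="pearson", min_periods=min_cases)
    # unit diagonal only where the feature itself has enough values
    for name in features:
        if frame[name].notna().sum() < min_cases:
            corr.loc[name, name] = np.nan
    return corr
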