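"""Closed-form surface-erosion models for seawater exposure.

Two equations link polymer physical properties and environment to surface
erosion (mg cm⁻² day⁻¹):

*Temperature-slope model.*  The sensitivity of erosion rate to seawater
temperature is

    k = exp( (T_water − Tg) / (LogP/SA) − c1 ) / c2,

with c1 = 28795 (°C·Å²) and c2 = 4177.3 as printed defaults (both
configurable — the constants are empirical and may be re-fitted).  The
model applies to polyesters and polyamides with LogP/SA > 0 and enthalpy of
melting below 85 J g⁻¹; outside those bounds it overestimates k, so
``check_applicability`` must gate any prediction.

*Total-erosion model.*  Total erosion combines the temperature-dependent
abiotic/biotic term with a mechanical wave contribution:

    E_total = k·T_water + b + E_waves,

where b is the intercept in the absence of mechanical forces and E_waves is
the measured difference between exposed and sheltered sites (e.g. ~0.017
mg cm⁻² day⁻¹ for a coastal location vs a sheltered mangrove).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DEFAULT_C1 = 28795.0  # (°C)·Å²
DEFAULT_C2 = 4177.3
ENTHALPY_BOUND_J_G = 85.0


class ApplicabilityError(ValueError):
    """The temperature-slope model is not defined for these inputs."""


@dataclass(frozen=True)
class ErosionModelParams:
    """Parameters of the total-erosion model (units: mg cm⁻² day⁻¹ family)."""

    k: float  # mg cm⁻² day⁻¹ °C⁻¹
    b: float  # intercept in the absence of mechanical forces
    e_waves: float  # wave contribution
    t_water: float  # °C
    c1: float = DEFAULT_C1
    c2: float = DEFAULT_C2

    def __post_init__(self):
        if self.e_waves < 0:
            raise ValueError("E_waves must be non-negative")
        if self.c2 <= 0:
            raise ValueError("c2 must be positive")


@dataclass(frozen=True)
class ApplicabilityVerdict:
    applicable: bool
    reasons: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if self.applicable != (len(self.reasons) == 0):
            raise ValueError("applicable must be equivalent to an empty reason list")


def erosion_slope_k(
    t_water: float,
    tg: float,
    logp_per_sa: float,
    c1: float = DEFAULT_C1,
    c2: float = DEFAULT_C2,
) -> float:
    """Temperature slope k (mg cm⁻² day⁻¹ °C⁻¹), exactly as the model is printed.

    Strictly increasing in ``t_water`` and decreasing in ``tg``; undefined
    (raises) for non-positive hydrophobicity indices.
    """
    if logp_per_sa <= 0:
        raise ApplicabilityError(
            f"temperature-slope model is undefined for LogP/SA = {logp_per_sa} <= 0"
        )
    with np.errstate(over="raise"):
        return float(np.exp((t_water - tg) / logp_per_sa - c1) / c2)


def check_applicability(
    logp_per_sa: float | None,
    enthalpy_melting: float | None,
    enthalpy_bound: float = ENTHALPY_BOUND_J_G,
) -> ApplicabilityVerdict:
    """Gate for the temperature-slope model: LogP/SA > 0 and enthalpy < bound.

    Accepts either raw values or a PolymerRecord via its attributes; missing
    values are an error (the verdict cannot be evaluated without them).
    """
    if logp_per_sa is None or enthalpy_melting is None:
        raise ValueError("applicability requires both logp_per_sa and enthalpy_melting")
    reasons = []
    if logp_per_sa <= 0:
        reasons.append(f"LogP/SA = {logp_per_sa} Å⁻² is not positive")
    if enthalpy_melting >= enthalpy_bound:
        reasons.append(
            f"enthalpy of melting {enthalpy_melting} J g⁻¹ is not below {enthalpy_bound} J g⁻¹"
        )
    return ApplicabilityVerdict(applicable=not reasons, reasons=tuple(reasons))


def check_applicability_record(record, enthalpy_bound: float = ENTHALPY_BOUND_J_G) -> ApplicabilityVerdict:
    """Applicability verdict for a PolymerRecord."""
    return check_applicability(
        record.logp_per_sa_A2, record.enthalpy_melting_J_g, enthalpy_bound
    )


def total_erosion(params: ErosionModelParams) -> float:
    """E_total = k·T_water + b + E_waves (mg cm⁻² day⁻¹)."""
    return params.k * params.t_water + params.b + params.e_waves


def fit_erosion_line(observations) -> tuple[float, float, float, float]:
    """OLS of erosion rate on seawater temperature.

    Returns (k_hat, b_hat, k_stderr, b_stderr); the slope is the empirical
    temperature sensitivity, the intercept absorbs b + E_waves when wave
    action is not separated out.
    """
    arr = np.asarray(list(observations), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise ValueError("need >= 3 (temperature, rate) pairs")
    temps, rates = arr[:, 0], arr[:, 1]
    if np.unique(temps).size < 2:
        raise ValueError("degenerate temperature column: all values equal")
    fit = stats.linregress(temps, rates)
    return (
        float(fit.slope),
        float(fit.intercept),
        float(fit.stderr),
        float(fit.intercept_stderr),
    )
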