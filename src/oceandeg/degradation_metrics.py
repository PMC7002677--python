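"""Surface-erosion rates and ordinal degradation categories.

Raw seawater-exposure measurements are reduced to a surface erosion rate
(mass loss normalized by exposed bulk surface area and time, mg cm⁻² day⁻¹)
or arrive as biochemical oxygen demand (BOD, % of theoretical demand per
day).  Either measure maps onto ordered category scales:

5-tier (erosion rate, mg cm⁻² day⁻¹):
    very_slow [0, 0.0003) < slow [0.0003, 0.003) < medium [0.003, 0.03)
    < fast [0.03, 0.3) < very_fast [0.3, ∞)
5-tier (BOD, % day⁻¹): cuts at 2, 4, 6, 8.
3-tier (erosion rate): slow [0, 0.003) < medium [0.003, 0.3) < fast [0.3, ∞)
3-tier (BOD): cuts at 4 and 8.

Intervals are lower-inclusive/upper-exclusive so every non-negative value
maps to exactly one tier.
"""

from __future__ import annotations

import enum

import numpy as np
from scipy import stats


class Tier5(enum.IntEnum):
    very_slow = 0
    slow = 1
    medium = 2
    fast = 3
    very_fast = 4

    def __str__(self) -> str:  # CSV-friendly
        return self.name


class Tier3(enum.IntEnum):
    slow = 0
    medium = 1
    fast = 2

    def __str__(self) -> str:
        return self.name


# tier cutpoints, lower-inclusive
_EROSION_CUTS_5 = (0.0003, 0.003, 0.03, 0.3)
_BOD_CUTS_5 = (2.0, 4.0, 6.0, 8.0)
_EROSION_CUTS_3 = (0.003, 0.3)
_BOD_CUTS_3 = (4.0, 8.0)


def surface_erosion_rate(mass_loss: float, sa_bulk: float, days: float) -> float:
    """Erosion rate in mg cm⁻² day⁻¹ from mass loss (mg), area (cm²) and time (days)."""
    if sa_bulk <= 0:
        raise ValueError(f"SA_bulk must be positive, got {sa_bulk}")
    if days <= 0:
        raise ValueError(f"days must be positive, got {days}")
    if mass_loss < 0:
        raise ValueError(f"mass_loss must be non-negative, got {mass_loss}")
    return mass_loss / (sa_bulk * days)


def _pick_input(erosion_rate: float | None, bod_rate: float | None) -> tuple[str, float]:
    if (erosion_rate is None) == (bod_rate is None):
        raise ValueError("provide exactly one of erosion_rate or bod_rate")
    kind, value = ("erosion", erosion_rate) if erosion_rate is not None else ("bod", bod_rate)
    if value < 0:
        raise ValueError(f"{kind} rate must be non-negative, got {value}")
    return kind, float(value)


def _categorize(value: float, cuts: tuple[float, ...], scale: type) -> enum.IntEnum:
    return scale(int(np.searchsorted(cuts, value, side="right")))


def tier5_category(erosion_rate: float | None = None, bod_rate: float | None = None) -> Tier5:
    """Map one measurement onto the 5-tier scale (very_slow … very_fast)."""
    kind, value = _pick_input(erosion_rate, bod_rate)
    cuts = _EROSION_CUTS_5 if kind == "erosion" else _BOD_CUTS_5
    return _categorize(value, cuts, Tier5)


def tier3_category(erosion_rate: float | None = None, bod_rate: float | None = None) -> Tier3:
    """Map one measurement onto the 3-tier scale (slow < medium < fast)."""
    kind, value = _pick_input(erosion_rate, bod_rate)
    cuts = _EROSION_CUTS_3 if kind == "erosion" else _BOD_CUTS_3
    return _categorize(value, cuts, Tier3)


def collapse_tier5(tier: Tier5) -> Tier3:
    """Consistent 5→3 tier collapse (very_slow/slow→slow, medium/fast→medium, very_fast→fast)."""
    return Tier3((Tier3.slow, Tier3.slow, Tier3.medium, Tier3.medium, Tier3.fast)[tier])


def temperature_normalize(
    observations: list[tuple[float, float]], t_ref: float
) -> tuple[float, dict]:
    """Adjust laboratory erosion rates measured at various temperatures to ``t_ref``.

    Fits rate = k·T + b by ordinary least squares over the (temperature,
    rate) pairs and evaluates the line at ``t_ref``.  Returns the adjusted
    rate and a provenance record flagging the adjustment; single-temperature
    input is refused (no adjustment can be estimated from it).
    """
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2 or len(obs) < 2:
        raise ValueError("need >= 2 (temperature, rate) observations")
    temps, rates = obs[:, 0], obs[:, 1]
    if np.unique(temps).size < 2:
        raise ValueError(
            "all observations share one temperature; no temperature adjustment is possible"
        )
    fit = stats.linregress(temps, rates)
    adjusted = float(fit.slope * t_ref + fit.intercept)
    provenance = {
        "adjustment": "linear-in-temperature normalization",
        "t_ref_C": t_ref,
        "slope_mg_cm2_day_C": float(fit.slope),
        "intercept_mg_cm2_day": float(fit.intercept),
        "n_observations": int(len(obs)),
    }
    return adjusted, provenance
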