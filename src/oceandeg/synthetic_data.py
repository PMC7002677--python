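"""Synthetic polymer data with the statistical structure the analyses assume.

Three generators make every pipeline stage testable offline:

* ``simulate_polymers`` — polymer records with independently sampled bulk
  features spanning realistic ranges (Tg −70…150 °C, Mn log-uniform
  1…1000 kg mol⁻¹, LogP/SA −0.01…0.03 Å⁻², enthalpy 0…140 J g⁻¹,
  crystallinity 0…80%), labelled by a planted axis-aligned decision rule
  with optional label-flip noise.  This emulates the fast/medium/slow zones
  a shallow tree should recover.
* ``simulate_erosion_series`` — erosion-vs-temperature series linear in
  temperature with additive Gaussian noise, truncated at zero (the forward
  model of the total-erosion equation).
* ``fixture_database`` — a small curated table of well-known polymers whose
  numeric fields carry literature-reported values (Tg, Tm, enthalpy,
  LogP/SA), plus curated 3-tier labels for exercising the classifiers.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .degradation_metrics import Tier3
from .polymer_db import DegradationObservation, PolymerRecord, FEATURES

#: feature sampling ranges (low, high); Mn is sampled log-uniformly
FEATURE_RANGES = {
    "Tg": (-70.0, 150.0),        # °C
    "Mn": (1.0, 1000.0),         # kg mol⁻¹, log-uniform
    "logp_per_sa": (-0.01, 0.03),  # Å⁻²
    "enthalpy": (0.0, 140.0),    # J g⁻¹
    "crystallinity": (0.0, 80.0),  # %
}


@dataclass(frozen=True)
class RuleNode:
    """Axis-aligned split; children are either class names or nested splits."""

    feature: str
    threshold: float
    left: "RuleNode | str"
    right: "RuleNode | str"

    def apply(self, values: dict[str, float]) -> Tier3:
        child = self.left if values[self.feature] < self.threshold else self.right
        return child.apply(values) if isinstance(child, RuleNode) else Tier3[child]

    def to_dict(self) -> dict:
        def _conv(c):
            return c.to_dict() if isinstance(c, RuleNode) else c
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": _conv(self.left),
            "right": _conv(self.right),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuleNode":
        def _conv(c):
            return cls.from_dict(c) if isinstance(c, dict) else c
        return cls(d["feature"], float(d["threshold"]), _conv(d["left"]), _conv(d["right"]))


@dataclass(frozen=True)
class PlantedRule:
    """Planted decision boundary plus label-flip noise probability."""

    root: RuleNode
    label_noise: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.label_noise < 1.0:
            raise ValueError("label_noise must be in [0, 1)")
        self._check_thresholds(self.root)

    @staticmethod
    def _check_thresholds(node: RuleNode) -> None:
        lo, hi = FEATURE_RANGES[node.feature]
        if not lo < node.threshold < hi:
            raise ValueError(
                f"threshold {node.threshold} for {node.feature} outside sampling range ({lo}, {hi})"
            )
        for child in (node.left, node.right):
            if isinstance(child, RuleNode):
                PlantedRule._check_thresholds(child)

    def to_json(self, **kwargs) -> str:
        return json.dumps({"root": self.root.to_dict(), "label_noise": self.label_noise}, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "PlantedRule":
        d = json.loads(text)
        return cls(root=RuleNode.from_dict(d["root"]), label_noise=float(d.get("label_noise", 0.0)))


def default_planted_rule(label_noise: float = 0.0) -> PlantedRule:
    """Depth-2 rule emulating the canonical degradation zones.

    Polymers with Tg above ~ocean temperature degrade slowly; below it, low
    molecular weight means fast erosion, higher molecular weight medium.
    """
    return PlantedRule(
        root=RuleNode(
            feature="Tg", threshold=25.0,
            left=RuleNode(feature="Mn", threshold=25.0, left="fast", right="medium"),
            right="slow",
        ),
        label_noise=label_noise,
    )


@dataclass(frozen=True)
class SimulationConfig:
    n: int = 200
    seed: int = 2020
    feature_ranges: dict = field(default_factory=lambda: dict(FEATURE_RANGES))
    erosion_noise_sd: float = 0.0

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        for name, (lo, hi) in self.feature_ranges.items():
            if not lo < hi:
                raise ValueError(f"degenerate range for {name}: ({lo}, {hi})")


def simulate_polymers(
    config: SimulationConfig, rule: PlantedRule
) -> tuple[list[PolymerRecord], list[Tier3]]:
    """Sample polymer records and planted-rule labels, reproducibly from the seed."""
    rng = np.random.default_rng(config.seed)
    ranges = config.feature_ranges
    tg = rng.uniform(*ranges["Tg"], config.n)
    mn = np.exp(rng.uniform(np.log(ranges["Mn"][0]), np.log(ranges["Mn"][1]), config.n))
    lps = rng.uniform(*ranges["logp_per_sa"], config.n)
    dh = rng.uniform(*ranges["enthalpy"], config.n)
    cryst = rng.uniform(*ranges["crystallinity"], config.n)

    records, labels = [], []
    for i in range(config.n):
        values = {
            "Tg": tg[i], "Mn": mn[i], "logp_per_sa": lps[i],
            "enthalpy": dh[i], "crystallinity": cryst[i],
        }
        label = rule.root.apply(values)
        if rule.label_noise > 0 and rng.random() < rule.label_noise:
            label = Tier3(int(rng.choice([c for c in range(3) if c != int(label)])))
        records.append(
            PolymerRecord(
                id=f"syn-{i:05d}",
                name=f"synthetic polymer {i}",
                polymer_class="synthetic",
                source="laboratory",
                tg_C=float(tg[i]),
                mn_kg_mol=float(mn[i]),
                logp_per_sa_A2=float(lps[i]),
                enthalpy_melting_J_g=float(dh[i]),
                crystallinity_pct=float(cryst[i]),
                provenance="synthetic: sampled from declared feature ranges",
            )
        )
        labels.append(label)
    return records, labels


def feature_matrix(records, features) -> np.ndarray:
    """(n_records, n_features) array of the named features (NaN where missing)."""
    out = np.empty((len(records), len(features)))
    for j, name in enumerate(features):
        if name not in FEATURES:
            raise KeyError(f"unknown feature {name!r}")
        out[:, j] = [np.nan if (v := r.feature(name)) is None else v for r in records]
    return out


def simulate_erosion_series(
    k: float,
    b: float,
    e_waves: float,
    temperatures,
    noise_sd: float = 0.0,
    seed: int = 2020,
    polymer_id: str = "syn-erosion",
) -> list[DegradationObservation]:
    """Erosion observations rate = k·T + b + E_waves + N(0, σ), truncated at 0."""
    temps = np.asarray(list(temperatures), dtype=float)
    if temps.size == 0:
        raise ValueError("temperature list must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rates = k * temps + b + e_waves
    if noise_sd > 0:
        rates = rates + rng.normal(0.0, noise_sd, temps.size)
    rates = np.maximum(rates, 0.0)
    return [
        DegradationObservation(
            polymer_id=polymer_id,
            condition="ocean",
            t_water_C=float(t),
            days=365.0,
            erosion_rate_mg_cm2_day=float(r),
            reference="synthetic: linear-in-temperature forward model",
        )
        for t, r in zip(temps, rates)
    ]


# Curated fixture: numeric fields hold literature-reported values (see the
# provenance tag on each record); tier labels are curated approximations for
# exercising classifiers, with PBAdip (medium) and PET (slow) anchored.
_FIXTURE_ROWS = [
    # id, name, class, Tg, Tm, Mn, enthalpy, logp_per_sa, label, provenance
    ("pe", "polyethylene", "polyolefin", None, None, None, None, 0.0236, "slow",
     "lit: LogP/SA"),
    ("pp", "polypropylene", "polyolefin", None, None, None, None, None, "slow",
     "curated class entry"),
    ("pcl", "polycaprolactone", "polyester", -60.0, 60.0, None, None, 0.0096, "fast",
     "lit: Tm, LogP/SA; Tg curated"),
    ("pla", "poly(lactic acid)", "polyester", 65.0, None, None, None, None, "slow",
     "lit: Tg"),
    ("pet", "poly(ethylene terephthalate)", "polyester", 78.0, None, None, None, None, "slow",
     "lit: Tg; label anchored (three-level model)"),
    ("pbat", "poly(butylene adipate terephthalate)", "polyester", -36.0, None, None, None, None,
     "medium", "lit: Tg"),
    ("phb", "poly(hydroxybutyrate)", "polyester", 3.5, None, 450.0, None, None, "medium",
     "lit: Tg midpoint of 2-5 °C, Mn midpoint of 200-700 kg/mol"),
    ("pes", "poly(ethylene succinate)", "polyester", None, 104.0, None, None, None, "medium",
     "lit: Tm"),
    ("pbs", "poly(butylene succinate)", "polyester", None, None, None, 132.0, None, "slow",
     "lit: enthalpy of melting"),
    ("pbseb", "poly(butylene sebacate)", "polyester", None, None, None, 125.0, None, "slow",
     "lit: enthalpy of melting"),
    ("pbadip", "poly(butylene adipate)", "polyester", None, None, None, None, None, "medium",
     "label anchored (reference polymer, medium on both scales)"),
    ("nylon4", "Nylon 4", "polyamide", None, 267.0, None, None, None, "fast",
     "lit: Tm"),
    ("nylon6", "Nylon 6", "polyamide", None, 220.0, None, None, 0.0045, "medium",
     "lit: Tm, LogP/SA"),
    ("nylon66", "Nylon 6,6", "polyamide", None, 264.0, None, None, None, "medium",
     "lit: Tm"),
    ("nylon12", "Nylon 12", "polyamide", None, None, None, None, None, "slow",
     "curated class entry"),
    ("peg", "poly(ethylene glycol)", "polyether", None, None, None, None, None, "fast",
     "water-soluble group"),
    ("pva", "poly(vinyl alcohol)", "polyol", None, None, None, None, None, "fast",
     "water-soluble group"),
]


def fixture_database() -> tuple[list[PolymerRecord], dict[str, Tier3]]:
    """Small curated polymer table with literature-reported numeric values.

    Returns the records and a 3-tier label per polymer id.  Labels are
    curated approximations (marked in each record's provenance) intended for
    exercising the classification code paths, not for reproducing the full
    curated-database accuracies.
    """
    records, labels = [], {}
    for (pid, name, cls, tg, tm, mn, dh, lps, label, prov) in _FIXTURE_ROWS:
        records.append(
            PolymerRecord(
                id=pid, name=name, polymer_class=cls, source="commercial",
                tg_C=tg, tm_C=tm, mn_kg_mol=mn, enthalpy_melting_J_g=dh,
                logp_per_sa_A2=lps, provenance=prov,
            )
        )
        labels[pid] = Tier3[label]
    return records, labels
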