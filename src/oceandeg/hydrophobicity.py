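"""Size-normalized hydrophobicity index LogP/SA for polymer repeat units.

The descriptor ranks how oil-like a polymer surface is, per unit of molecular
surface area.  For a repeat unit with two attachment points the pipeline is

    repeat unit → head-to-tail n-mer (H-capped) → 3D embedding +
    force-field minimization → atom-contribution LogP and molecular
    surface area (1.40 Å probe) → LogP/SA ratio,

averaged over 10-, 12- and 14-mer chain models so that end-group effects
shrink relative to the repeating backbone.  Positive values indicate
water-insoluble, hydrophobic polymers (polyolefins sit above ~0.015 Å⁻²),
values near zero mark hydrolysable polyesters/polyamides, and negative
values mark water-soluble polymers such as PVA.

LogP uses the Wildman–Crippen (1999) atom-contribution table shipped with
RDKit, a published member of the Ghose–Crippen atom-typing family.  Relative
to ALogP98 parameterizations it assigns amide and ether environments a more
hydrophobic contribution, so indices for polyamides (and the sign of
near-zero polyethers) carry a systematic offset; see docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen

from .surface import BONDI_RADII, DEFAULT_PROBE_RADIUS, surface_area

DEFAULT_LENGTHS = (10, 12, 14)
DEFAULT_SEED = 2020
DEFAULT_N_CONFORMERS = 6


class RepeatUnitError(ValueError):
    """Invalid repeat-unit structure (unparseable or wrong attachment count)."""


class EmbeddingError(RuntimeError):
    """3D embedding failed after bounded retries."""


@dataclass(frozen=True)
class RepeatUnit:
    """A polymer repeat unit given as SMILES with exactly two ``*`` attachment points."""

    name: str
    structure: str
    polymer_class: str = "unknown"

    def to_mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.structure)
        if mol is None:
            raise RepeatUnitError(f"repeat unit {self.name!r}: unparseable SMILES {self.structure!r}")
        n_attach = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
        if n_attach != 2:
            raise RepeatUnitError(
                f"repeat unit {self.name!r}: expected exactly 2 attachment points, found {n_attach}"
            )
        return mol


@dataclass(frozen=True)
class ConvergenceSpec:
    """Force-field minimization tolerances.

    Defaults: 1.0e-4 kcal mol⁻¹ on energy and 0.005 kcal mol⁻¹ Å⁻¹ on
    force, standard tight geometry-optimization thresholds.  (The
    displacement threshold is recorded for provenance; the MMFF minimizer
    used here terminates on the energy/force pair.)
    """

    energy_tol: float = 1.0e-4
    force_tol: float = 0.005
    displacement_tol: float = 5.0e-5
    max_iterations: int = 5000


@dataclass
class OligomerModel:
    """A capped n-mer chain model, optionally with minimized 3D coordinates."""

    unit_name: str
    n_units: int
    mol: Chem.Mol
    total_energy: float | None = None
    energy_before_minimization: float | None = None
    seed: int | None = None

    @property
    def coordinates(self) -> np.ndarray:
        if self.mol.GetNumConformers() == 0:
            raise ValueError("oligomer has no 3D coordinates; run minimize_conformer first")
        return self.mol.GetConformer().GetPositions()


@dataclass(frozen=True)
class LengthResult:
    logp: float
    surface_area: float  # Å²
    ratio: float  # Å⁻²


@dataclass
class HydrophobicityResult:
    """Per-chain-length LogP, surface area and ratio, plus their mean."""

    unit_name: str
    per_length: dict[int, LengthResult]
    mean_logp_per_sa: float  # Å⁻²
    provenance: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        payload = {
            "unit_name": self.unit_name,
            "per_length": {
                str(n): {"logp": r.logp, "surface_area_A2": r.surface_area, "ratio_A-2": r.ratio}
                for n, r in sorted(self.per_length.items())
            },
            "mean_logp_per_sa_A-2": self.mean_logp_per_sa,
            "provenance": self.provenance,
        }
        return json.dumps(payload, **kwargs)


def build_oligomer(unit: RepeatUnit, n_units: int, cap: str = "H") -> OligomerModel:
    """Head-to-tail concatenation of ``n_units`` copies of the repeat unit.

    The first attachment point of the SMILES is the head, the second the
    tail; the tail of copy i bonds to the head of copy i+1 with a single
    bond, and both free chain ends are capped (default: hydrogen).
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if cap != "H":
        raise ValueError(f"unsupported cap rule {cap!r}; only hydrogen caps are implemented")
    base = unit.to_mol()
    chain: Chem.Mol | None = None
    for _ in range(n_units):
        copy = Chem.Mol(base)
        if chain is None:
            chain = copy
            continue
        combo = Chem.RWMol(Chem.CombineMols(chain, copy))
        offset = chain.GetNumAtoms()
        old_dummies = [a.GetIdx() for a in combo.GetAtoms()
                       if a.GetAtomicNum() == 0 and a.GetIdx() < offset]
        new_dummies = [a.GetIdx() for a in combo.GetAtoms()
                       if a.GetAtomicNum() == 0 and a.GetIdx() >= offset]
        tail, head = old_dummies[-1], new_dummies[0]
        tail_nbr = combo.GetAtomWithIdx(tail).GetNeighbors()[0].GetIdx()
        head_nbr = combo.GetAtomWithIdx(head).GetNeighbors()[0].GetIdx()
        combo.AddBond(tail_nbr, head_nbr, Chem.BondType.SINGLE)
        for idx in sorted((tail, head), reverse=True):
            combo.RemoveAtom(idx)
        chain = combo.GetMol()
    rw = Chem.RWMol(chain)
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    mol = Chem.RemoveHs(mol)
    return OligomerModel(unit_name=unit.name, n_units=n_units, mol=mol)


def minimize_conformer(
    model: OligomerModel,
    seed: int = DEFAULT_SEED,
    tolerances: ConvergenceSpec = ConvergenceSpec(),
    max_attempts: int = 5,
) -> OligomerModel:
    """Embed a 3D conformer (ETKDG, seeded) and minimize it with MMFF94.

    Deterministic for a given (topology, seed).  Embedding is retried with
    incremented seeds (falling back to random initial coordinates) before
    giving up.
    """
    molH = Chem.AddHs(model.mol)
    embedded = False
    for attempt in range(max_attempts):
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed + attempt)
        if attempt >= 2:
            params.useRandomCoords = True
        if AllChem.EmbedMolecule(molH, params) == 0:
            embedded = True
            break
    if not embedded:
        raise EmbeddingError(
            f"embedding failed for unit {model.unit_name!r} "
            f"(n_units={model.n_units}, seed={seed}) after {max_attempts} attempts"
        )
    props = AllChem.MMFFGetMoleculeProperties(molH)
    ff = AllChem.MMFFGetMoleculeForceField(molH, props)
    energy_before = float(ff.CalcEnergy())
    ff.Minimize(
        maxIts=tolerances.max_iterations,
        energyTol=tolerances.energy_tol,
        forceTol=tolerances.force_tol,
    )
    return OligomerModel(
        unit_name=model.unit_name,
        n_units=model.n_units,
        mol=molH,
        total_energy=float(ff.CalcEnergy()),
        energy_before_minimization=energy_before,
        seed=seed,
    )


def atom_contribution_logp(model: OligomerModel | Chem.Mol) -> float:
    """Wildman–Crippen atom-contribution LogP (conformation-independent)."""
    mol = model.mol if isinstance(model, OligomerModel) else model
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            raise ValueError(
                f"atom {atom.GetIdx()} is an attachment point; cap the chain before computing LogP"
            )
    return float(Crippen.MolLogP(mol))


def molecular_surface_area(
    model: OligomerModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    convention: str = "solvent_excluded",
    **sampling,
) -> float:
    """Molecular surface area (Å²) of a minimized oligomer model."""
    coords = model.coordinates
    radii = []
    for atom in model.mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z not in BONDI_RADII:
            raise ValueError(
                f"no van der Waals radius for atom {atom.GetIdx()} (Z={z}) in the frozen radii table"
            )
        radii.append(BONDI_RADII[z])
    return surface_area(coords, np.asarray(radii), probe_radius, convention, **sampling)


def hydrophobicity_index(
    unit: RepeatUnit,
    lengths: tuple[int, ...] = DEFAULT_LENGTHS,
    seed: int = DEFAULT_SEED,
    n_conformers: int = DEFAULT_N_CONFORMERS,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    convention: str = "solvent_excluded",
    tolerances: ConvergenceSpec = ConvergenceSpec(),
) -> HydrophobicityResult:
    """LogP/SA index averaged over chain models of the given lengths.

    For each length the surface area is the mean over ``n_conformers``
    independently embedded and minimized conformers (distinct derived
    seeds), damping the conformational noise of flexible chains; LogP is
    conformation-independent and computed once per length.
    """
    if not lengths:
        raise ValueError("lengths must be non-empty")
    per_length: dict[int, LengthResult] = {}
    for n in sorted(lengths):
        topology = build_oligomer(unit, n)
        logp = None
        areas = []
        for c in range(n_conformers):
            minimized = minimize_conformer(topology, seed=seed + 7919 * c, tolerances=tolerances)
            if logp is None:
                logp = atom_contribution_logp(minimized)
            areas.append(
                molecular_surface_area(minimized, probe_radius=probe_radius, convention=convention)
            )
        sa = float(np.mean(areas))
        per_length[n] = LengthResult(logp=logp, surface_area=sa, ratio=logp / sa)
    mean_ratio = float(np.mean([r.ratio for r in per_length.values()]))
    return HydrophobicityResult(
        unit_name=unit.name,
        per_length=per_length,
        mean_logp_per_sa=mean_ratio,
        provenance={
            "logp_table": "Wildman-Crippen 1999 (RDKit Crippen)",
            "radii": "Bondi 1964",
            "surface_convention": convention,
            "probe_radius_A": probe_radius,
            "lengths": list(sorted(lengths)),
            "n_conformers": n_conformers,
            "seed": seed,
            "force_field": "MMFF94",
            "energy_tol_kcal_mol": tolerances.energy_tol,
            "force_tol_kcal_mol_A": tolerances.force_tol,
        },
    )
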