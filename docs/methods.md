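# Methods

`oceandeg` implements a structure–property pipeline for ranking how plastics
degrade in seawater: a molecular hydrophobicity descriptor computed from
polymer repeat units, conversion of heterogeneous degradation measurements
onto ordinal category scales, shallow interpretable classification trees over
bulk physical properties, and two closed-form surface-erosion equations.
This note records the models, the numerical choices, and what the synthetic
data can and cannot establish.

## The hydrophobicity descriptor LogP(SA)⁻¹

**Model.** A polymer's affinity for water is summarized by the computed
octanol–water partition coefficient of a finite chain model divided by the
chain's molecular surface area (units Å⁻²). Dividing by surface area makes
chains of different length comparable and emphasizes the interfacial
character of degradation: hydrolysis and microbial attack act at the polymer
surface. Positive values mean water-insoluble; polyolefins sit near
0.02 Å⁻² and above, hydrolysable polyesters/polyamides between 0 and
~0.013 Å⁻², and water-soluble polymers below 0.

**Protocol.** Given a repeat unit (SMILES with exactly two attachment
points), the pipeline builds head-to-tail 10-, 12- and 14-mers, caps both
ends with hydrogen, embeds each with the distance-geometry ETKDGv3 method
(seeded), and minimizes with MMFF94 to an energy tolerance of
1.0e-4 kcal mol⁻¹ and a force tolerance of 0.005 kcal mol⁻¹ Å⁻¹. LogP is
the sum of Wildman–Crippen atom contributions (conformation-independent);
the surface area is the solvent-excluded (Connolly-type) area with a 1.40 Å
water probe. The index is the mean of the three per-length LogP/SA ratios.

Because single embeddings of flexible chains scatter the surface area by
up to ~10%, each length averages the surface area over 6 independently
seeded conformers; with that choice the per-length ratios of all tested
homopolymers agree within 10% of their mean. The whole computation is a
pure function of (repeat unit, lengths, seed) and is bit-reproducible.

**LogP parameterization.** The atom-contribution table is Wildman &
Crippen (1999) as shipped with RDKit — a published member of the
Ghose–Crippen atom-typing family. Members of this family disagree most for
heteroatom environments: relative to ALogP98-style tables, Wildman–Crippen
assigns amide and ether fragments a more hydrophobic contribution. In
practice the index of polyethylene and polycaprolactone lands within the
package's documented ±25% implementation tolerance of widely quoted
values, while polyamide indices come out systematically high (Nylon 6
≈ 0.0074 vs the commonly quoted 0.0045 Å⁻²) and poly(ethylene glycol)
sits marginally above zero instead of below. The table choice is exposed in
the result provenance; the relative ordering PE > PCL > Nylon 6 > PEG/PVA
is robust to it.

**Surface numerics.** The solvent-excluded surface is computed as the
boundary of the probe-expanded union of Bondi-radius atom spheres eroded by
the probe ball. Implementation: binary voxelization (default 0.35 Å
spacing), Euclidean distance transforms to locate the erosion level set,
refinement of the distance field in a narrow band using exact distances to
a Shrake–Rupley dot sample of the union boundary (default 400 dots/atom),
and marching-cubes triangulation. On analytic spheres the error is <1%,
and default-vs-10×-cost sampling agrees to well under 1% on many-atom
geometries. The solvent-accessible convention (classic Shrake–Rupley,
960 dots/atom) is available via a switch; it is the convention under which
a single united atom has exactly the analytic area 4π(r+1.4)². The
solvent-excluded convention is the default because it is the convention the
descriptor's reference values assume.

Degenerate geometries (coincident atoms) are rejected; embedding failures
are retried with incremented seeds (random-coordinate fallback) before
raising an error that names the unit and seed.

## Degradation measurements and category scales

Surface erosion is mass loss divided by bulk surface area and exposure time
(mg cm⁻² day⁻¹). Biodegradation screens instead report BOD (% of
theoretical oxygen demand per day). Both map onto ordinal scales with fixed
cutpoints (see module docstring for the full grid); intervals are
lower-inclusive/upper-exclusive so that the mapping is total and
deterministic — published range endpoints overlap ("2–4", "4–6"), and a
boundary value is assigned to the upper tier. When both measures are
present, the mass-based erosion rate takes precedence (configurable).
The 5→3 tier collapse is very_slow/slow→slow, medium/fast→medium,
very_fast→fast, which keeps the two scales consistent on shared ranges.

Laboratory rates measured at above-ocean temperatures can be normalized to
a reference temperature by an ordinary least-squares line in temperature —
a declared stand-in for the unspecified adjustment used in the original
compilations. The adjustment is opt-in, requires at least two distinct
temperatures, and is always flagged in the returned provenance.

## Classification trees

Trees classify polymers into {slow, medium, fast} from bulk features (Mn,
enthalpy of melting, LogP(SA)⁻¹, Tg). Depth is capped at 2–3 by design —
the cap is the only regularization, and keeps each split physically
readable (the learned Tg split on planted data sits near ocean
temperature). Split search is exact: candidate thresholds are midpoints of
consecutive sorted unique feature values; the split maximizing Gini
impurity decrease wins; ties break to the lowest feature index in the
declared order (Mn, enthalpy, LogP(SA)⁻¹, Tg), then the lowest threshold.
Routing is left on value < threshold, right on ≥; leaf ties break toward
the slower class (a conservative default: under-predicting degradation is
the safer error). Trees are scale-invariant, so no standardization is
applied to them.

A note on optimality: greedy Gini trees do not in general coincide with the
depth-2 tree that globally maximizes training accuracy (random-label
experiments show disagreement on ~45% of small datasets). The test suite
therefore verifies the split search against an independent from-scratch
enumeration of the same greedy procedure, and verifies on separable planted
data that the greedy tree attains the global optimum (100%).

Cross-validation uses stratified 10-fold splitting (scikit-learn), seeded,
reporting the mean over folds of holdout accuracy. On noiseless planted
data a holdout point adjacent to the planted boundary can still be
misassigned when the threshold is refit without it, so "separable" implies
mean accuracy near, not exactly, 100%.

The 2-D decision-region shading uses an RBF-kernel SVM (γ = 0.2, C = 10.0)
on z-scored features. It is a visual layer only; no reported accuracy
depends on it.

## Erosion equations

The temperature sensitivity of surface erosion is modelled as

    k = exp((T_water − Tg) / (LogP/SA) − c1) / c2,

with c1 = 28795 and c2 = 4177.3 as defaults, applicable to polyesters and
polyamides with LogP/SA > 0 and enthalpy of melting below 85 J g⁻¹ (the
stricter of the two published bounds; configurable). Outside those bounds
the model overestimates k, so every prediction surface routes through the
applicability check first and returns a verdict with named reasons rather
than a silent number. As printed, the formula is dimensionally awkward:
with descriptor magnitudes of order 0.01 Å⁻² the exponent argument is far
below c1 and k underflows to zero. The constants are therefore exposed as
configuration (permitting re-fitting) and the implementation follows the
published form without guessing a correction; the analytic identities
k = 1/c2 at exponent argument c1, and k = 1 at c1 + ln c2, hold to machine
precision.

Total erosion adds environment: E_total = k·T_water + b + E_waves, with b
the intercept absent mechanical forces and E_waves the measured difference
between exposed and sheltered sites (order 0.005–0.017 mg cm⁻² day⁻¹ for
estuary/coastal settings). E_waves is user-supplied; the package does not
estimate wave energy. `fit_erosion_line` recovers (k, b + E_waves) from
rate-vs-temperature series by OLS with standard errors.

## Synthetic data and the fixture table

`simulate_polymers` draws features independently and uniformly over
realistic ranges (Tg −70…150 °C; Mn log-uniform 1…1000 kg mol⁻¹; LogP/SA
−0.01…0.03 Å⁻²; enthalpy 0…140 J g⁻¹; crystallinity 0…80%), labels each
record by a planted axis-aligned rule (default: Tg split at 25 °C, then an
Mn split at 25 kg mol⁻¹), and flips labels to a uniformly random other
class with the configured probability. `simulate_erosion_series` is the
forward model of the total-erosion equation with additive Gaussian noise
truncated at zero. Both are pure functions of (config, seed).

What this emulates: axis-aligned class structure with label noise and
linear-in-temperature erosion — exactly the statistical assumptions the
tree and line-fitting stages make. What it does not: inter-feature
correlations of real polymers (features are sampled independently), class
imbalance of the literature corpus, measurement error on the features
themselves, and any chemistry linking features to labels. Passing the
recovery tests therefore demonstrates correctness of the estimators under
their own assumptions, not predictive validity on real polymer data.

The packaged fixture (`fixture_database`, 17 polymers) carries
literature-reported values where available (e.g. PE LogP/SA 0.0236 Å⁻²,
Nylon 6 Tm 220 °C, PBS enthalpy 132 J g⁻¹) with a per-record provenance
tag; its 3-tier labels are curated approximations for exercising the
classification code paths (only the reference polymer PBAdip = medium and
PET = slow are anchored assignments). The published training/CV accuracies
of the full ~110-polymer curated database (72.2%/87.1% training,
57.8%/63.2% CV) require that database's source file and are out of the
package's reproduction surface; the fixture and synthetic suites exercise
the same code paths instead.

## Problem sizes and runtime

Default problem sizes were chosen so a full run is comfortable on one CPU:
descriptor acceptance uses 3 chain lengths × 6 conformers per polymer
(≈1–2 min for the largest polyamide chains), tree oracle suites use ≤20
records × 60 random datasets, planted-recovery and CV use n = 200, and
noise-calibration checks use n = 10⁴ samples.

## Known limitations

- Wildman–Crippen vs ALogP98 systematics for amide/ether-rich polymers
  (documented above); absolute indices for polyamides are high.
- Single-molecule vacuum conformers stand in for bulk amorphous surfaces;
  the descriptor is a ranking tool, not a physical surface energy.
- The solvent-excluded area is mesh-based; expect ~1% resolution error at
  defaults.
- The temperature-slope constants are used as published; their dimensional
  convention for LogP/SA is unresolved, and realistic inputs underflow.
- Tier labels in the fixture are curated, not measured.
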