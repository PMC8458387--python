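# Methods

## Two-state denaturation models

Both unfolding models assume a folded↔unfolded equilibrium whose observed
signal is a population-weighted mixture of two states, each with a signal
that drifts linearly in the perturbation variable (the standard
linear-baseline treatment of CD and fluorescence data):

* chemical: exponent −m(Cm − D)/RT, with D the denaturant concentration
  (M), Cm the midpoint and m (kJ·mol⁻¹·M⁻¹) the slope of the unfolding
  free energy with denaturant (m > 0 under this sign convention);
* thermal: exponent ΔHm(1 − T/Tm)/RT, with temperatures in kelvin
  internally (°C + 273.15 at the interface) and ΔHm the van't Hoff
  enthalpy, negative for unfolding here so the denatured population grows
  with temperature.

An algebraic consequence used as a test invariant: at the midpoint the
model value equals the mean of the two baseline values, for any baseline
slopes.

Constants: R = 8.314×10⁻³ kJ·mol⁻¹·K⁻¹; chemical fits default to
293.15 K, the storage/measurement temperature of the titrations this
design emulates. m-values are kept in kJ·mol⁻¹·M⁻¹ throughout so that
½(m + m′)ΔCm is directly in kJ/mol.

### Fitting

`scipy.optimize.curve_fit` with the trust-region reflective method,
xtol = ftol = gtol = 1e-12, ≤10⁴ evaluations; fits are deterministic given
the data. Starting values are derived automatically, never hand-seeded:
baseline intercepts/slopes from ordinary least squares on the outer 20% of
points at each end; the midpoint from the half-range crossing of the
monotonised per-point fraction; the steepness (m or ΔHm) from the slope of
logit(fraction) over the central part of the transition (m ≈ s·RT,
ΔHm ≈ −s·R·Tm²). Standard errors come from the fit covariance. Degenerate
inputs are rejected explicitly: fewer than 8 distinct x values, a fitted
midpoint outside the sampled range, a non-finite covariance, or baselines
that remain within 5% of the signal span of each other at the midpoint
(no observable transition — the midpoint would be meaningless).

Replicates are pooled as individual points in the fit; alternatively
`normalize_fraction_denatured` blank-subtracts, averages replicates
point-wise and rescales affinely so min = 0 and max = 1 (with an
orientation flag choosing which end is "denatured"), mirroring how plate
fluorescence data are usually reduced before fitting. Both raw-signal and
fraction ordinates are supported in the fitters.

### ΔΔG conventions

The thermal comparison ΔΔG = ΔHm·ΔTm/Tm leaves open whose ΔHm and Tm
enter. This package uses the *reference* protein's ΔHm and Tm (in kelvin):
with the tabulated WRAP-T permutant parameters this convention reproduces
all three published values (−1.5, −2.1, +8.7 kJ/mol) at printed precision;
attributing ΔHm or Tm to the mutant does not. Likewise ΔCm is taken as
Cm,ref − Cm,mut, the orientation that reproduces the published chemical
values (−1.5 for nv, +16 for v22). Both choices make positive ΔΔG mean
"mutant destabilised" (the glossary convention used throughout).

The published stability table prints the ΔG₀^H₂O row identical to the Cm
row; we treat that as a typesetting error and compute ΔG₀ = m·Cm (22.1,
32.76 and 18.45 kJ/mol for nv, v22 and v13), with first-order error
propagation when parameter standard errors are supplied.

## Blade geometry

Each blade is represented by four marker Cα: p1, p2 on the innermost
strand (β1) and q1, q2 on β3. Marker selection is configuration-driven
(1-based offsets within each blade range): published analyses identify
these columns only graphically, so no residue numbers are hard-coded.

The symmetry axis is not an input. For every cyclic blade pair (i, i+1)
the blades (trimmed to their common length from the range start) are
superposed by Kabsch's method — SVD of the cross-covariance with the
reflection-correcting sign flip, so the rotation is always proper — and
the rotation axis and angle are read off the matrix
(angle = arccos((trace−1)/2); axis from the skew part, right-handed for
the positive angle, which fixes the axis sign so the per-blade rotation is
positive going N→C around the ring). Axes are sign-aligned, averaged and
renormalised; a spread above 15° between per-pair axes raises an
asymmetry error. The axis point solves the stacked fixed-point equations
(I − Rₖ)p = tₖ in the least-squares sense (the minimum-norm solution pins
the otherwise free coordinate along the axis).

Derived parameters: a, b are point-to-line distances of p1, p2 from the
axis; c, d, e, f are Euclidean distances between corresponding markers of
cyclically subsequent blades, all n pairs including last→first, because
the structures are closed rings; α is the mean per-pair rotation angle;
δ is the angle between p2−p1 and the axis mapped into [0°, 90°]; β is the
signed dihedral (P+ẑ, P, p1, p2) with P the axis projection of p1 — the
twist of β1 out of the axial plane through p1; γ is the signed dihedral
(p1, p2, q2, q1) — the internal twist between β1 and β3. Dihedrals use
the IUPAC sign convention (right-handed about the middle segment).
Absolute signs of β and γ depend on that convention; magnitudes and
trends, validated on synthetic ground truth, are the tested contract.
Means and sample standard deviations are reported over blades.

For a perfect n-fold ring every marker family lies on a circle, so the
inter-blade distances are chords of a regular n-gon: c = 2a·sin(180°/n).
The half-angle form is deliberate: the full-angle variant sometimes quoted
for the isosceles-triangle picture is inconsistent with the published
distance tables (2×4.6×sin 60° = 8.0 Å against an observed chord of
4.5 Å for the six-bladed case, whereas the half-angle form gives 4.6 Å).

Regressions of a parameter against blade number are ordinary least
squares (`scipy.stats.linregress`), with label-based exclusions; r² is the
squared Pearson correlation. On the published per-structure means, the
inner radius a regressed on n over the 6–9-bladed designs gives
r² = 0.969 and the β twist excluding Tako8 gives r² = 0.962 — both
reproduce the published "r² > 0.95" claims. (Regressing the mean of a and
b also exceeds 0.95, so the choice of "channel radius" does not affect
the conclusion. The tilt δ regressed on n gives r² ≈ 0.23 from the
printed means — essentially uncorrelated; the published figure, < 0.2,
was presumably computed from per-blade rather than mean values, so this
quantity is reported but not asserted.)

## Synthetic data generators

All generators are pure functions of a parameter record containing an
explicit seed (numpy `default_rng`; no global state). Noise is applied to
signals or coordinates, never to the sampling grid.

* Thermal melts: 20–85 °C in 0.2 °C steps, model value plus N(0, σ²);
  defaults are the reference permutant's published parameters
  (Tm = 77.68 °C, ΔHm = −790 kJ/mol) with flat 0/1 baselines and
  σ = 0.01.
* Chemical titrations: 0–6 M in 0.25 M steps, triplicate, 293.15 K,
  σ = 0.02 fraction units; defaults Cm = 2.05 M, m = 9 kJ·mol⁻¹·M⁻¹.
  Published fitted values for the other permutants are carried as
  documented reference constants, not as fit-reproduction targets: the
  raw curves behind them are not deposited, so simulated curves are the
  test substrate.
* Ideal propellers: blade 0's four markers are placed from radii,
  heights and azimuth offsets (defaults approximating the seven-bladed
  WRAP-T: a = 5.82 Å, b = 8.51 Å, outer radii chosen so the outer chords
  match its e/f values), optionally densified into straight strand
  traces, then copied by rotations of 360°/n about z; an optional rigid
  pose and isotropic coordinate noise follow. The twist/tilt angles are
  *derived* truth, not inputs: the four marker positions over-determine
  {a, b, δ, β, γ}, so the generator reports their exact values
  (closed-form for distances and α, the shared dihedral construction on
  the ideal pre-pose coordinates for β/γ) in the ground-truth record.
  Axis detection, the distance recovery, and the chord identities are
  therefore genuinely independent checks, while β/γ recovery checks axis
  detection and pose-equivariance of the dihedral construction.
* Repeat families: i.i.d. per-site substitution of a consensus repeat to
  a uniformly random different residue. At rate 0.03 over 14 copies of a
  47-mer the expected identity to the consensus is ~97%, the divergence
  regime of the natural template family this emulates.

What the generators do *not* emulate: instrument drift and photobleaching,
non-two-state (intermediate or kinetically limited) unfolding,
replicate-level systematic offsets, realistic side-chain or full-backbone
geometry, and phylogenetic correlation between repeats. Passing tests
therefore demonstrate correctness of the estimators under the stated
models and designs, not robustness to those real-data pathologies.

## Problem sizes and determinism

The distributional recovery tests use 100 seeded simulations per assay at
the design grids above — enough for stable medians (median |Ĉm − Cm| ≈
0.012 M and |T̂m − Tm| ≈ 0.07 °C at σ = 0.02) while keeping the whole
suite fast. Synthetic propellers in tests use 2–6 points per strand;
results are exact at machine precision for noiseless input regardless of
density. Fits and geometry are deterministic given data; everything
stochastic takes an explicit seed.

## Design choices on open points

* Consensus ties default to background-table arbitration (mimicking how
  a profile from a larger sequence family resolves a two-way tie, as was
  done for the Arg/Trp column of the WRAP repeat, settled by a WD40
  family logo in favour of Thr); strict mode raises instead. Overrides
  always win and are recorded.
* Gaps are excluded from column denominators; all-gap columns are errors
  (the repeat families targeted here align ungapped).
* The permutation cut point is the last loop residue before the target
  strand, so the deleted residue is always a loop residue; the
  prefer-glycine policy formalises "delete a glycine if the loop has
  one", and the explicit-position escape hatch covers loops that lack
  one (the v22 case, where a central aspartate is removed instead).
* Percent identity is reported to the nearest integer by default.
* Structure reading: first model only, polymer Cα only, altloc resolved
  by occupancy then label; PDB/mmCIF via gemmi, format sniffed.
* Residue ranges are 1-based inclusive everywhere (PDB convention).
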