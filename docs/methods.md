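# Methods

## The clinical dose model

The package implements the modified microdosimetric kinetic model (MKM) as
used clinically for scanned carbon-ion beams.  Cell survival follows a
linear-quadratic (LQ) law whose linear coefficient depends on beam quality
through the saturation-corrected dose-mean specific energy deposited in
subcellular domains, z\*₁D:

    α(z*) = α₀ + β·z*₁D,mix ,    β constant.

The clinical (RBE-weighted) dose expresses the absorbed dose as the dose of
a **carbon reference radiation** (linear coefficient α_r) producing the same
survival, scaled by a facility-calibrated clinical dose scaling factor
F_clin:

    D_RBE = F_clin · ( −α_r/2β + sqrt( (α_r/2β)² + (α₀D + β z* D + β D²)/β ) ).

Solving this for z\* given (D_RBE, D_abs) is algebraic and exact
(`invert_zstar`); no iteration is involved, and round-trip identity holds to
1e-10 relative over the clinically relevant domain (D ∈ (0, 20] Gy, z\* ∈
[0, 50] Gy), which the test suite asserts.

In a mixed radiation field, z\*₁D,mix is the dose-and-weight-weighted mean
of per-component values over energy layers *i* and fragment species:

    z*₁D,mix(x) = Σᵢ dᵢ(x)·z*₁Dᵢ(x)·wᵢ / Σᵢ dᵢ(x)·wᵢ .

Depths with zero total dose have no defined beam quality; the package
represents them with an explicit `nan` sentinel that propagates through
reports and is never silently replaced by zero.

### Parameters

| parameter | value | unit | meaning |
|---|---|---|---|
| α₀ | 0.172 | Gy⁻¹ | linear coefficient in the limit LET → 0 (HSG cells) |
| β | 0.0615 | Gy⁻² | quadratic coefficient, radiation-type independent |
| α_r | 0.764 | Gy⁻¹ | carbon reference-radiation linear coefficient |
| F_clin | 2.40 / 2.41 | – | clinical dose scaling factor (two shipped presets) |
| r_d | 0.32 | µm | domain radius (metadata only) |
| R_n | 3.9 | µm | nucleus radius (metadata only) |

Two unit/precision inconsistencies in published parameter tables are worth
recording.  First, α₀ is sometimes printed in Gy⁻² and β in Gy⁻¹;
dimensional analysis of the dose equation forces α₀, α_r in Gy⁻¹ and β in
Gy⁻², which is the convention used here.  Second, the reference beam-centre
z\*₁D,mix is sometimes quoted as 0.963 Gy, which is inconsistent with
α_r = α₀ + β·z\* = 0.764 Gy⁻¹; consistency requires z\* = (0.764−0.172)/0.0615
= 9.62602 Gy.  The package treats the printed value as a decimal-point slip:
it stores the derived 9.62602 Gy (validated to 1e-9 relative on
construction) and rejects parameter sets carrying the slipped value rather
than silently correcting them.  The track-model radii are carried as
metadata only; re-fitting them to cell-survival data is out of scope.

## The synthetic beam model

Clinical MKM engines consume two precalculated tables — z\*₁D versus
kinetic energy for ion species Z = 1–6 (from an amorphous track-structure
calculation) and depth-dependent fragment dose spectra of the carbon beam
(from Monte Carlo transport).  Neither is publicly distributable, so the
package ships a deterministic parametric surrogate with the same structure
and interface; externally supplied tables in the documented CSV/JSON
schemas are first-class replacements.

The surrogate stacks four power-law/saturation ingredients, all exposed as
`BeamKnobs` with units and defaults:

* **Range–energy**: R = a·E^1.8 with a set so a 430 MeV/u carbon beam has a
  31 cm water-equivalent range.  Representative energy per species per
  depth is the deterministic inverse of this law applied to residual range;
  fragment ranges scale as (A/Z²) relative to carbon (H and He travel ~3×
  further at equal velocity), which is what populates the fragment tail
  beyond the Bragg peak.  No spectral sampling is involved, keeping every
  per-component z\* well defined without Monte Carlo.
* **LET surrogate**: L(Z, E) = 37·Z²·E^−0.8 keV/µm (≈11 keV/µm for carbon at
  400 MeV/u), used both for the z\* response and for dose-averaged LET
  reporting (the 80 keV/µm neutron-equivalent depth utility).
* **z\*(L) response**: z\* = z_sat·u^q/(1+u^q), u = L/L_half, with
  z_sat = 35 Gy, L_half = 68 keV/µm, q = 3.  The response is monotone and
  saturating: the ceiling plays the role of the overkill saturation
  correction.  A genuinely non-monotone (post-peak declining) response was
  considered and rejected because it can order z\* of different species
  inconsistently at equal velocity; with a monotone response, higher-Z ions
  at fixed energy always carry higher z\*, an invariant the tests assert.
* **Depth dose**: the primary-carbon curve is a stopping-power rise
  (R−x)^−0.445 times a nuclear-survival attenuation exp(−x/130 cm),
  Gaussian-smeared with a straggling width σ = 0.006·R + 0.12 cm and
  hard-zeroed beyond R + 5σ.  Smearing the one-sided rise pulls the maximum
  proximally, so the curve is built twice, the second time with the range
  advanced by the measured offset — the Bragg peak then sits on the nominal
  range to within one grid step.  Fragment dose is a monotone build-up
  share of the field (the primary dose *fraction* is exactly
  exp(−x/130 cm), hence monotone non-increasing, another asserted
  invariant) distributed over Z = 1–5 with fixed shares and per-species
  exponential distal tails.

The default layer library covers ranges 1.0–27.7 cm at 0.1 cm pitch on a
0.05 cm depth grid (configurable).  The generator is fully deterministic;
randomness exists only behind an optional multiplicative noise knob
(default 0), and the seed is recorded in the provenance either way.

**Calibration of the defaults.**  The free knobs were fixed once so the
synthetic conditions reproduce the study geometry's reference scales: the
representative plan (R21.1M6D5.8) yields a target-centre z\*₁D,mix of
10.97 Gy, inside the [8, 12] Gy bracket around the 9.63 Gy reference value;
a fresh 400 MeV/u carbon beam has z\* ≈ 0.15 Gy (below 1 Gy, as expected
for the thinnest clinical beam quality); the fragment tail just beyond the
range carries ~11% of the peak dose; and the RBE-weighted distal edge falls
below half the prescription within 0.5 cm of the range for every
evaluation plan.

**What the surrogate does not emulate** — and hence what passing tests do
not demonstrate about real data: no lateral dose or multiple-Coulomb halo,
no nuclear cross-section physics (fragment shares are fixed, not
energy-dependent), no energy-spectrum mixing within a component, no
beamline-specific ripple or range shifter effects.  Quantities tied to
absolute beam quality (target-mean absorbed doses, calibrated F_clin
values) therefore differ from any facility's numbers by construction; the
procedures, identities and convergence properties are what the package
validates.

## SOBP planning and inverse optimization

A plan `R{range}M{modulation}D{prescription}` places a cube target's
central-axis chord at [range − modulation, range] (a sphere is reduced to
its chord-length-weighted depth span).  Layer selection anchors a 0.3 cm
comb at the library layer nearest the plan range and steps proximally,
adding one proximal guard layer.  No layer is placed beyond the range: the
deepest layer's peak defines the distal edge, as in clinical scanned-ion
practice — a distal guard layer turns out to be counterproductive (the
optimizer loads it to shape the edge and thereby broadens the distal
falloff).  Anchoring the comb at the range is what makes a flat
RBE-weighted plateau reachable at the distal edge; the fine 0.1 cm library
pitch exists so a layer is always available there for plan ranges quoted to
millimetre precision.

The optimizer targets **RBE-weighted** flatness (never absorbed-dose
flatness) and is deterministic:

1. *Damped multiplicative fixed point*: each layer's weight is scaled by
   (prescription / D_RBE at the layer's peak depth)^0.7 until the update
   factors are within 0.1% of unity.
2. *Non-negative least-squares polish on the linearized dose operator*:
   Gauss–Newton steps on the full Jacobian of D_RBE with respect to the
   weights (both the direct dose term and the z\*-mixing term), solved as
   bounded least squares with w + Δw ≥ 0 and a halving line search.  When
   a step stalls, one frozen-z\* NNLS step (fitting the absorbed-dose
   profile implied by the current beam quality) is tried before declaring
   convergence failure.

Convergence is declared at RMS deviation ≤ 0.5% of prescription over the
target span (optionally chord-weighted); non-convergence raises an error
carrying the last residual.  On the default model all seven evaluation
plans converge to ≤ 0.35% RMS and ≤ 0.9% maximum deviation.

Target-mean RBE is defined as the ratio of target means,
(mean D_RBE)/(mean D_abs), not the mean of pointwise ratios — this is the
definition under which published comparison tables are self-consistent.

## Benchmarking and evaluation

**F_clin calibration** iterates: optimize the representative plan under the
current F_clin → compute target-mean RBE → rescale
F_clin ← F_clin·(RBE_ref/RBE_now) → re-optimize, until the relative
deviation is ≤ 1e-4.  Because F_clin is a pure prefactor of the dose
equation, one update is exact at fixed beam quality; re-optimization
perturbs the fixed point only through the changed absorbed-dose/z\*
coupling, and the loop converges in ≤ 3 outer iterations on the default
model.  Parameter-recovery tests regenerate references at known true
factors in [2.25, 2.55] and recover them within 0.01%.

**Suite evaluation** optimizes each of the seven plans (three ranges ×
fixed width, three widths × fixed range, three prescriptions) and reports
per-plan target means against reference records, with the RBE deviation

    diff% = (D_abs_ref / D_abs_test − 1) · 100

positive when the reference RBE exceeds the test RBE, and a median
(min–max) summary.  Depth-resolved comparisons are masked where the
RBE-weighted dose is below 10% of the prescription (boundary closed:
exactly 10% is included) and flagged where they reach the ±3% band.
Profile pairs must share one depth grid — no implicit resampling.

The printed reference table ships with the package.  Recomputing each row's
deviation from its printed 2-d.p. doses reproduces the printed value for
four of seven rows; three rows (the shallow-range plan, the widest-
modulation plan, and the low-prescription plan) differ by ≤ 0.05 percentage
points, evidence that the published deviations were computed from unrounded
doses.  The report stores both values and flags the discrepancy rather than
choosing; report precision is 2 d.p. for doses and percents and 1 d.p. for
the summary median, with raw values always retained.

## Mixed-field LQ conversion

The conversion engine re-expresses a frozen optimized fluence under any
per-species tabulated LQ model.  Mixing is dose-averaged in α and
sqrt-dose-averaged in β (Zaider–Rossi-style):

    α_mix = Σ dᵢαᵢ / Σ dᵢ ,   sqrt(β_mix) = Σ dᵢ√βᵢ / Σ dᵢ ,

an explicit modelling choice, stated here because mixed-field practice
varies.  The converted dose solves the photon LQ equivalence
αₓDₓ + βₓDₓ² = α_mix·D + β_mix·D² in closed form.  The photon pair
(αₓ, βₓ) encodes a tissue choice and has **no default anywhere in the
package** — it is a required input.

Two tables ship: the MKM's own effective LQ table (per-species
α(E) = α₀ + β·z\*(E), constant β, photon pair (α_r/F_clin, β/F_clin²)),
for which conversion must return the original prescription — an exact
identity used for verification (holds pointwise to 1e-9 on shared energy
grids because linear interpolation commutes with the affine α(z\*) map) —
and a synthetic "LEM-like" demonstration table (α rising with LET,
α/β rising) that is explicitly *not* a local-effect-model implementation.

The study driver sweeps isocentre depths 7 and 11 cm × cube/sphere ×
sizes 4–12 cm × single/opposed/orthogonal beams (60 geometries), optimizes
each to 4.0 Gy(RBE), and reports converted target means with (min–max)
spans.  Multi-beam composition is 1-D: opposed beams mirror the field on a
phantom of length twice the isocentre depth (both beams then see identical
geometry and share layer weights by symmetry); the orthogonal configuration
adds the perpendicular beam's depth dose at its crossing depth as a
laterally uniform contribution.  Component bookkeeping (per-layer,
per-species dose, z\*, energy) is preserved through composition so the
mixed-field averages stay exact.

## Numerical choices and degenerate inputs

* Depth grids are uniform, default 0.05 cm spacing, beam entry at 0 cm;
  grid uniformity and monotonicity are validated on construction.
* Undefined values (zero-dose depths) are `nan`, never 0; masks make the
  undefined region explicit in every report.
* The masking boundary (10% of prescription) and the target-span endpoints
  are closed intervals; ties at the boundary are included.
* Zero-modulation plans degenerate to a single target grid point and a
  two-layer comb; the optimizer handles them exactly.
* A (D_RBE, D_abs) pair implying z\* < 0 is physically inconsistent; the
  negative value is returned with a warning rather than clipped, so
  downstream reports can flag it.
* Reports round doses and percents to 2 d.p. (summary median 1 d.p.) while
  retaining raw values; serialized floats round-trip exactly
  (`float_precision="round_trip"` on read).
* End-to-end runs are deterministic: no timestamps in outputs, provenance
  and config hashes embedded, same configuration → byte-identical files.

## Problem sizes

Default analyses use the 0.05 cm grid (641 depth points to 32 cm), a
268-layer library, 12–42 selected layers per plan, 10⁴ sampled pairs for
the inversion check, and the full 60-geometry conversion sweep; the entire
test suite and the acceptance script each complete in a few seconds on one
CPU.

## Known limitations

* The beam surrogate's absolute dose and beam-quality scales are synthetic;
  only structure, identities and procedures transfer to real beam data.
* 1-D only: no lateral profiles, no 3-D dose grids, no patient or
  heterogeneous geometries.
* The conversion engine accepts LQ tables but implements no particular
  alternative RBE model; published converted-dose values for specific
  clinical models are out of scope.
* The calibration procedure is validated by parameter recovery on
  synthetic references; reproducing any facility's published F_clin would
  require that facility's measured beam model.
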