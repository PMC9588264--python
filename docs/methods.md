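# Methods

## The question the package answers

An iodinated rectal hydrogel spacer reads ~120 HU on planning CT but stops
protons almost like water (SPR ≈ 1.02–1.03). A dose engine that assigns
stopping power from the CT calibration curve therefore overestimates the
spacer's SPR by roughly 8% and predicts a shorter beam range through any
path crossing it. `spacerdose` measures the dosimetric consequence of that
assignment choice by planning once on the true material (TM) and
recalculating the identical, fixed plan under the CT-number assignment (NM)
and a water override (WM). Every difference between the three dose volumes
is attributable to the spacer's material model — nothing else changes.

## Material physics

SPR is computed as relative electron density times the ratio of Bethe
stopping numbers,

SPR = ρₑ,rel · L(I_m, β²) / L(I_w, β²),  L = ln(2 mₑc² β² / (I(1−β²))) − β²,

with β² from the proton kinetic energy (rest energy 938.272 MeV) and mean
excitation energies by Bragg-additivity log-averaging over electron
fractions. The I-value table uses the ICRU condensed-compound constituent
convention (H 19.2, C 81, N 82, O 106, I 491 eV …). The water reference is
computed by the *same* additivity rule (≈75.3 eV, vs the nominal 75 eV for
liquid water), which makes SPR(water) exactly 1 by construction and makes
density scaling at fixed composition exact — two invariants the test suite
relies on. With the spacer recipe (88% water, 0.7% trilysine expanded as
C₁₈H₃₈N₆O₄, 10.1% PEG as its C₂H₄O repeat unit, 1.2% iodine; 1.03 g/cm³)
this gives SPR = 1.0239 at 198.3 MeV, inside the ±0.01 band around the
measured 1.03 benchmark. (Pure elemental I-values with a fixed 75 eV water
reference would give 1.0335 — also in band — but break the exact-self-ratio
invariant; we prefer the consistent rule.)

Effective atomic number uses the power-law mean over electron fractions,
Z_eff = (Σ fᵢ Zᵢ^m)^{1/m} with m = 3.5 (photoelectric-regime convention;
configurable). The spacer computes to 14.26; the published comparison value
is 14.47, whose exact formula/exponent is not public, so agreement is
expected only to a few percent.

The HU→SPR calibration curve is a representative bilinear soft-tissue/bone
shape with knots (−1000, 0.001), (−100, 0.93), (0, 1.00), (100, 1.10),
(1600, 1.85); institutional curves are scanner-specific and not public.
Only its qualitative property matters to the analysis: curve(120 HU) = 1.11
exceeds both the true spacer SPR and water. The curve is fully overridable.

## Phantom generator — what it emulates and what it does not

The generator emulates the planning-CT inputs of a prostate spacer cohort:
a 240×240×160 mm pelvic field of view at 2-mm voxels (desk-scale, smaller
than a clinical 50-cm scan; no fidelity claim to the clinical matrix),
canonical ROIs, per-tissue Gaussian HU noise (soft tissue ≈ 40 HU mean,
fat −100, rectal gas −700, cortical bone 700, spacer 31; sd 10–30 HU), and
a crescent spacer one thickness (10 mm) deep on the prostate's posterior
surface over a 120° arc (~20 cm³). The NVBs are 5-mm cylinders abutting the
prostate capsule posterolaterally (offset 24, 14 mm), which places them in
the lateral-beam corridor behind the spacer — the geometric condition under
which spacer range errors project onto the NVB. Cohorts jitter sizes ±10%
and positions ±3 mm with per-case child seeds (master·1000 + index).

Iodination replaces in-mask voxels with Normal(120, 15) draws (the sd is
not published; 15 HU is typical soft-tissue CT noise) and applies
mask-normalized Gaussian smoothing (σ = 1 voxel) restricted to the spacer
with a one-voxel blend rim, so the in-mask mean is preserved and distant
anatomy is untouched.

Not emulated: beam hardening, metal or motion artifacts, inter-fraction
anatomy change, realistic organ shapes/textures. Passing tests therefore
demonstrate the *mechanism* and the pipeline's correctness, not clinical
effect sizes: published patient-cohort magnitudes (e.g. NVB dose deviations
of hundreds of cGy, PR11 dipping toward 0.7) depend on real anatomy and a
commercial Monte Carlo engine and are reproduced here only as orderings
(NM worse than WM; NVB the worst-affected OAR).

## Dose engine

A deterministic pencil-beam stand-in replaces Monte Carlo transport:

* Pristine peaks: Bragg–Kleeman range R = αE^p (α = 0.0022 cm·MeV⁻ᵖ,
  p = 1.77), residual-range stopping power (R−z)^{1/p−1} convolved with
  Gaussian range straggling σ_R = 0.012·R^0.935 (cm), tabulated at 0.1 mm.
* SOBPs: layers tile the target interval at 80% of the local peak FWHM,
  with the deepest layer one straggling σ beyond the distal edge (the
  Bragg maximum sits ~1σ proximal of the CSDA range); non-negative least
  squares flattens the plateau to within ±3% of its mean, with dose
  falling below 10% within 8 mm of the distal edge.
* Planning: two lateral beams (±x), a 4-mm ray lattice over the CTV
  beam's-eye-view footprint + 5 mm, per-ray SOBP spanning the CTV WEPL
  interval ± 5 mm (margin rays borrow the nearest CTV column's interval),
  equal beam weights, and a global scale setting CTV D95 = prescription
  (hence V(Rx) ≥ 95% by construction; a 1e-9 relative nudge keeps the
  D95-defining voxel above Rx after rounding).
* Dose: per ray, the SOBP is looked up at the WEPL accumulated on the
  *current* scenario's SPR grid and spread laterally by a Gaussian with
  σ(depth) = 3 mm + 0.02·depth, normalized to the ray-lattice cell so a
  uniform lattice sums to a flat field.

Robustness optimization is deliberately replaced by static margins: the
comparison is between nominal recalculations of one fixed plan, which is
what isolates the material effect. Known limitations: no nuclear halo, no
spot deliverability, target homogeneity poorer than clinical plans (hot
center ~115–130% of Rx because edge rays anchor D95), so the body point-
dose constraint can fail post hoc — constraints are reported, not enforced.

## Gamma, DVH, EUD

The gamma search minimizes √(|Δr|²/δr² + ΔD²/δD²) over evaluated positions
on a subvoxel lattice (0.1·δr steps to 3·δr; trilinear interpolation),
normalized globally to the reference (TM) maximum; offsets are visited in
increasing distance with early termination once the distance term alone
exceeds a voxel's best value, which makes whole-volume maps cheap wherever
the doses agree. Pass rule is strict γ < 1; passing ratios exclude voxels
below 10% of the reference maximum (by reference dose; a flag switches the
normalization to local). An exhaustive brute-force oracle validates the
implementation on small grids. The cohort pipeline coarsens the subsample
step to 0.2·δr; the PRs are insensitive at our dose gradients.

Dx values use exact order statistics on raw voxel doses (hottest-x%
convention); DVH bins (10 cGy) serve plotting and EUD. EUD uses the DVH/
voxel power mean with a = −10 (targets; the published sign convention,
taken as printed) and a = +8 (rectum, bladder, NVB); zero-dose bins are
floored at 0.1 cGy for a < 0 to avoid the singularity.

## Statistics

Scenario differences are paired within cases, so the permutation null flips
each case's difference sign independently; the statistic is the mean
difference, two-sided. With n ≤ 12 cases the full 2ⁿ set is enumerated
(exact p); otherwise 1000 random flips with the add-one estimator, which
bounds p ≥ 1/(n_perm+1). The published analysis does not state its
permutation scheme beyond being nonparametric with n = 1000; the sign-flip
design is the simplest exchangeable null for paired data, and its type-I
error is verified by simulation (nominal 5% level within [3%, 7%]).
Boxplot summaries follow the 1.5·IQR whisker convention with whiskers at
actual data points. Raw p-values are primary; Benjamini–Hochberg
annotation is available but off by default.

## Problem sizes and numerical choices

Default analyses use the 120×120×80 × 2-mm phantom (one full case — plan,
three scenario doses, six gamma maps, all indices — runs in ~2 s on one
CPU); the 20-case cohort study runs in under a minute. The spacer-HU
acceptance statistics use the 1-mm variant of the same geometry
(~2×10⁴ spacer voxels) so the 1-HU tolerance on the mean is meaningful.
A 3-mm `reduced` preset exists for smoke tests and examples; it is not
used for headline numbers because coarse voxels inflate hot-edge EUDs on
thin structures adjacent to steep gradients.

Ties and degenerate inputs: D95-defining voxel handled as above; empty
gamma denominators return NaN (undefined) rather than raising; single-layer
SOBP requests return one pristine peak; a one-voxel CTV still yields a
valid two-beam plan; all-zero paired differences give p = 1.
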