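# Methods

## Scope and data model

`ricdosim` implements the standard preclinical internal-dosimetry chain
for radioimmunoconjugates: tidy per-animal biodistribution tables
(%ID/g) → absolute source-region activity curves → time-integrated
activity (Ã) → MIRD-style equivalent doses → %kg/g human projection,
with a saturation radioligand-binding analysis alongside.  Inputs are
plain delimited text throughout; per-animal long format is the canonical
layout because group SEMs and small-sample rank tests need individual
animals, and the familiar wide "organ × time" table is produced only as
a report.

%ID/g values are treated as decay-corrected at measurement, because the
dosimetry formula re-applies the physical decay factor e^(−λt)
explicitly.  For counting pipelines that do not decay-correct, every
entry point accepts `apply_decay=False`.

## Decay and nuclides

λ is always derived as ln 2 / t½, so λ·t½ = ln 2 holds to machine
precision.  The bundled registry carries Cu-64 (t½ = 12.7 h,
λ ≈ 1.516×10⁻⁵ s⁻¹) and Lu-177 (t½ = 6.7 d, λ ≈ 1.197×10⁻⁶ s⁻¹); users
can load their own table to use, e.g., t½ = 6.647 d for Lu-177.
Emission metadata is provenance only — all dose physics enters through
S-values.  Internal time is seconds; public inputs are hours (the units
biodistribution studies are sampled in).

## Time-integrated activity

Ã = AUC₀–T (trapezoid on the sampled activity curve) + A(T)/λ.  Choices
and their rationale:

* **Trapezoid** — the rule behind the AUC of common graphing software,
  and the least-assumption numerical integral for 3-point curves.  No
  compartmental fitting is attempted at these sampling densities.
* **Boundary rule for [0, t_first]** — the study design leaves 0–6 h
  unobserved.  Default `plateau` holds the first observation back to
  t = 0, which is conservative (dose-overestimating) for blood-borne
  agents whose activity declines from injection; `zero` and `linear`
  (back-extrapolation of the first two points, floored at 0) are
  selectable, and the choice is recorded in report provenance.
* **Tail** — A(T)/λ assumes elimination after the last sample is by
  physical decay only (no further biological clearance), again
  conservative.  If the last observation precedes T the tail attaches
  there, with a warning.
* **Group means vs per-animal curves** — destructive sampling (each
  animal contributes one time point) means only group-mean curves exist;
  the pipeline therefore integrates group means.  Per-animal curves can
  be fed through the same functions when longitudinal (e.g. imaging ROI)
  data are available.

Organ masses are required — %ID/g → absolute activity has no other
route — and come from per-row values when recorded or from a registry.
The bundled registry is a literature-style 30 g mouse (liver 1.75 g,
kidneys 0.45 g, blood 2.3 g, ...); it is a default users are expected to
replace with study-specific weights.

## Dose computation

D(target) = Σ Ã(source)·S(target←source)·W_R, with W_R = 1 by default
(β/γ/x).  Published phantom S-value tables (rodent or human) are
third-party data and are consumed as input tables; absent cross-organ
entries contribute zero, so self-dose-only tables are a degenerate but
first-class case, and reports record which table and mode produced them.
The package ships no phantom values: test fixtures are generated from
the non-penetrating approximation S = E_mean/m (mean emitted energy per
decay over region mass), which makes every computed dose analytically
checkable (D = Ã·E_mean/m) and is clearly labelled synthetic in the
table's phantom id.

The tumour is dosed exclusively by sphere self-dose (no cross-dose
exchange with normal organs): S(m) curves are interpolated log-log,
which is exact for the near power-law mass dependence of sphere
self-dose values and exact at the nodes; extrapolation outside the
tabulated mass range raises an error unless clamping is explicitly
requested.  Whole-body Ã is either a measured whole-body row or the sum
of organ sources — both modes exist because published reports rarely say
which construction they used.

## Human projection

(%ID/organ)_human = (%ID/organ)_mouse × BW_mouse/BW_human with defaults
30 g / 56,900 g, time grid unchanged (no allometric time scaling).
Since the whole chain is linear in %ID, the projected human Ã of every
organ is exactly the body-weight ratio times the mouse Ã on the same
grid; the implementation uses this identity, and the test suite pins it
to 1e−12 relative.  The projected tumour keeps the mouse-measured time
course (converted at the mouse tumour mass) but is dosed as a 2 cm
diameter unit-density sphere (4.19 g) by default.  The audit table of
mouse and projected human %ID/organ per time point is written alongside
every projection report.

## Binding assay

The classical workflow is followed: NSB (excess-competitor arm) is
modeled as ns·F and subtracted from TB; SB is fit to
B_max·F/(K_d + F) by bounded least squares (`scipy.optimize.curve_fit`,
unweighted by default, 1/Y² weighting selectable).  A joint
TB = B_max·F/(K_d+F) + ns·F fit is available as an alternative mode.
Free concentration is the nominal added concentration — at ~10⁶ cells
and pmol-scale capacity, ligand depletion is <2% across the
0.098–200 nmol/L series — with a depletion-corrected mode available.
A fit whose K_d lands outside [0.01·F_min, 100·F_max] is rejected as
unidentified by the design rather than reported.  Receptors/cell =
B_max·10⁻¹²·N_A / n_cells.

## Synthetic data generators

Generators are pure functions of (spec, seed) and emulate the study
design, not just the numbers:

* **Biodistribution** — each organ follows either a biexponential
  decline (blood-like) or an uptake–washout difference of exponentials
  (tumour-like, uptake rate > washout rate).  The default "study-like"
  spec set interpolates a published-style three-point (6/24/48 h) group
  mean table: blood 10.6 → 4.8 → 1.9 %ID/g, tumour 9.3 → 14.9 → 9.8
  (peak near 24 h), liver declining slowly; the parameters were fit once
  by least squares and frozen (muscle/bone/skin smoothed by hand where
  an unconstrained fit produced unphysical t = 0 amplitudes).  Noise is
  multiplicative mean-one lognormal at a per-organ CV (default 10%,
  the SEM/mean scale of small-group biodistribution tables), which
  preserves positivity and leaves group means on the true curve.
  Animals are distinct per time point (terminal sampling).
* **Binding assay** — TB = B_max·F/(K_d+F) + ns·F and NSB = ns·F with
  the same noise model, in duplicate over a 2-fold dilution series
  0.098–200 nmol/L (defaults K_d = 2.9 nmol/L, B_max = 1.83 pmol/10⁶
  cells ≈ 1.1×10⁶ sites/cell, ns = 0.002 pmol per nmol/L, 5% CV).
* **S-value fixtures** — E_mean/m self-dose tables and sphere curves as
  above.

What the generators deliberately do **not** emulate: inter-animal
pharmacokinetic heterogeneity beyond independent lognormal scatter,
correlated organ uptake within an animal, counting statistics,
depletion/crossover effects, or true phantom geometry.  Passing tests
therefore demonstrate the pipeline's arithmetic and contracts under the
study's design, not the biological fidelity of any kinetic model.

## Statistics

Group cells report arithmetic mean ± SEM (sample SD/√n).  Tumour/blood
ratios come in two modes: ratio of group means (what printed wide tables
support) and mean of per-animal ratios with SEM (the default when
per-animal pairing exists, and the mode that published T/B rows with
their own SEMs imply).  The Mann–Whitney test is exact: all
C(n_a+n_b, n_a) assignments of pooled midranks are enumerated and the
two-sided p is P(|U − n_a·n_b/2| ≥ |U_obs − n_a·n_b/2|) under that
uniform null — well-defined under ties, symmetric in its arguments,
invariant to monotone transforms, and verified against a brute-force
permutation oracle for all group sizes summing to ≤ 8 (and against
scipy's exact method on tie-free data).  No multiplicity correction is
applied.  Intended regime is n ≤ 10 per group.

## Problem sizes and determinism

The simulation studies shipped with the package use 100 binding-assay
replicates and groups of 3–5 animals (50 for law-of-large-numbers
checks) — the scale of the study design they emulate; everything runs in
seconds.  All random streams derive from explicit numpy `SeedSequence`
seeds; reports and CLI runs record their configuration hash, seeds and
input-table checksums.

## Known limitations

* No compartmental/biexponential fitting for Ã, no uncertainty
  propagation through the AUC; dose SEMs across animals are out of scope
  (group-mean curves carry no dispersion).
* No decay-chain (daughter) dosimetry, voxel dosimetry, or Monte Carlo
  transport; S-values must come from the user.
* The %kg/g projection inherits all the usual caveats of linear
  interspecies extrapolation (no kinetic time-scaling, no
  species-specific receptor biology).
* The exact rank-sum test is combinatorial and intentionally capped at
  n = 10 per group.
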