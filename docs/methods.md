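# Methods

## Model structure

The model tracks complexes of four entities — the VEGF-A165 dimer (V), a
matrix/heparin binding site (M), VEGFR2 (R2) and Neuropilin-1 (N1) —
across five compartments: extracellular fluid, cell surface, Rab4/5 early
endosomes, Rab11 recycling endosomes, and a retained degraded pool.
Composition rules (N1 and M exclude each other on one VEGF dimer; R2
couples to N1 or M only through V) admit nine complex types; with every
VEGFR2-containing form carrying all eight phosphorylation patterns of
{Y951, Y1175, Y1214}, enumeration yields 97 species: 3 extracellular
(V, M, V·M), 34 surface (R2, V·R2, M·V·R2, V·N1·R2 × 8 states + N1,
V·N1), 27 in each endosomal compartment (R2, V·R2, V·N1·R2 × 8 + N1,
V·N1 + free V), and 6 phospho-free degraded pools. Free V appears in both
endosomal compartments because it is generated there by dissociation; in
Rab11 it only rebinds (no degradation rate is defined for it), in Rab4/5
it is degraded at 1.2×10⁻² s⁻¹. M·V·R2 exists only at the surface and is
never internalized (the ligand is anchored). Degraded pools are retained,
not deleted, which turns receptor mass balance into a testable identity.

All reactions are mass action. Binding occurs in every compartment where
both partners exist (15 reversible types); trafficking
(internalization, recycling from Rab4/5 and Rab11, Rab4/5→Rab11 transfer,
degradation from Rab4/5 only) applies per species form with
phospho-uniform rates; phosphorylation and dephosphorylation are
first-order per residue and per (form, compartment) class — 10 classes ×
3 residues × 4 source states = 120 reversible reactions. Degradation
clears the phospho-state; every other process preserves it. Assumptions
inherited from the underlying biology: ligand and receptor are
pre-dimerized; phosphatases are in excess (first-order dephosphorylation);
trafficking depends on ligation, not phosphorylation state; newly produced
receptor is unphosphorylated.

## Parameters and units

Kinetic constants, trafficking rates, and phospho rates are the published
representative set (fluid-phase k_on in M⁻¹s⁻¹, receptor–receptor coupling
in (mol/cm²)⁻¹s⁻¹, first-order rates in s⁻¹). M·V·R2 uses the surface
V·R2 phosphorylation rates (the intrinsic chemistry is assumed identical
for immobilized and soluble ligand), and the M + V·R2 capture reaction
uses the study-specific V·M kinetics.

Internally every pool is stored as molecules per cm² of cell surface;
extracellular molar pools are mapped through N_A × (fluid volume per unit
area) so cross-compartment fluxes are exactly 1:1 and a single absolute
tolerance applies. Bulk association constants are divided by
N_A × V_fluid (surface reactions) or N_A × V_endosome (endosomal
reactions); areal coupling constants are divided by N_A. Reported time
courses convert extracellular species back to molar.

Geometry defaults (exposed in `Geometry`): cell density 10⁵ cells/cm²
(confluent endothelial monolayer), endosomal volume 10⁻⁷ cm³ per cm² of
cell surface for each of Rab4/5 and Rab11, fluid depth 0.5 cm (0.05 cm for
the 2011-study immobilized arm), VEGF dimer mass 45 kDa, matrix-site mass
40 kDa. The matrix-site mass converts a gel loading of 3 mg/mL into a
7.5×10⁻⁵ M binding-site concentration — ≈30× the V·M K_D of the
gel studies, so ≥95% of VEGF is matrix-bound at equilibrium, consistent
with initializing immobilized protocols with all VEGF in V·M. These four
numbers are order-of-magnitude morphometry, not measured values; the
acceptance quantities that depend on them say so below.

Study configurations reproduce the published columns: PAEC trafficking
arms (37,400 R2; 108,000 R2 + 113,000 N1; 113,000 N1 alone) at 50 ng/mL
soluble VEGF; HUVEC presentation studies (6,000 R2, 35,000 N1) with all
degradation rates ×2.4 and, for [V] > 50 ng/mL, ligated-receptor
internalization ÷6 (saturation of endocytosis at high occupancy; at
exactly 50 ng/mL the original rate is kept). Receptor production rates
are computed analytically from the unligated linear subsystem
(s = k_degr·E45 with E45 = k_int·S/(k_rec4 + k_4to11 + k_degr)), which
holds the no-VEGF distribution stationary — for VEGFR2, 57.8% surface,
39.4% Rab4/5, 2.8% Rab11.

## Numerics

The system is stiff (rates span 30–75 s⁻¹ to 10⁻⁵ s⁻¹), so the default
integrator is scipy's BDF with an analytic sparse Jacobian assembled from
the reaction list; relative tolerance 10⁻⁸, absolute tolerance 10⁻⁶
molecules/cm² (both exposed). An explicit adaptive 5th-order Runge–Kutta
(RK45) option is retained; a regression test holds the two to within 0.1%
on the acceptance scenarios. Pre-stimulus steady states are analytic (the
no-VEGF subsystem is linear), verified by a derivative-norm check that
excludes the degraded pools (which grow at exactly the production rate).
Estimation and sensitivity simulations use rtol 10⁻⁶ / atol 10⁻³ — the
observables live on a percent scale — keeping a cost evaluation below
0.1 s. Negative excursions beyond 100× atol abort a run; accepted
trajectories are clipped at zero. Peaks and AUCs are evaluated on a
1-second resampled grid; ratio observables return NaN where the
denominator is below 10⁻³% of baseline, and "early window" for ratio
statements means 2–10 min.

## Observables

All receptor readouts are normalized to total (non-degraded) VEGFR2 at the
pre-stimulus steady state = 100%. pY951/pY1175/pY1214 sum every
R2-containing species with that residue set; pR2 is the union (≥1 residue
set), not the sum. The phosphorylated fraction of ligated receptor divides
phospho-ligated (V·R2, M·V·R2, V·N1·R2 over surface + endosomes) by all
ligated receptor.

## Estimation

Six trafficking rates are free — k_rec4(R2), k_rec11(N1), k_4to11(N1),
k_degr(V·R2), k_degr(N1), k_degr(V·N1·R2) — with the published tie
structure (e.g. NRP1 species recycle from Rab4/5 at 1/100 the VEGFR2 rate;
free-receptor degradation is 1/10 of ligated). Optimization runs in log10
space under box bounds [10⁻⁵, 1] s⁻¹ via scipy's trust-region-reflective
least squares (the bounded Levenberg–Marquardt-type method), from starts
drawn log-uniformly in [10⁻⁴, 10⁻²] s⁻¹; ensembles accept sets within 15%
(trafficking; 65% for phospho problems) of the lowest cost, subject to a
plausibility filter rejecting sets predicting < 10 phospho-receptors per
cell at peak. The steady-state term penalizing departure of the no-VEGF
surface share from 60% enters as one residual with weight 1 in the same
percent units as the data (a fixed, exposed weight; a weight defined as a
fraction of initial cost degenerates on self-consistent data).

The original measurement tables are not distributed with the model, so
the machinery is validated by synthetic-data recovery: observations are
the normalized internal distributions (Rab4/5 / Rab11 / degraded fractions
summing to 100% per receptor, at 10 and 30 min), surface-NRP1 and
total-receptor time courses (5–60 min) for the three transfection arms of
the trafficking experiment, with multiplicative Gaussian noise (CV 0.1)
and post-noise renormalization of the fractions. The NRP1-only arm is
essential: without it k_degr(N1) is unidentifiable because V·N1·R2
degradation dominates N1 loss in double-transfected cells. The fit runs on
the phospho-free reduced network (trafficking is phospho-blind; the
equivalence is itself a tested property). What recovery shows: the
optimizer and observable pipeline are correctly wired and the stated
parameters are identifiable from the stated data at 10% noise
(≥80% of 20 replicates recover all six within 2×). What it does not show:
that real colocalization data — with its segmentation biases, non-Gaussian
noise and Rab4-vs-Rab5 split — would constrain the same rates equally
well.

## Sensitivity

One-at-a-time ×2 and ÷2 perturbations; per output the absolute percent
change from baseline is computed, the two directions averaged, and results
aggregated over a panel (pY1175, pY1214, pY1214/pY1175 at 5/15/30 min,
soluble and immobilized VEGF at 2 and 200 ng/mL). Tied trafficking
families are perturbed as a unit to preserve the published ratios; outputs
under the ratio floor are excluded and counted.

## Known limitations and a documented table inconsistency

* Spatial transport is lumped into effective rates; no diffusion, no
  explicit Rab7 compartment, no downstream signaling (ERK/p38/Akt), no
  stochasticity.
* Geometry (cell density, endosomal volumes, matrix-site molarity) is
  order-of-magnitude; quantities driven by surface-vs-internal
  partitioning under immobilized VEGF inherit that uncertainty.
* The published trafficking table is internally inconsistent in its Rab11
  recycling block (a corrupted exponent and tie annotations referencing a
  nonexistent parameter). Taken as printed, ligated receptor exits Rab11
  faster (71 s residence) than it exits Rab4/5 (48 s), so ligated receptor
  can never accumulate in the fast-dephosphorylating Rab11 pool. As a
  consequence this implementation — which follows the printed values
  exactly — predicts a *higher* phosphorylated fraction of ligated
  receptor under immobilized VEGF (≈80% at 5 min, ≈56% at 30 min) than
  the original report (33% / 7%), and a pY1214:pY1175 peak balance below
  the reported >2×. Re-tying Rab11 recycling of V·N1·R2 to the slow
  ligated-R2 value reproduces the reported qualitative behavior but not
  the printed numbers, and contradicts the printed table; we therefore
  ship the printed values and flag the four affected quantities rather
  than silently altering a published rate. The corresponding acceptance
  tests fail by design and say so.
* Y951 dephosphorylation rates were poorly constrained in the original
  fits; pR2-based readouts here are dominated by Y951 occupancy on
  surface-ligated receptor and should be interpreted with that caveat.
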