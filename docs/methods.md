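# Methods

## Scope and model structure

`lungdose` estimates whole-lung aerosol deposition over full tidal breaths
for three reference subjects (infant, 3 months; child, 6 years; adult,
36 years) breathing 1, 3 and 5 µm unit-density rigid spheres. The pipeline
is: subject record → FRC-scaled airway morphometry → tidal waveform → 1D
trumpet transport with mechanistic wall losses → dosimetry metrics.

Image-based 3D airway geometries and computational fluid dynamics are out
of scope: the entire tree, from the trachea down, is represented by the 1D
cross-section-integrated (trumpet) equation. This is a deliberate
desk-scale surrogate; its consequences are discussed under *Limitations*.

## Subjects

The packaged subject records hold resting-breathing parameters: tidal
volume TV (49/209/500 mL), respiratory rate RR (0.66/0.32/0.25 breaths/s),
FRC volume (81/830/3000 mL), lung surface area at FRC A_FRC
(3.2/27.4/64.7 m²), body surface area BSA (0.31/0.77/1.64 m²) and tracheal
diameter (4/8/16 mm; the infant value is anatomical, child and adult
follow a height-based doubling). A_FRC is never recomputed from the
generated tree — surface-area normalizations always use the tabulated
value.

## Morphometry

Each lung is a shared path (trachea, generation 0; main bronchi,
generation 1) feeding five lobe trees with subtended volume fractions
0.25/0.20/0.25/0.09/0.21 (LI/LS/RI/RM/RS). Within a lobe, generation k has
2^k airways. Defaults, all overridable per run configuration:

| parameter | default | rationale |
|---|---|---|
| conducting taper (d, L per generation) | 2^(−1/3) ≈ 0.794 | classical Weibel-type regular dichotomy |
| length:diameter ratio | 3 | typical conducting-airway value |
| generations | 24 (0–23) | full adult path |
| respiratory zone start | generation 16 (17 for the infant's left inferior lobe) | first alveolated generation |
| acinar taper | 0.93 per generation | transitional bronchiole ~0.5 mm to alveolar sac ~0.25 mm (adult) over ~8 generations; the conducting decay law does not continue into the acinus |
| alveolar volume per respiratory row | 2× duct lumen volume | acinar partition between duct lumen and alveoli; weights expandable volume toward the deep acinus because duct volume itself grows distally |
| alveolar diameter | 0.5× local duct diameter | settling scale of alveolus-resident aerosol |
| within-generation length CV (σ_L/L) | 0.3 | drives the mixing coefficient |
| mean \|cos\| airway-to-gravity angle | 0.5 | randomly oriented airways |
| branch angle | 35° | typical mean branching angle from the parent axis |
| trachea length | 0.6 mm per cm body height | height-based scaling (96/69/33 mm) |

Every lobe tree is rescaled (linear dimensions by the cube root of the
volume ratio, alveolar volumes by its cube) so that lobe volume equals its
fraction of FRC minus the shared-path volume; the assembled model matches
the subject FRC to 0.1%. Only the *shape* of the seed tree matters — the
absolute seed diameter cancels under FRC scaling. The resulting conducting
airway volume is ~4% of FRC (≈144 mL for the adult), consistent with
intrathoracic anatomic dead space. Users can substitute any morphometry
through the CSV dialect (`lobe,generation,n_airways,diameter_mm,length_mm,
length_sd_mm,zone,gravity_cos,branch_angle_deg,alveolar_volume_ml`).

## Breathing

Flow is prescribed, not solved: half-sinusoid inspiration and expiration
with a configurable I:E time ratio (default 1:1). Each half integrates
exactly to TV. Mean inspiratory flow is TV divided by inspiratory time
(2·TV·RR at 1:1), giving 15 L/min for the adult and 64.7 mL/s for the
infant. Pressure–resistance–compliance dynamics are not modelled.

## Transport solver

The five lobes are solved as independent 1D columns; each column prepends
the shared path with its cross-section scaled by the lobe's flow share
(the lobe's fraction of total expandable volume), so conduit speeds in the
shared path are the physical ones. On each column the solver advances

∂(A_tot c)/∂t + ∂(Q c)/∂x = ∂/∂x (D_app A_aw ∂c/∂x) − Λ A_tot c

by a conservative finite-volume scheme (cells per generation configurable,
default 2): first-order upwind advection, explicit central mixing with
D_app = D_B + β σ_L |u| (β default 1; only the functional dependence on the
length spread and the conduit speed is specified, the constant is a model
choice), and exponential (unconditionally stable) loss. Alveolar cell
volumes inflate linearly with the whole-lung waveform volume; axial face
flows follow from continuity, Q(x) = Q_in(t) × (expandable volume distal
to x)/(total expandable volume), so the distal end carries zero flow. The
sub-step is fixed per call from the sampled peak flow and end-expiratory
cell volumes at CFL 0.9 (combined advective/diffusive limit); the scheme
preserves positivity and closes the mass balance to machine precision
(inhaled = deposited + exhaled + suspended; the suite enforces 0.01%).

Deposition mechanisms differ in what they act on:

* *Resident* mechanisms (sedimentation) act on all mass in a cell. The
  settling scale is the duct diameter for conducting cells; for alveolated
  cells it is the 1/d-weighted harmonic combination of the duct and
  alveolar compartments. This matters: most acinar mass resides in
  alveoli, whose settling dimension is about half the duct's.
* *Per-transit* mechanisms (impaction at the generation's bifurcations,
  diffusive wall capture over the duct length) are incurred once per
  passage, so the solver exposes only the through-flowing flux to them —
  aerosol parked in an alveolar reservoir crosses no bifurcation and must
  not accumulate impaction losses.

When the local speed falls below 1 µm/s the kernel residence time is
capped at the current sub-step to avoid singular probabilities; single-
mechanism rates are capped at 10⁴ 1/s. Removed mass is credited to a
ledger by generation, lobe, zone, mechanism and breath phase. The inlet
holds a fixed concentration (default 1 µg/mL) whenever flow is
inspiratory, making the injected mass flux proportional to the local flow
rate; mass crossing the inlet during expiration is tallied as exhaled.
One breath is simulated by default; the model is deterministic — no Monte
Carlo.

## Dosimetry metrics

All metrics are exact arithmetic on the closed ledger and the subject
record, independent of the solver: Dep_T/Dep_C/Dep_R (% of inhaled over
both phases), CR = Dep_C/Dep_R (flagged infinite when Dep_R = 0), exhaled
and suspended percentages, tissue dose Dep_T·TV/A_FRC (%·mL/cm², TV in
mL), deposition rate Dep_T·TV·RR (%·L/s, TV in L), its BSA-normalized
form, and TV-scaled deposition Dep_T·TV/TV_adult. Zone-area-normalized
doses are computed only when the user supplies zone surface areas — the
package never invents normalizers. The NP statistic
(N_e/N_T)·(Σ_T/Σ_e) has area-weighted mean 1 by construction.

Extrathoracic (mouth/nose-throat) pre-filtering is off by default and no
efficiency coefficients ship with the package; users register a
correlation η(Re, Stk) and the inhaled bolus is scaled by 1 − η/100. The
extrathoracic Reynolds and Stokes numbers use Re = 4ρQ̄/(πµD) and
Stk = ρ_p Cc d_p² w/(18 µ d_c) with air at ρ = 1.2 kg/m³,
µ = 1.8×10⁻⁵ Pa·s; the slip correction is included in Stk by default
(flag recorded in metadata), and Brownian diffusivity uses body
temperature (310 K).

## Synthetic variability

The synthetic module perturbs the fixture subjects (TV, RR, FRC) and lobe
morphometries (diameters, lengths) with multiplicative lognormal noise of
configurable CV (default 0.1, a modest anatomical spread; no population
calibration is claimed). Perturbed lobes are rescaled back to their FRC
share, so the whole-lung volume constraint holds exactly. Output is
deterministic per seed, bitwise through the whole pipeline.

## Numerical and test problem sizes

The shipped defaults keep every run desk-scale: 2 cells per generation
(≈240 cells across five columns), a few thousand sub-steps per breath; a
full-breath run takes ~1–3 s. The test suite runs the 3 subjects × 3 sizes
campaign at this resolution, the grid-refinement comparison at 1 vs 4
cells per generation, and the intersubject-robustness experiment with 6
perturbed infants vs 6 perturbed adults at 1 cell per generation — sizes
chosen so the whole suite completes in about a minute while still
exercising every stage.

## Verification

* Mass balance closes to well below 0.01% on all fixture runs.
* A bolus traversing a rigid uniform tube with a constant first-order loss
  rate k reproduces the analytic deposited fraction 1 − exp(−kL/u) within
  1% at 4 cells per generation.
* Refining 1 → 4 cells per generation moves Dep_T by < 2 percentage
  points (infant and adult, 3 µm).
* Trend structure holds: Dep_T increases with particle size and decreases
  with age (3 and 5 µm); the CR ratio increases with particle size;
  the exhaled fraction decreases with particle size.

## Limitations

* **Central-airway deposition is under-represented.** A 1D conduit with
  laminar empirical kernels cannot reproduce the enhanced impaction caused
  by the laryngeal jet, turbulence and secondary flows in real central
  airways (tracheal Reynolds numbers reach ~1000–2300 here). Yeh–Schum
  impaction at the conducting-tree Stokes numbers of the infant
  (~0.03) captures only a few percent per generation, so the
  conducting/respiratory deposition ratio comes out markedly lower than
  image-based 3D/1D coupled simulations report, especially for the infant.
  Total deposition, exhaled fractions and all trend orderings are much
  less sensitive to this split. Turbulent-deposition kernels are
  deliberately out of scope; the kernel registry exists so users can swap
  in stronger published efficiencies.
* The default morphometry is a regular-dichotomy stand-in, not a measured
  lobe-specific table; lobe differences enter only through volume
  fractions and the infant's delayed left-inferior alveolation.
* Exhalation re-enters the same 1D domain (no separate central-domain
  hand-off); deposition is still split by phase in the ledger.
* Particles are rigid, non-hygroscopic spheres; no electrostatics, no
  cloud effects, no breath-hold maneuvers.
* The synthetic variability model tests robustness of the pipeline; it is
  not a calibrated population model, so spreads across synthetic subjects
  must not be read as epidemiological variability.
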