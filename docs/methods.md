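# Methods

`afconcord` models, at desk scale, the computational arm of a
simulation-vs-ECGI comparison of reentrant drivers (RDs, rotors) in
persistent atrial fibrillation: monodomain propagation on fibrotic 2D
atrial sheets with chronic-AF membrane kinetics, multi-site burst-pacing
AF induction, phase-singularity (PS) tracking and RD classification,
virtual ablation with re-inducibility testing, and the region-level
agreement and outcome statistics used to compare simulated against
clinically mapped RD locations.

## Membrane models

**Full atrial backend.** The Courtemanche–Ramirez–Nattel human atrial
model (21 state variables) integrated with Rush–Larsen updates for the
15 Hodgkin–Huxley-type gates and explicit updates for voltage and
concentrations, dt ≤ 0.02 ms. The chronic-AF electrical-remodeling
variant is applied as named conductance multipliers with defaults
g_to ×0.5, g_CaL ×0.3, g_K1 ×2.0, g_Kur ×0.5 — the widely used
AF-remodeling set, chosen because the precise multipliers are a
literature convention rather than a single canonical value; all are
config-overridable. Under these defaults the quiescent cell rests at
−84.1 mV and paces with APD90 ≈ 136 ms at a 500 ms cycle length, in the
chronic-AF range. A 60 s equilibrated fixed point is pinned as the
default initial state so short equilibrations start at rest
(|dV/dt| ≈ 2×10⁻⁸ mV/ms).

**Fibrotic remodeling.** Fibrosis-affected myocytes scale three maximal
conductances: I_K1 ×0.5, I_CaL ×0.5, I_Na ×0.6. A `remodeled` flag
forbids double application, since silently compounding ×0.5 scalings is
an easy bug to ship. Under these scalings the full-backend fibrotic cell
rests ≈2.8 mV depolarized (reduced inward rectifier) and repolarizes
about 15% later (APD90 156 vs 136 ms): the I_K1 reduction outweighs the
I_CaL reduction.

**Surrogate backend.** Tissue-scale work uses a three-variable
Fenton–Karma-style excitable medium (fast inward, slow inward, ungated
plus gated outward currents; two recovery gates), with the activation
variable mapped affinely to millivolts (rest −85 mV, excursion 105 mV)
so activation detection and phase mapping are backend-agnostic. The
slow-inward activation is graded (tanh midpoint u = 0.5) and its resting
value is subtracted so u = 0 is an exact fixed point. Defaults (tau_d
0.25 ms, tau_o 12.5, tau_r 32, tau_si 36, tau_w+ 400, tau_w− 41 ms, …)
were chosen once to give a short chronic-AF-like action potential
(APD90 ≈ 95 ms) whose spiral waves are stable and spatially confined on
centimeter-scale sheets: with the default conduction velocity
(≈0.40 mm/ms) the reentrant wavelength ≈ 40 mm fits a 60×60 mm sheet
with enough margin that a cross-field rotor meanders within a ~11 mm
radius instead of being pushed around by the boundaries. Fibrotic
remodeling maps onto the surrogate as (i) excitability ×0.6 (tau_d /
0.6, mirroring the I_Na scaling — the fibrotic diastolic threshold is
measurably higher), (ii) plateau outward slowed by ×1.04 on tau_r,
calibrated so the fibrotic/non-fibrotic APD90 ratio (1.15) matches the
full backend under identical scalings, and (iii) tau_o ×2 mirroring the
slower inward-rectifier-driven late repolarization. The longer, less
excitable fibrotic action potential is what creates the dispersion of
refractoriness that lets rapid pacing break wavefronts at patch borders.

## Tissue model

Monodomain reaction–diffusion on a regular 2D sheet, node spacing
dx = 0.5 mm by default (the same resolution class as the patient
finite-element meshes, ~0.46 mm edges). The diffusion term ∇·(D∇V) uses
a per-node anisotropic tensor built from the local fiber angle with
D_trans/D_long = 0.25 by default, discretized in conservative
finite-volume (face-flux) form: every face flux enters its two nodes
with opposite signs, so a uniform field maps exactly to zero, column
sums vanish, and total voltage is conserved to machine precision when
the reaction term is off. Faces touching a non-conductive node carry
zero flux, which makes ablation lesions and obstacles true no-flux
boundaries (mirror method). Mixed-derivative (fiber-rotation) terms are
also in flux form; their cross-differences are dropped one-sided where a
stencil node is non-conductive.

Time stepping is operator-split explicit (diffusion, then reaction) with
the diffusion stability bound dt ≤ dx²/(4·max D) enforced, and an
instability detector aborts if |V| exceeds 100 mV. The loop is fused in
a numba kernel (CSR matvec + per-node reaction with precomputed gate
decay factors); runs are bitwise deterministic for a given grid, config
and seed. Fibrosis-labeled nodes step with the remodeled parameter set
and additionally scale D by 0.5 (slowed fibrotic conduction).

Conduction velocity is measured from a linear fit of activation times
(−40 mV upstroke crossings, interpolated) over the central 50% of a
planar-wave strip, and calibrated by iterating the near-√D law
D ← D·(target/measured)². Defaults give ≈0.40 mm/ms longitudinally —
deliberately at the slow end of the clinical atrial range, consistent
with remodeled AF atria and with keeping rotor wavelength below the
sheet size. At dx = 0.5 mm the wavefront is marginally resolved and CV
sits ~10% below its continuum value; convergence tests therefore compare
dx = 0.25 vs 0.125 mm (CV changes <5%, and the √D scaling ratio is
2.05).

## Virtual patients and the region scheme

Fibrosis maps are Gaussian random fields (white noise smoothed with a
Gaussian kernel of standard deviation = correlation length, default
5 mm) thresholded at the empirical (1−density) quantile, so the realized
fibrotic burden equals the requested density up to single-node
quantization for every seed. Generator defaults span the burdens of
fibrotic-AF cohorts (10–40%); the packaged demonstrations use 30%.

The seven clinical anatomical regions map onto the sheet as a fixed
template (fixed, like the clinical scheme, so region-level results are
comparable across seeds):

```
        x →
  +---------+----+---------+
  | 1 LPVs  |    | 2 RPVs  |     left column  = "left atrium" side
  +---------+ 7  +---------+     right column = "right atrium" side
y | 3 PLA   |IAG | 4 SRA   |     central band = inter-atrial groove
  +---------+    +---------+                   (~10% of nodes)
  | 6 ALA   |    | 5 IRA   |
  +---------+----+---------+
```

LPV/RPV = left/right pulmonary veins, PLA/ALA = posterior/anterior left
atrium, SRA/IRA = superior/inferior right atrium, IAG = inter-atrial
groove. The six lateral zones have equal areas to within 2%.

**Synthetic ECGI observations.** The simulated (latent) RD-region set of
a patient generates a clinical observation by keeping each latent region
with probability p_manifest (default 0.7) and adding each non-latent
region with probability p_extra (default 0.1). This is the statistical
skeleton of the mechanistic picture behind the comparison: simulations
enumerate every site the fibrotic substrate *could* sustain, only part
of which manifests in a mapped episode, while some clinical RDs arise
from mechanisms unrelated to fibrosis. The two probabilities are
binomially identifiable; their MLEs are the pooled observed fractions,
recovered within ±0.03 from 500-patient ensembles.

## Induction protocol

Pacing sites are placed by farthest-point sampling over conductive
nodes, seeded at the centroid-nearest node (deterministic, ties to
lowest (y, x)), 30 sites by default. Each site receives a decremental
burst train — 6 beats at each of 200, 150, 120 ms by default, 2 ms
pulses of 30 mV/ms (~4× diastolic threshold) in a 1 mm radius — followed
by a 2.5 s free run. The ramp ends near the fibrotic tissue's refractory
period (non-fibrotic APD90 95 ms, fibrotic ≈109 ms plus slowed
post-repolarization recovery), because wavebreak requires the last beats
to encroach on dispersed refractoriness; ramps ending at 200 ms (far
above APD) never induce. Sustained AF is declared when at least one node
activates in the final 250 ms of the free run and the median per-node
activation count over the free run is ≥2 (both thresholds
config-exposed; the criterion is a package convention). Sustained
episodes go through the phase pipeline and their RDs are pooled into the
patient's RD-harboring region set. At 30% burden roughly half to
two-thirds of sites induce sustained reentry.

## Phase analysis

Instantaneous phase is the angle of the analytic signal (Hilbert
transform) of each node's mean-subtracted voltage; time-delay embedding
(quarter-cycle delay, same sign convention) is available as a config
alternative. PSs are detected per frame by topological charge: the sum
of wrapped phase differences counter-clockwise around every 2×2
plaquette of valid conductive nodes equals ±2π at a singularity, the
sign giving chirality. Detections are linked frame-to-frame by greedy
nearest-neighbor assignment constrained to equal chirality and step
distance ≤ v_max·Δt (v_max 3 mm/ms — rotor tips jump up to ~2.5 mm
between 1 ms frames during meander), bridging up to 20 ms of missed
detections; ties break by distance then lowest (y, x), so linking is
deterministic.

A trajectory is classified as a reentrant driver when it persists
≥200 ms and ≥2 rotations, stays within a 15 mm confinement radius of its
centroid, and does not encircle a non-conductive obstacle larger than 4
nodes (macro-reentry exclusion, tested by convex-hull containment).
Rotations are counted as unwrapped phase accrual at the node nearest the
trajectory centroid divided by 2π — robust to meander; duration/period
is available as an alternative. Duration and rotation thresholds follow
the clinical RD definition; the confinement radius is a package default
(the clinical criterion is qualitative).

## Virtual ablation

Lesions are the union of 3.5 mm-radius disks around every PS point of
the targeted trajectories, applied instantaneously as non-conductive
tissue (no border zone), matching the "render the trajectory
non-excitable" protocol. The two-round design ablates RDs in
ECGI+/Sim+ regions first, then all Sim+ targets, re-running the full
induction protocol after each round; de-novo RD regions are those absent
pre-ablation. Acute response of a matched pre/post episode pair is
positive on termination (no sustained activity post) or cycle-length
prolongation >10 ms (strict), with CL measured as the ROI median of mean
inter-activation intervals over the final 1 s of each episode — a
package convention, since the clinical CL measurement protocol does not
transfer to a sheet.

## Concordance statistics

Each RD is assigned to the region holding the plurality of its PS
points (ties: latest point's region, then lowest id). Per patient the
seven regions are labeled ECGI±/Sim± by set membership, pooled into a
2×2 table (a, b, c, d). Two chance-corrected agreement coefficients are
always reported side by side: Cohen's κ (chance = product of the two
raters' marginals) and an intraclass κ₀ (raters interchangeable;
chance = p̄² + (1−p̄)² with p̄ the mean positive rate). On the packaged
pooled table (19, 23, 9, 33) they evaluate to 0.238 and 0.216
respectively. The κ₀ = 0.11 printed in the source analysis is not
reproducible from the pooled table by any standard 2×2 formula we
evaluated (Cohen, Scott/intraclass, prevalence-adjusted); the package
therefore reports both computed variants and makes no assertion about
0.11.

Fisher's exact test (two-sided, summing hypergeometric probabilities no
more probable than the observed table) is delegated to scipy and
cross-checked against full enumeration in tests. The Wilcoxon
signed-rank test is implemented in-package because an exact two-sided
p-value with midranked ties and dropped zeros is needed at n ≤ 25:
doubled midranks are integers, so the exact null distribution of the
positive-rank sum is built by integer dynamic programming (equivalent to
enumerating all 2ⁿ sign assignments, verified against that enumeration).
Medians and IQRs use the positional convention h = (n+1)p with linear
interpolation (numpy's "weibull" method) and half-away-from-zero
rounding to one decimal — the convention that reproduces every printed
IQR in the packaged per-stage RD counts. Outcome tabulation works at
the ablation-target level with integer-percent rounding.

## Packaged fixtures

The per-patient agreement counts (12 rows), the region×stage occupancy
of the six virtually ablated models, the pooled 2×2 concordance counts,
the acute-outcome counts (13/23, 9/22, 7/23, 4/22) and the regional
distributions (33/5/4 and 17/9/2) are shipped as CSV files with SHA-256
integrity checks, so every region-level statistic of the comparison is
recomputable in milliseconds without clinical data. `repro_study()`
recomputes them; `repro_study_report()` emits the pass/fail table.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale as
the package's standard demonstration sizes: 120×120 nodes (60×60 mm) for
the cross-field rotor and ablation demonstrations; a 100×100, 30%-burden
virtual patient with 2–3 pacing sites and a 1.5 s free run for the
induction regression; 60×60 with 2 sites for the end-to-end determinism
check; 500-patient ensembles for generator-parameter recovery. Pipeline
defaults (30 sites, 2.5 s free runs) reproduce the full study design and
take tens of minutes per patient on one core. dt defaults: 0.1 ms
(surrogate), 0.02 ms (full backend); halving dt changes single-cell
APD90 by <1 ms.

## What the generator does and does not emulate

The synthetic substrates reproduce the *statistical* structure the
analysis relies on — patchy fibrosis with controllable burden and patch
scale, a fixed region scheme, partial manifestation of latent RDs —
but not patient geometry: no 3D bi-atrial anatomy, wall-thickness
variation, fiber atlas, imaging segmentation, or the ECGI inverse
problem. Ablated-tissue percentages are area fractions of a sheet and
are not numerically comparable to the ablated-volume percentages of 3D
atria. Passing tests therefore demonstrate the correctness and internal
consistency of the algorithms (induction, PS tracking, RD criteria,
ablation accounting, statistics) under controlled conditions, not
patient-level predictive accuracy.

## Known limitations

- The chronic-AF multiplier set and the pacing ramp are conventions
  (config-exposed defaults), not values printed in the source analysis.
- The surrogate's restitution is simpler than the full model's; induction
  rates at a given fibrosis burden are not calibrated to clinical
  inducibility.
- Greedy PS linking can swap identities when two same-chirality tips
  pass within v_max·Δt of each other; region assignment by plurality is
  insensitive to such swaps in practice.
- Wilcoxon p-values fall back to a tie-corrected normal approximation
  above n = 25 paired samples.
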