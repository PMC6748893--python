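# Methods

`clotflow` models clot growth in a 2-D section of a microfluidic channel
(600 µm long, 60 µm high; the 250-µm out-of-plane width enters only in
flux conversions) with a thrombogenic collagen + TF patch centered at
x = 300 µm on the bottom wall.  Four canonical conditions cross the patch
length (20 or 100 µm) with the TF surface density (0.1 or 2
molecules/µm²).  This note records the model, its numerical treatment,
the parameter choices that matter, and what the synthetic data do and do
not establish.

## Flow

Blood is Newtonian (µ = 3.5 mPa·s, ρ = 1060 kg/m³); red-cell effects are
carried by the diffusivity and margination closures, not the rheology.
The steady Stokes–Brinkman problem is discretized on a staggered (MAC)
uniform grid and solved as one sparse saddle-point system by direct LU
with two steps of iterative refinement, which conserves the discrete mass
balance to machine precision.  The inlet imposes the plane-Poiseuille
profile whose wall shear is the 1000 s⁻¹ arterial target (mean velocity
γ̇_w h/6 = 10 mm/s); the outlet pins pressure to zero with zero-gradient
velocity; walls are no-slip.  At these scales Re ≈ 0.2, so the default
solve omits the inertial terms; a Picard-iterated inertial solve is kept
for the creeping-flow consistency check (difference < 10⁻⁵ relative).
The device itself reports both a 20 µL/min total outflow and the
1000 s⁻¹ per-channel shear; the per-channel flow split of the 8-channel
pressure-relief network is not determinable from those numbers, so the
shear target is taken as authoritative.

The Brinkman coefficient is the sum of Kozeny–Carman terms for bound
platelets (grain size 2 µm) and fibrin (fiber scale 0.1 µm), with fibrin
concentration converted to volume fraction at 1.5×10⁻⁴ per 1000 nM.

Quasi-steady coupling: the transport/platelet macro-step is 0.5 s and
the flow (with the shear-dependent diffusivities and the transport
operators that depend on it) is refreshed every 10 macro-steps (5 s
simulated).  The clot's resistance evolves over tens of seconds, so this
cadence is well inside the quasi-steady regime: halving it changes the
100-s platelet total by 0.12% and the (tiny, pre-ignition) thrombin total
by ~2%, at ~45% more cost.

## Species transport

All mobile species (and mobile platelets) are advanced by implicit-Euler
advection–diffusion: flux-form first-order upwind advection with central
diffusion, one sparse factorization per Brownian-diffusivity class
(generic protein 5×10⁻¹¹, fibrinogen 3.1×10⁻¹¹, platelet 1.6×10⁻¹³ m²/s)
re-used between flow refreshes.  The scheme is unconditionally stable,
positivity-preserving (M-matrix), and exactly conservative in a closed
domain; the Gaussian-pulse variance-growth identity 2·D·t holds exactly
for the discrete operator, which the oracle tests exploit.  At large
Courant number in the fast lumen the implicit step relaxes fields toward
the quasi-steady plume balance — the physically relevant limit there,
since lumen residence times (~ms) are far below the 0.5-s step.  Shear
augmentation of every diffusivity uses the red-cell form
k_sh a² γ̇ H (1−H)^0.8 with k_sh = 0.15, a = 2.75 µm, H = 0.4.

Fibrin does not move: it polymerizes where it forms (see below).

## Coagulation chemistry

The reaction table (src/clotflow/data/network.yaml, versioned) is a
TF-pathway network in the Hockin–Mann lineage restricted to the nine core
proteins and their complexes: surface TF binds FVII/FVIIa; TF:VIIa
activates FIX and FX by Michaelis–Menten surface catalysis whose products
enter the wall-adjacent cell; thrombin feedback activates FV, FVIII and
FVII; intrinsic tenase (IXa:VIIIa) and prothrombinase (Xa:Va) assemble
reversibly and drive the explosive phase; TFPI neutralizes Xa and then
quenches TF:VIIa.  Rate constants are standard literature values recorded
in the config file.  Two localization closures matter:

- **Complex assembly requires platelet membrane.**  Tenase and
  prothrombinase assembly rates scale with min(1, φ_b/0.01).  Without
  procoagulant surface there is no propagation phase in the lumen; this
  is what makes thrombin output a strongly superlinear function of total
  TF and yields the large synergy between surface length and TF density.
- **Fibrin anchors to the platelet aggregate.**  Fibrin deposition ramps
  from zero at φ_b = 0.03 (the shell threshold) to full rate at 0.12.
  The nine-protein network contains no antithrombin, so thrombin that
  escapes downstream is not neutralized; without anchoring it would paint
  a fibrin wake far outside the platelet domain, contradicting the
  observed architecture in which the platelet shell fully surrounds the
  fibrin core.  Physically, fibrin that polymerizes without a scaffold is
  washed out; the un-anchored soluble fraction is not tracked.

Reactions are integrated per macro-step by vectorized classical RK4
(sub-step 0.025 s) restricted to cells that can have nonzero rates
(any active enzyme > 10⁻⁹ nM, bound platelets, or the thrombogenic wall
cells); the surface ODEs advance alongside with explicit Euler at the
same sub-step.  The integrator matches an independent LSODA solution of
the same table to < 0.5% on closed-cell trajectories.  Plasma baselines
(FII 1400, FX 170, FIX 90, FVII 10 (1% VIIa), FVIII 0.7, FV 20,
fibrinogen 9000, TFPI 2.5 nM) represent an average healthy subject.

## Platelets

Four phenotypes: mobile/bound × resting/activated.  Mobile fields are
number concentrations (baseline 250,000/µL) transported with the blood;
bound fields are immobile volume fractions capped at φ_max = 0.6.  Count
and volume interconvert through an 11-fL platelet volume.

- **Margination.**  The red-cell-induced near-wall excess is imposed as
  an equilibrium enhancement profile (wall/bulk ratio 3 within 5 µm of
  either wall, channel mean 1); each macro-step the mobile fields are
  multiplicatively reweighted toward it column by column, conserving
  every column total exactly and reducing to the identity for a uniform
  profile.
- **Capture.**  Collagen faces capture near-wall mobile platelets with a
  capture velocity of 2 µm/s × the single ×4 arterial calibration
  multiplier (standing in for vWF-mediated capture at high shear — the
  one deliberately calibrated parameter of the underlying model).
  Cells adjacent to activated bound platelets (φ_ba > 0.02) capture at
  3 µm/s (activated platelets) and 45% of that for resting ones; capture
  saturates as (1 − φ/φ_max) with internal sub-stepping so φ never
  overshoots.  The resting/activated contrast is what lets
  thrombin-driven activation raise the long/high clot above the others.
- **Activation.**  Thrombin activates mobile and bound platelets with a
  Hill rate (EC50 1 nM, n = 1, 0.5 s⁻¹ at saturation); bound platelets
  also activate at an autocrine 0.025 s⁻¹ (0.05 s⁻¹ extra on collagen).
  The ~40-s bound-activation lag, together with the capture velocities,
  sets the ~0.04–0.05 µm/s vertical growth of the deposit front and hence
  the 17–20 µm 400-s heights; these were fixed once against the observed
  height scale (the model's only other free kinetic scale besides the ×4
  multiplier) and then left alone.
- No shedding/embolization term: deposits grow monotonically.

## Core/shell analyses

The core is the largest connected 1-nM superlevel component of fibrin;
the shell is the 5%-of-φ_max superlevel of bound platelets (a fixed,
reproducible stand-in for boundary determination by eye).  Contours come
from marching squares at cell resolution, mirrored below the wall so they
close on y = 0; satellites are dropped by the largest-component rule.
Because simulated fibrin spans ~6 decades, its level set sits essentially
one cell above the last fibrin-bearing cell, so extracted cores can
exceed extracted shells by up to one cell; nesting of simulated fields is
therefore a cell-resolution statement, and the core/shell height and
length ratios used for embedding are capped at 1.  Embedding into a
measured shell preserves those ratios and the core's relative downstream
offset (the centering convention is not pinned down by the source
description; preserved-offset is assumed).  Flow through measured shapes
assigns the spatially averaged simulated core and shell resistances as
piecewise constants and re-solves the same Stokes–Brinkman problem.  The
"low-velocity region" is the set of cells with axial speed below 10% of
the lumen mean; the thin no-slip layer qualifies everywhere (as it does
physically), so the informative metrics are the layer's thickness at the
clot center versus far upstream.

## Measurement pipeline and statistics

Profile edges are the outermost sustained crossings (≥ 5 consecutive
samples) of 10% of the profile maximum — the run-length requirement keeps
isolated noise spikes from masquerading as edges; centers (edge
midpoints) are shifted to 300 µm with linear resampling on a 1-µm grid.
Spurious-profile rejection uses two translation-invariant rules, each
logged: supra-threshold signal outside the main contiguous region
exceeding 20% of the total (only supra-threshold signal counts, so the
noise floor over the long empty stretch cannot trigger it), or a
secondary peak above 50% of the main one at > 100 µm separation.
Comparisons route on Jarque–Bera normality of both samples (χ²₂
reference; anticonservative at small n, which only pushes the routing
toward the rank-sum branch), then an unpaired two-sided t test or
Wilcoxon–Mann–Whitney (exact null when min(n) ≤ 8 without ties, else the
tie-corrected normal approximation), with Bonferroni adjustment across
the comparison family.

## Synthetic data

The generator emulates the study design: 5 donors × 4 repetitions per
condition; squared-cosine deposition bumps (support = surface length +
120 µm) centered at 300 µm with N(0, 25 µm) frame jitter; event peak
heights = condition mean (7.5 µm short/low; 13–16 µm otherwise) × a
shared lognormal donor multiplier (CV 25%) × N(1, 0.3) event scatter,
growing linearly in time; additive N(0, 0.4 µm) noise clipped at zero;
10% of events carry a spurious secondary bump.  Kinetics are saturating
curves (τ = 150 s) sampled every 50 s to 450 s whose plateaus encode the
observed ordering, including a 20× thrombin/fibrin plateau ratio between
long/high and short/low.  Profiles are generated in height-equivalent
µm so they compare directly to simulated deposition domains.

What passing tests show: the processing chain recovers known centers,
heights and spurious labels from data with this statistical structure,
and the statistical machinery is calibrated on it.  What they do not
show: robustness to raw-image artifacts (background drift, segmentation
errors), non-Gaussian frame jitter, or donor effects beyond a shared
multiplicative factor.  Pooling donors × repetitions ignores the donor
design effect by construction (as the assay's analysis does); the
type-I-calibration tests therefore run with the donor component disabled.

## Numerical choices and limitations

Desk-scale default grid dx = dy = 2 µm (300 × 30 cells); the simulations
behind the reported numbers use this grid to 450 s, ~2.5–3 min per
condition on one CPU.  A 1-µm preset exists for overnight runs.  Known
limitations: 2-D geometry; no clot viscoelasticity or embolization; no
contact pathway (the assay inhibits it with CTI); single-phase Newtonian
blood; fibrin represented as immobile concentration rather than polymer
microstructure; margination imposed as an equilibrium profile rather
than a drift flux.  The single-factor TF-density effect is much larger in
this reduced network than the combined-versus-baseline contrast reported
for the measured system — threshold behavior of the propagation phase is
sharper without the plasma inhibitors omitted from the nine-protein
scope — but the headline synergy and height structure are reproduced.
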