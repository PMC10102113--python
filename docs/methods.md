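# Methods

This note documents the models, parameter choices and numerical decisions
behind `ablsim`, and what the desk-scale setup can and cannot show.

## Geometry

The left atrium is an ellipsoidal shell (semi-axis ratios 1 : 0.9 : 0.8,
default mean radius 20 mm, wall thickness 4.5 mm — the thick-walled end of
atrial anatomy) built from an icosphere subdivided to the requested
resolution and extruded into at least two transmural element layers.
Openings are cut for the mitral annulus and four pulmonary-vein ostia
(angular radius 0.24 rad); an appendage bulge and landmark sets (ostium
rings, annulus ring, appendage, roof, Bachmann-bundle and posterior/
coronary-sinus entry sites on the septal aspect) provide the anatomical
hooks the lesion rules and stimulation protocol need. A seeded tangential
jitter makes distinct, reproducible fixtures. The mechanics mesh is the
prism-split shell; the EP mesh is its uniform 1:8 refinement, so the
parent map is exact and lesion masks cover identical tissue fractions on
both meshes.

Fibers are circumferential with a roof-to-annulus rotation gradient
(0–40°), the sheet axis in-plane and the normal axis transmural. The
ventricular slab rule interpolates the fiber angle +60°→−60° and the
sheet angle −65°→+25° across the wall. These simplified rules keep the
qualitative anisotropy of rule-based atrial/ventricular fiber fields
without their anatomical machinery.

## Lesions

Lesion paths are great-circle geodesics between landmark directions on
the shell midsurface, dilated to a 5 mm average width and applied to
whole transmural columns (hence exactly transmural). PVI is the closed
band around each ostium; BL is the union of the roof line and an
inferior posterior line, so BL ⊇ RL holds by construction. EP masks map
to the mechanics mesh by volume-majority vote over refinement children.
A per-lesion width-scaling dictionary is exposed for calibration; the
defaults are uncalibrated 5 mm widths, which on this small shell produce
larger ablated fractions (≈22–30%) than a full-size atrium — orderings
and correlations, not absolute fractions, are the meaningful outputs.

## Electrophysiology

The atrial membrane model is the full Courtemanche–Ramirez–Nattel
formulation with the original parameter values; it was validated against
resting-state stability (‖dy/dt‖ < 10⁻² at the published rest state), AP
morphology (peak ≈ +22 mV) and APD90 ≈ 303–309 ms at a 1.2 s cycle
length. The ventricular surrogate is a Mitchell–Schaeffer-type
two-variable model rescaled to physical voltage (rest −85 mV, peak
+36 mV) with τ_close = 175 ms so its APD (~330 ms) exceeds the atrial
model's, as ventricular myocytes' should. Single-cell pacing uses an
adaptive stiff integrator (LSODA); tissue uses forward-Euler voltage and
exact exponential (Rush–Larsen) gate updates at Δt = 10 µs.

The monodomain equation is discretized with linear tetrahedra, lumped
mass and homogeneous Neumann boundaries; first-order operator splitting
advances reaction explicitly and diffusion implicitly (backward Euler,
one sparse LU factorization reused every step; backward Euler is chosen
because the first-order splitting makes anything higher-order moot).
β = 140 mm⁻¹ and Cₘ = 0.01 µF/mm² are declared defaults — only their
product enters, and conductivity tuning absorbs it.

Activation maps sample Vₘ at 1 ms cadence and interpolate the first
upward −20 mV crossing linearly; sub-millisecond accuracy is unnecessary
for 100 ms-scale maps. An element is inactive if at least half its
vertices never cross threshold, or if it is scar; this makes IT ⊇ AT
structural. Conduction velocity is the least-squares slope of coordinate
vs activation time over the central 60% of a planar-wave fixture, and
conductivity tuning exploits CV ∝ √σ for a fast fixed-point iteration
(converges in 2–4 solves to within 2% of target).

Two discretization facts matter for interpretation. First, conductivity
values are tuning outputs at the working resolution, not portable
constants: at the shell's ~2.6 mm EP edge length the discrete CV of the
stiff atrial upstroke is strongly mesh-limited, so the atrial σ_f = 1.1
S/m default is the value that calibrates the control total atrial
activation to ≈100 ms on this mesh (measured: 104 ms). Second, the
fast endocardial layer is implemented as a 4× conductivity multiplier
(doubling the intrinsic CV exactly, as the strand tests show); in a thin
coupled wall the measured surface speed-up is smaller (~1.6×) because the
bulk loads the layer.

Sinus activation of the LA-only shell enters through four sites with
fixed onsets (Bachmann 29 ms; two septal posterior connections 36/42 ms;
coronary-sinus region 65 ms), mimicking the normal right-to-left
breakthrough sequence. Ventricular tissue, when simulated, is stimulated
160 ms after the atria (AV delay) at root sites with δ_rad = 3 mm and
δ_m = 0.05 extents.

## Mechanics

Myocardium uses the orthotropic exponential strain energy
Ψ = μ/2(e^{αQ}−1) + κ/2(log J)², Q = Σ b_ij E_ij² in the fiber frame,
with μ = 325.56 Pa, α = 22, κ = 10⁶ Pa, ρ₀ = 1082 kg/m³ and
b = (1, 0.4, 0.3, 0.7, 0.6, 0.2). Scar keeps the form but sets
b_ff = b_ss = b_nn = 1, b_fs = b_fn = b_ns = 0.5 (isotropized), μ → 2μ
(651.12 Pa) and α → 5α (110); vessels, valve plugs and the pericardial
layer are Neo-Hookean. Stress and the consistent material tangent are
analytic (verified against finite differences of Ψ to ~10⁻¹⁰ relative).

The FEM is total-Lagrangian with linear tetrahedra and one-point
quadrature. Loads: follower pressure on the endocardium (with analytic
load stiffness), nodal boundary springs on the mitral annulus ring
(0.05 N/mm — the desk-scale stand-in for the annulus' attachment to the
ventricle), zero displacement at the PV ostium rings (vein truncations),
and optionally a penalty tether to an analytic pericardium-like sphere
through the piecewise gap (quadratic below d = 0.1 mm, linear to
d_M = 8 mm, zero beyond; k_epi = 10 MPa/mm). Cavity volumes close the
endocardial surface with centroid fans over each opening ring (the fans
follow the deforming rings; openings that pinch at a vertex merge loops,
which still caps every boundary edge exactly once).

Dynamics: Newmark with β = 0.3, γ = 0.6, Δt = 1 ms and Rayleigh damping
D = α₁M + α₂K₀ (α₁ = 500 s⁻¹, α₂ = 0.005 s) built from the tangent
stiffness frozen at the reference state, which keeps D constant. The
"K u" term is assembled as the nonlinear internal force. Newton uses the
analytic tangent, relative tolerance 10⁻⁸, at most 25 iterations, with a
halving line search guarding element inversion; the active-stress
tangent neglects the dS_A/dλ length-dependence term (extra Newton
iterations absorb it). The Newmark update formulas are validated against
the closed-form damped oscillator (second-order convergence), numerical
dissipation for γ > 0.5, and discrete energy conservation at
β = 1/4, γ = 1/2.

Unloading is the backward-displacement fixed point
X ← X − 0.9(X + u(X; p) − X_img), stopped when re-inflation reproduces
the imaged geometry within 0.1 mm; the same unloaded configuration is
meant to be reused across lesion cases. Near-incompressibility holds to
|J − 1| < 0.05 away from the artificially pinned rings; elements touching
the idealized Dirichlet rings concentrate up to |J − 1| ≈ 0.07, a fixture
artifact of pinning a coarse shell, not a material property.

Internal units are mm/ms/g (stress in MPa); 1 mmHg = 133.322 Pa.

## Active tension

S_A = S_peak φ(λ) tanh²(t_s/τ_c) tanh²((t_dur − t_s)/τ_r) on
0 < t_s < t_dur, t_s = t − t_A − t_emd, φ(λ) = max(tanh(ld(λ − λ₀)), 0),
τ_c = τ_c0 + ld_up(1 − φ). The parameter values are declared
implementation defaults (ventricle: S_peak 60 kPa, t_dur 400 ms,
τ_c0 80 ms, τ_r 70 ms, ld 5, ld_up 500 ms, λ₀ 0.7, t_emd 20 ms; atrium:
30 kPa, 140 ms, 40 ms, 40 ms, ld_up 300 ms). The atrial duration is
chosen so an atrial twitch started at activation time 0 has fully decayed
before ventricular tension onset at the 160 ms AV delay plus t_emd —
atrial and ventricular tension do not overlap under sinus timing. Scar
never reaches the voltage threshold, so t_A is undefined there and no
tension develops. Activation weights default to n_f = 1, n_s = n_n = 0.

## Circulation and the lumped lesion coupling

The 0D loop has four RC compartments and four elastance chambers whose
normalized drive reuses the tension twitch shape at λ = 1. All
compartment and valve parameters are implementation defaults tuned once
so the control case is physiologically plausible (LA 47.7–68.4 mL,
atrial EF 30.2%, LV SV ≈ 60 mL); they are not published values. States
are volumes, every flow enters two derivatives with opposite signs, and
RK4 at 1–2 ms steps conserves total blood volume to round-off. Valves
are smooth resistors (logistic opening fraction over 0.3 mmHg). The
stopping criterion integrates Q_SysArt − Q_PulArt, compares |SV_diff|
with 1 mL at cycle boundaries and resets it when unmet (the integral is
signed within a cycle; the absolute value applies only at the check).

For the ten-case experiments the LA chamber is informed by the EP stage:
its contractile elastance scales with the active-tissue fraction
(1 − IT/100), its onset shifts by the volume-weighted mean activation
delay vs control, and its passive elastance stiffens with the scar
burden (gain 0.6 per unit ablated fraction, scaled by the
scar-stiffness sensitivity knob whose reference is the 2μ/5α scar).
This lumped route is the default because no acceptance-level quantity
requires a full 3D beat: the 3D FEM path is exercised through the
quasi-static EDPVR (stiff scars reduce the inflated LA volume at 8 mmHg,
matching the expected direction), the unloading round trip, and the
3D–0D coupling operator, which sub-iterates the static FEM chamber until
|V³ᴰ(p) − V⁰ᴰ(p)| < 10⁻⁷ mL.

## Desk-scale problem sizes

Default test/analysis sizes, chosen as this package's working scale: the
shell's mechanics mesh has ≈1.5 k tetrahedra (EP ≈12 k, ≈2.6 k nodes);
the ten-case sweep uses 50 µs EP steps and unpaced initial states, which
reproduce the 10 µs paced results to within a millisecond of activation
time; CV tuning fixtures run the full 10 µs production step. Single-cell
pre-pacing defaults to 1000 beats in the protocol object; the pipeline
default is 2 beats, since tissue-level conclusions here are insensitive
to the slow concentration drift.

## What the synthetic setup does and does not show

The generator emulates the topological and biophysical features the
lesion analysis needs: a thin anisotropic atrial wall with realistic
entry sites, closed PVI rings, an isolable posterior box, an appendage
whose anterior route the AL blocks. It does not emulate patient anatomy:
absolute volumes (the shell holds ~15 mL at 8 mmHg), ablated fractions,
AVPD magnitudes and pressures are not comparable to a full-size
four-chamber heart, and fibrotic conduction heterogeneity, adipose
tissue and mechanoelectric feedback are absent. Passing tests therefore
demonstrate the directional and correlational claims — IT ≥ AT with
strict excess for box lesions, EF loss increasing essentially linearly
with inactive tissue (Spearman ρ ≥ 0.9 on the simulated sweep), delayed
appendage activation under AL, volume loss under scar stiffening, CV
∝ √σ — and exact reproduction of the published table's statistics, not
patient-level absolute biomarkers.

## Known limitations

- Linear tetrahedra lock in thin bending-dominated walls; the coarse
  shell overestimates stiffness and the |J − 1| tolerance excludes
  pinned-ring elements.
- The lumped LA-lesion coupling linearizes mechanics into three scalars
  (active fraction, delay, stiffening); regional dyssynchrony within the
  atrium is not represented in the hemodynamic stage.
- The ventricular surrogate has no calcium dynamics; restitution is
  gate-recovery driven.
- Circulation parameters are plausible defaults, not fitted values; only
  relative case-to-case changes are meaningful.
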