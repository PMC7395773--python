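# Methods

## Governing equations

The tissue model is the monodomain equation ∂V_m/∂t = ∇·(D∇V_m) + I_ion
with homogeneous Neumann (no-flux) boundaries, the standard reduction of
the bidomain model under equal anisotropy ratios. The conductivity tensor
is transversely isotropic about the local fiber direction f(x) and scaled
by the healthy-volume fraction h(x):

    D = h(x) [ d⊥ I + (d∥ − d⊥) f f^T ]

with defaults d∥ = 0.1 mm²/ms and d⊥ = 0.025 mm²/ms (anisotropy ratio 4,
within the physiological 4–9 range). h = 0 marks non-conductive infarct
core, intermediate h the peri-infarct gray zone. h scales conductivity
only; ionic parameters are not blended across the gray zone — partial
electrical uncoupling is the one gray-zone mechanism the model commits to,
since it is the only one the conductivity law itself defines.

Gel injectates are passive: their elements carry no reaction term and an
isotropic tensor c·d⊥·I, where c is the gel-to-tissue conductivity ratio.
For c = 0 the gel elements are removed from the assembled operators, which
realizes the no-flux interface exactly; for c > 0 the gel is folded into
the single global diffusion solve. A separate steady Laplace solve on the
gel submesh (`solve_gel_potential`) exists to verify the passive-conductor
behavior in isolation; folding the gel into the parabolic operator and
solving the gel Laplace problem separately agree in the limits exercised
here, so the cheaper folded treatment is the production path.

## Ionic model

Cells follow the ten Tusscher–Panfilov 2006 (TP06) human ventricular
formulation: I_Na, I_K1, I_to, I_Kr, I_Ks, I_CaL, I_NaCa, I_NaK, I_pCa,
I_pK, I_bCa, I_bNa; calcium handling with a diadic subspace (Ca_ss), SR
compartment (Ca_SR), rapid buffering, and the R̄ ryanodine-release
adaptation variable. Endo/mid/epi variants differ in G_Ks, G_to and the
s-gate kinetics. Two parameter modes exist:

- `restitution`: the published layer-specific conductances;
- `VF`: the steep-restitution overrides used for fibrillation studies
  (G_Kr = 0.172; G_Ks = 0.0515 mid, 0.2205 endo/epi; G_pCa = 1.8545;
  G_pK = 0.00073 nS/pF; f-gate time constant doubled). The overrides are
  applied only in VF mode; restitution-protocol runs use the published
  sets unmodified.

One printed initial-condition entry for the d gate (3.373×10⁵) is
physically impossible for a gate confined to [0,1]; it is read as
3.373×10⁻⁵, the order of the published TP06 resting value. The correction
is flagged in the code rather than silently absorbed.

The stimulus is a square pulse in current density over capacitance
(mV/ms), added directly to dV_m/dt; the default strength is 40 mV/ms for
2 ms.

## Discretization

Space: linear (P1) simplicial finite elements — segments, triangles, or
tetrahedra — with the symmetric stiffness form K_ij = Σ_e |e| ∇N_i·D_e∇N_j,
so no-flux boundaries need no surface terms and ∫V dΩ is conserved exactly
by the diffusion sub-step (asserted in the tests to solver tolerance).

Time: first-order operator splitting, reaction then diffusion, at
dt = 0.1 ms. The reaction sub-step uses the hybrid Rush–Larsen scheme
(exponential update for the 12 gates and R̄, forward Euler for V and the
five concentrations). The diffusion sub-step is a θ-scheme with the
consistent mass matrix (θ = 0.5, Crank–Nicolson, by default; θ = 1 gives
backward Euler), factorized once per run; a lumped-mass forward-Euler
path (`diffusion_solver="explicit"`) exists for speed, with a CFL guard.

The ionic state lives, by default, at element quadrature points (one
centroid point per element): nodal V is interpolated to the centroid, the
reaction step advances the quadrature state, and the voltage increment is
projected back through the mass matrix. A nodal placement
(`reaction="nodal"`) is available and is what the cheaper fixtures use.

### Why quadrature-point reaction, and what "0.8 mm" means

Coarse P1 meshes distort conduction velocity (CV) in scheme-dependent
ways: nodal (interpolated-current) reaction underestimates CV as the mesh
coarsens and blocks outright near 1.6 mm, while quadrature-point reaction
overestimates it. For this model the mesh-converged planar CV at
d∥ = 0.1 mm²/ms is ≈ 0.63–0.64 mm/ms. On a thin bar of structured
tetrahedra with characteristic element size 0.8 mm — element size meaning
the tet diameter, i.e. a lattice pitch of 0.8/√3 ≈ 0.46 mm — the default
scheme (quadrature reaction + Crank–Nicolson) gives 0.67 mm/ms at normal
pacing, which is the physiological target value for this conductivity and
the configuration the conduction-velocity acceptance check runs. Halving
the element size moves CV by ≈ 9% toward the converged value at this
baseline; near-converged fixtures (0.2–0.4 mm nodal cables) change by
< 5% under refinement and are the ones used for the scaling properties
(CV ∝ √conductivity, anisotropic CV ratio √(d∥/d⊥) = 2), which hold
within 10% only once both propagation directions are resolved.

Divergence guard: |V_m| > 500 mV aborts with a diagnostic. Linear solves
use a factorized direct method (relative residual well below 1e−8).

## Synthetic geometries

The generator replaces image-derived anatomy with parametric fixtures:

- cable / sheet / slab at a given spacing (fibers along +x, h = 1);
- an idealized biventricle: truncated thick-walled LV ellipsoid
  (default outer semi-axes 16×16×26 mm, 6 mm wall) with a fused
  thinner-walled (3 mm) partial RV shell, meshed by masking a structured
  lattice into tetrahedra. Rule-based fibers rotate linearly across the
  wall from −60° (endo) to +60° (epi) in the local
  circumferential–longitudinal frame — the community-standard stand-in
  when no diffusion-tensor data exist. The default dimensions are a
  desk-scale miniature; the construction is scale-free.

Transmural layers come from a Laplace solve (0 on endocardium, 1 on
epicardium) thresholded at 3/8 and 6/8, giving epi:mid:endo = 2:3:3 —
epi is the outer 2/8 per the stated layer order. The LV mid-myocardial
analysis surface (LVMM) is the set of interior faces crossed by the
mid-layer's central level set (φ = 0.5625), restricted to the LV wall.

Infarcts: h = 0 inside a core geometry, rising linearly with signed
distance to 1 over a configurable gray-zone width (the ramp shape is a
free choice; linear is the least-informative default). The gray-zone
width is exposed as a parameter because plausible gray-zone area ratios
constrain it only loosely.

Gel injections emulate the clinical delivery protocol: 12–14 (default 13)
injections of 0.3 mL each, in two circumferential rows ≈ 15 mm apart in
the LV free-wall mid-layer, each solidifying into an ellipsoid with its
long axis along the local fiber direction (default 2:1 aspect). Placement
jitter sits behind a single seed recorded in outputs. On the miniature
biventricle the per-injection volume is scaled so the gel occupies ≈ 3%
of the conductive volume, the fraction the full-size protocol produces.
The gray-zone ratio (GZR) of an analysis surface is the area fraction of
its simplices with 0 < h < 1.

## Protocols

Dynamic restitution: repeated stimulation at a site (apex on anatomical
meshes) through a monotone non-increasing cycle-length schedule. The
default schedule holds 4 beats at each of 8 geometrically spaced CLs from
1000 ms down to 350 ms (32 beats; the per-beat CL sequence is fully
configurable since only the endpoints are constrained by the study design
it emulates). Per beat and node, APD is paired with the preceding CL and
DI = CL − previous APD; CL = APD + DI holds exactly on the recorded
samples. Conduction block is recorded as missing data, never as zero.

S1–S2 induction: a conditioning S1 and a premature cross-field S2 near
the repolarization tail of the S1 wave (`locate_wave_tail` finds nodes
that repolarized within a configurable lag). Outcomes are classified from
post-S2 activity: `no reentry` (activity extinct within ~one AP duration
of S2), `transient reentry`, and `sustained VF` (activity beyond 2000 ms
after S2, the sustained criterion). The vulnerable-window scan returns
both the set of coupling intervals that sustain reentry and its extent,
since a single number cannot distinguish a window location from a width.

The desk-scale induction fixture is a 160×160 mm sheet of VF-mode
epicardial cells at 1.2 mm spacing with isotropic d = 0.1 mm²/ms (nodal
reaction). Isotropy and the coarse pitch keep the reentrant wavelength
inside the domain at a tractable node count; S2 = 220 mV/ms (5.5× S1)
over a 70×70 mm corner block produces wavebreak, and coupling intervals
around 455–465 ms (inside the fixture's vulnerable window) yield
multi-wavelet reentry sustained beyond 2 s, while later ones (475 ms+)
self-terminate — the expected window structure.

## Arrhythmia metrics

AT/RT/APD: activation is the upward crossing of −70 mV; repolarization
defaults to APD90 (recovery through V_rest + 0.1·(V_peak − V_rest), with
V_rest the pre-upstroke value of that beat) with a fixed-voltage rule
available, since the repolarization fraction is a convention rather than
a measurement. Crossings are linearly interpolated between samples taken
at the analysis cadence dt* = 5·dt on a configurable node subset,
accumulated online during the run so full-resolution storage is never
needed.

Restitution distributions: Gaussian KDE (Scott's rule bandwidth,
recorded) over APD samples at fixed CL per region, with sample median,
standard deviation and mode count (KDE local maxima; > 1 flags
bimodality).

Filaments: a phase singularity is the intersection of the −70 mV
isopotential line with the dV_m/dt = 0 waveback. Per element straddling
the isopotential, dV/dt is linearly interpolated onto the points where
the element's edges cross the isoline; the element is singular when
those on-isoline rates bracket zero within ±0.1 mV/ms. Interpolating
onto the isoline matters on coarse meshes: a raw nodal sign-change test
flags every wavefront element, because one element can hold both a
quiescent node and an upstroke node (and, at ≥ 1 mm spacing, the phase-1
notch behind the peak). On the isoline itself a front is crossed while
depolarizing and a back while repolarizing, so plane waves stay clean
and only true front–back junctions pass through zero; this is validated
on analytic rotating-spiral and planar phantoms and on simulated planar
controls. Singular-element centroids are clustered with DBSCAN
(eps = 2× the characteristic element size, min_points = 1 so a
single-element filament counts); each cluster is one filament. Counts
are taken every 10 ms and time-averaged after a burn-in (default
2500 ms, the time VF complexity takes to stabilize). With min_points = 1
the count provably equals the eps-ball connected-component count, which
the tests assert against a graph oracle.

Pseudo-ECG: V_e = −∫ ∇V_m·∇(1/ρ) dΩ with ρ the distance to an electrode
placed outside the tissue (2 cm off the wall by convention), evaluated
per element from the P1 gradient with centroid quadrature of the
lead-field kernel; the quadrature error scales as (element/distance)²
and the tests check a single element against dense quadrature. The
fundamental frequency is the dominant peak of a Hann-tapered periodogram
above a 0.5 Hz DC-exclusion floor.

## What the synthetic data do and do not show

The generator reproduces the *structural motifs* of the study system —
transmural layering, fiber rotation, infarct core with a gray-zone ramp,
clinically patterned gel inclusions — on idealized shapes at desk-scale
resolution. It does not reproduce subject-specific wall geometry,
DT-MRI fiber fields, image-derived h(x) textures, or full-heart size;
quantities that depend on those (absolute filament counts during VF,
vulnerable-window locations, whole-heart ECG morphology) are therefore
exercised as mechanisms and invariants, not as reproductions of any
particular heart. Passing tests show the solver, protocols and metrics
are correct at the scales run here, not that a specific animal's VF
statistics would be recovered.

## Numerical choices and degenerate inputs

- dt = 0.1 ms default; single-cell APD changes < 2 ms when dt is refined
  to 0.02 ms.
- Rush–Larsen time constants are floored at 1e−12 ms so that wildly
  divergent states reach the |V| > 500 mV guard instead of crashing.
- Snapshot and analysis cadences must be positive multiples of dt;
  violations are rejected at configuration time.
- Empty gel masks, empty scans, zero-area surfaces, non-unit or missing
  fibers on conductive tissue, and overlapping endo/epi boundary sets
  are all rejected with named errors.
- Elements straddling an infarct boundary average h over their nodes, so
  tissue within one element of the core boundary remains weakly coupled;
  "interior" in tests means more than one element inside.
- All placement randomness flows from a single integer seed; identical
  seed and pattern give byte-identical gel flags.

## Known limitations

- First-order (Godunov) splitting and centroid quadrature bound accuracy;
  no Strang splitting in the default path.
- The biventricle is lattice-masked, so its boundary is watertight but
  locally non-manifold at isolated lattice edges; surface areas and GZR
  are unaffected, but surface-mesh consumers expecting strict manifolds
  should re-mesh.
- Gray-zone electrophysiology is conduction-only (no ionic remodeling).
- Filament identity is per-instant; no tracking of filament lifetimes or
  genealogy across instants.
- The phase singularity detector is the isopotential/waveback
  intersection method; Hilbert-transform phase mapping is out of scope.
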