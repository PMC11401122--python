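# Methods

## Model

The macular tissue is an axisymmetric, rigid-skeleton porous medium in
cylindrical coordinates (r, z), RPE at z = 0, ILM at z = h(r), symmetry
axis through the foveal centre and a far rim at r = L = 8 mm where nothing
macular is felt and zero-flux conditions apply. Edema develops over weeks,
so both transport problems are solved in steady state; water is
incompressible and albumin is the single osmotically active solute
(Van't Hoff, Π = RTc, valid at the dilute interstitial concentrations
≤ 0.5 mol/m³ involved here).

Water: Darcy flow `u = −K∇p` with `∇·(K∇p) + q = 0`. Albumin:
`∇·(uc) − ∇·(D∇c) − q_a = 0` with free-solution diffusivity
D = 6.1e-11 m²/s (no hindrance factor; a limitation, see below).

Membranes (n = outward normal, flux positive out of the tissue):

* RPE: `u·n = Γ_RPE[(p − p_c) − σ(Π − Π_c)] + Q_RPE`, and zero total
  albumin flux (tight junctions). Q_RPE = 1e-8 m/s is the active pump.
* ILM: `u·n = Γ_ILM[(p − p_v) − σ(Π − Π_v)]` and the Kedem–Katchalsky
  solute flux `ωRT(c − c_v) + ½(c + c_v)(1 − σ)u·n`. With the default
  σ = 1 the convective solute term vanishes and albumin can leave only by
  diffusive permeation, ωRT ≈ 5.1e-8 m/s.

Both Starling conditions evaluate Π on the tissue side of the membrane
(the reservoir osmotic pressures Π_c, Π_v are fixed by c_c = 0.053 and
c_v = 0.011 mol/m³). Choroidal and vitreal hydrostatic pressures are the
zero reference, so every pressure printed is a departure from them.

### Conductivity map

Hydraulic conductivity is controlled by the Müller-cell architecture.
Radially: foveola (r < L_f = 0.17 mm, density 500 cells/mm², straight
cells) gets C_f = 1e-9 m²/s/Pa; fovea (to L_1 = 0.75 mm, 10,000 /mm²,
straight) gets the straight-cell parafoveal value K1 — the published map
does not pin this ring, and K1 is the conservative choice, exposed as
`K_fovea`; parafovea (27,000 /mm²) is three equal layers with
K1 = K3 = ratio·K2. At every ratio the series composite
`[(d/K1)+(d/K2)+(d/K3)]⁻¹` is held exactly at Γ_ret = 2.54e-10 m/s/Pa, so
the ratio redistributes resistance without changing the column total; the
default ratio 60 comes from the homogenization analysis below.

All region/layer steps are smoothed with a compact-support half-cosine ramp
(C1, exactly 0/1 outside a half-width w): w = 50 µm radially, h₀/30
axially. Axial blending interpolates resistivity 1/K, so the
through-thickness composite is preserved through the transitions (verified
to 0.1%); radial blending interpolates log K between values 2–3 decades
apart. Layer interfaces sit at fixed fractions of the local thickness and
follow the deformed profile.

### Exudation source

BRB impairment is a distributed leak in the ring L_e1 = 1.33 mm to
L_e2 = 1.83 mm (the inner ETDRS ring, where the capillary plexus sits),
confined to the inner third of the thickness:
`q = A_f(p_a − p)(h₀/h)F_r(r)F_z(z)`, `q_a = a·q` with a = 0.5 mol/m³
(just under the plasma albumin concentration 0.53 — exuding plasma-like
filtrate). The h₀/h factor makes the leak rate independent of the tissue
deformation. A_f = 1.15e-4 with p_a = 25 mm Hg.

**Unit convention for A_f.** Interpreting A_f as 1/(s·Pa) makes the ring
inflow ≈ 2e-10 m³/s, two orders of magnitude beyond the combined RPE/ILM
drainage capacity of the whole 8-mm domain (≈ 2e-12 m³/s) — the tissue
pressure would have to climb toward the full capillary pressure.
Interpreting it as 1/(s·mm Hg) gives an inflow of 1.5e-12 m³/s,
commensurate with drainage, and that is the default
(`numerics.af_convention = "mmHg"`, i.e. the internal SI amplitude is
A_f/133.322); `"si"` selects the literal reading. Even under the default,
the steady albumin budget is demanding: with σ = 1 everything leaked must
leave by ILM permeation, so the domain-integrated ILM excess concentration
equals (a·A_f·(p_a−p)·V_ring)/(ωRT) regardless of how it spreads, and the
simulated pathological state settles at peak concentrations near
0.35 mol/m³ and excess pressures near 6 mm Hg. Both scale close to
linearly with A_f (the amplitude sweep computes this), so `A_f` — exposed
in `[parameters]` — is the single knob for matching a given clinical
severity; the packaged default keeps the published amplitude under the
audited unit reading rather than re-fitting it.

### Deformation closure

The parenchyma responds to the *excess* of the depth-averaged pressure
over the converged physiological reference, Δp(r) ≥ 0 (clipped; the
reference state is the unloaded configuration). Müller cells act as a bed
of independent axial springs — a Winkler foundation — with areal stiffness
k(r) = β·n(r)·κ_c, where κ_c = Eπd_c²/4 ≈ 4.9e-9 N is the single-cell
axial stiffness (E = 0.25 kPa, d_c = 5 µm) and n(r) the density profile;
the strain is ε = Δp/k and h = h₀(1+ε). β is the one calibrated constant:
it is chosen once, at the baseline amplitude, so that the most compliant
column doubles its thickness (max h/h₀ ≈ 2, the clinically motivated
anchor); with the default configuration β ≈ 277. Because the 54× density
contrast between parafovea and foveola carries through to stiffness, the
thickening localizes at r = 0 even though Δp peaks at the exudation ring —
the mechanism the model exists to exhibit. The closure lives behind
`thickness_update` so a nonlinear spring could replace it; depth-averaging
can be switched to mid-depth sampling (`numerics.depth_average`).

The fluid–structure loop: solve transport on the current domain → Δp(r) →
spring law → blend with the previous profile (relaxation 0.5) → C1 radial
smoothing (150 µm kernel) → remesh by mapping z ↦ z·h(r)/h₀ → repeat until
max |Δh|/h₀ < 1e-3 (≤ 50 outer iterations; a strain cap of 3 aborts with
advice to re-calibrate β). Ten outer iterations typically suffice.

### Homogenization of the cell-array permeability

Müller cells are idealized as parallel cylinders (d_c = 5 µm) on a square
lattice with spacing s = n^(−1/2) (≈ 6.09 µm at parafoveal density,
solid fraction 0.53). Inclination by θ keeps the end-points on the lattice
and tilts the shafts, contracting the perpendicular spacing to s·cosθ in
the inclination plane (contact at θ ≈ 34.8°, reported on rejection). The
cell problems on the resulting rectangle-with-cylinder are solved on a
staggered (MAC) finite-difference grid with volume penalization of the
solid (mask smeared over one cell, penetration depth 1% of a cell — a
first-order-accurate interface treatment; the published dilute-limit
expansion for transverse flow past a square lattice is reproduced within
5% at 128 cells/edge): periodic Stokes with unit body force for the two
transverse components (zero-mean pressure via a bordered constraint),
periodic Poisson for the axial one. Intrinsic permeability k = μ⟨u⟩/f is
converted to hydraulic conductivity with water viscosity at 37 °C
(0.6913 mPa·s). The tensor is symmetrized (reciprocity holds to ~1e-12),
checked positive definite, and its axial component always exceeds the
transverse ones.

Contraction throttles the transverse component that crosses the chains of
nearly-touching cylinders (k_xx: force along the uncontracted axis
squeezing through the contracted gaps); the in-plane component barely
drops. The inclination table therefore reports
ratio(θ) = k_xx(0)/k_xx(θ) — 1 at θ = 0, monotone in θ — and the
calibration geometry (surface gap 5% of d_c, θ ≈ 30.4°, just above the 2%
regularization floor) yields a straight-to-inclined conductivity ratio of
≈ 35, the physical basis for the order-60 middle-layer contrast used in
the tissue map. The axial-over-obstructed variant (≈ 140) is exported
alongside; solid fractions this high are far outside the dilute regime, so
both numbers carry the penalization scheme's few-percent resolution error.

## Discretization and solvers

Transport uses P1 triangles on a structured (r, ζ = z/h) tensor mesh:
anchored uniform spacing (25–30 µm) through the macula and ring, geometric
coarsening (factor 1.09, capped at 120 µm) to the rim; 36 vertical
elements; ~10,600 elements in production. All integrals carry the
axisymmetric r-weight; volume quadrature is the degree-2 edge-midpoint
rule, boundary quadrature 2-point Gauss. Using the same quadrature for
assembly and for the budget reports makes the discrete water and albumin
balances close to solver precision (reported with every state, together
with the maximum cell Péclet number — O(0.2) at baseline, so
streamline-diffusion stabilization exists but defaults to off). The
pressure operator (including the implicit p-dependence of the leak) is
factorized once per mesh; manufactured-solution tests confirm
second-order L2 convergence of both operators, and on an r-independent
column the solver matches an independently coded 1D two-point
boundary-value solution to better than 1e-4.

Pressure and concentration alternate in a damped Picard iteration
(relaxation 0.3 with automatic halving when the iteration stalls — the
osmotic ILM feedback is non-contractive undamped at baseline), converging
both fields to a relative L2 change below 1e-9; the trivial equilibrium
(equal reservoirs, no pump, no leak) is reproduced exactly in one sweep.
Production-mesh invariance is verified by the built-in eight-mesh study
(+10% elements per step, five probes spanning foveola, ring and far
field): production deviates < 0.1% from the finest mesh.

Sweep metrics (foveolar mean pressure vs. amplitude or layer ratio) are
computed on the rigid domain: the leak rate is deformation-invariant by
construction and the pressure metrics change negligibly under the
deformation, at a fraction of the cost. The headline edema scenario always
runs the full fluid–structure loop.

## What the defaults do and do not represent

The configuration represents a mid-sized human macula with homogeneous
layer thirds, flat geometry (no foveal pit, no scleral curvature — both
deliberately neglected), isotropic per-layer conductivity, a rigid
physiological reference, and a single solute. Passing tests demonstrate
internal consistency — conservation, convergence, calibration, and the
qualitative clinical picture (central thickening despite eccentric
leakage, osmosis-dominated excess pressure, layered protection of the
fovea) — not patient-level accuracy: real edema involves cystoid voids,
hindered macromolecular diffusion, anisotropic and heterogeneous tissue,
pulsatile pressures and active transport regulation, none of which are
modelled.

Known limitations worth flagging: (i) the pathological magnitudes at the
default amplitude sit well above the sub-mm Hg clinical scale — see the
A_f audit above; ratio-type outputs (osmosis dominance, layer-protection
factor, pumping sensitivity) are robust to this common scale, absolute
peaks are not; (ii) the foveolar-pressure-vs-ratio curve is non-monotone
below ratio ≈ 10 (the more conductive outer layers transmit ring pressure
inward before the middle-layer shielding wins); (iii) the Winkler closure
has no bending stiffness or poroelastic time scale; (iv) the unit-cell
scheme's diffuse interface limits near-contact accuracy to a few per cent,
and gaps below 2% of d_c are refused rather than resolved.
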