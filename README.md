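# macuflow

Steady-state simulation of interstitial fluid and albumin transport in the
macula, for researchers in ocular biomechanics and physiological fluid
dynamics who want a transparent, scriptable alternative to commercial FEM
packages for studying exudative macular edema (EME).

## The model

The retina is treated as an axisymmetric porous slab `{0 ≤ r ≤ L, 0 ≤ z ≤
h(r)}` bounded by the retinal pigment epithelium (RPE, `z = 0`) and the
internal limiting membrane (ILM, `z = h`). Interstitial water obeys Darcy's
law and steady mass conservation,

    u = −K ∇p,        ∇·(K ∇p) + q = 0,

with a hydraulic-conductivity map `K(r, z)` built from the Müller-cell
architecture: a highly conductive foveola (`C_f`, cells sparse and
straight), a straight-cell fovea ring, and a three-layer parafovea whose
middle layer — where Müller cells are inclined and nearly in contact — is
60× less conductive than its neighbours, while the through-thickness series
composite is pinned to the measured overall retinal conductivity
`Γ_ret = 2.54e-10 m/s/Pa`. Albumin, the osmotically dominant interstitial
protein, is advected and diffuses,

    ∇·(u c) − ∇·(D ∇c) = q_a,

and couples back into the flow through Van't Hoff osmotic pressure
`Π = R T c` in the Starling membrane conditions: at the RPE,
`u·n = Γ_RPE[(p − p_c) − σ(Π − Π_c)] + Q_RPE` (active pumping toward the
choroid, tight junctions blocking albumin), and at the ILM a Starling water
flux plus a Kedem–Katchalsky solute flux
`(uc − D∇c)·n = ωRT(c − c_v) + ½(c + c_v)(1 − σ) u·n`.

Edema is a leak: inside a parafoveal capillary ring (1.33–1.83 mm) in the
inner third of the retina, water and albumin enter at rates
`q = A_f (p_a − p)(h_0/h) F_r F_z` and `q_a = a·q`. The excess tissue
pressure over the physiological reference loads a Winkler foundation of
axial Müller-cell springs, `ε(r) = Δp(r)/(β n(r) κ_c)`, thickening the
tissue most where cells are sparsest — the foveal centre — and the
transport and deformation problems are iterated to a self-consistent state.

A homogenization module computes the permeability tensor of the cell array
itself (periodic Stokes flow past a lattice of cylinders on a staggered
grid) and quantifies how inclination, by bringing cells nearly into
contact, collapses the transverse conductivity.

## Worked example

```python
import macuflow as mf
from macuflow import experiments as ex

params = mf.load_parameters()          # baseline physiology
phys = ex.run_physiological(params)
print(phys.metrics["trans_retinal_dp_mmHg"])   # 0.314
print(phys.metrics["max_speed_foveola"])       # 8.08e-08

edema = ex.run_pathological(params)    # full fluid–structure solve
print(edema.metrics["max_thickening"])         # 1.96
print(edema.metrics["max_excess_p_mmHg"])      # 6.02
print(edema.metrics["peak_c"])                 # 0.354
```

Reading the numbers: in healthy conditions the RPE pump drains the retina
toward the choroid with a trans-retinal pressure difference of only a third
of a millimetre of mercury, and flow funnels through the high-conductivity
foveola an order of magnitude faster than in the periphery. With the
baseline capillary leak switched on, albumin accumulates around the
exudation ring (peak 0.354 mol/m³), its osmotic pull raises the tissue
pressure by ~6 mm Hg — and although that pressure peaks *at the ring*, the
converged thickness profile doubles *at the foveal centre* (h/h₀ = 1.96),
because the foveola is 54× more compliant: the model's explanation for why
edema fluid collects in the avascular fovea.

The same API exposes the sweeps (`sweep_exudation`, `sweep_hc_ratio`), the
RPE-pumping and albumin-switch experiments, the mesh-invariance study, and
the unit-cell solver (`macuflow.homogenization`). A CLI mirrors them:

    macuflow --out out/ physiological
    macuflow --out out/ pathological --af-fraction 1.0
    macuflow --out out/ homogenize

Each run writes CSV profiles, legacy-VTK fields, JSON-lines metrics and a
manifest.

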