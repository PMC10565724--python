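# phasecell

3D phase-field simulation of single-cell migration on curved and porous
substrates, with a membrane-tension / curvature-sensing actin source.

`phasecell` is for researchers in cell mechanobiology and biomaterials who
want to ask how the *geometry* of a scaffold — convex bumps, adhesive
micropatterns, the spherical pockets and narrow interconnect windows of
particle-templated materials (PTM), or the saddle-curved bicontinuous
channels of bijel-templated materials (BTM) — steers the migration and
shape of a generic motile cell, without tracking any explicit surface.

## The model

The cell is a diffuse order parameter ρ (the cell occupies ρ ≥ 0.5)
coupled to an actin polarity field **p**; the substrate is a static
diffuse field Φ with a wider "sensing" field Ψ. All quantities are
nondimensional with 1 length unit = 1 μm and 1 time unit = 10 s:

```
∂ρ/∂t = D_ρ∇²ρ − α p·∇ρ − κ(x)∇Φ·∇ρ − λρΦ² + ω ρ(1−ρ)(ρ−(1−δ))
∂p/∂t = D_p∇²p − τ₁⁻¹p − γ(∇ρ·p)p − Φ²p − β·S
S     = e^(−ζ|c|) · ( Ψ[(1−θ)P̂(∇ρ) + θ∇ρ] + εχ∇ρ )
δ     = ½ + μ(V₀−V) − σ|p|²
```

The terms: interface diffusion, advection of the cell along its actin
field, adhesion toward conformal substrate contact, exclusion from the
solid, and a bistable interface cubic whose setpoint δ weakly conserves
the initial volume V₀ and retracts contractile (σ|p|²) regions. The actin
source S pushes the membrane outward, splitting near a substrate between
pushing into it (θ) and turning parallel to it (the rotation operator
P̂), plus a membrane polymerization term ε gated by the membrane
indicator χ = 1 − tanh²(G(ρ−½)). The model's key ingredient is the
membrane-tension factor e^(−ζ|c|): polymerization decays exponentially
where the membrane is strongly bent (local mean curvature c of the ρ
field) while the cell is globally stretched (ζ = f₀T·(A−A₀)/A₀, with A₀
the area of the relaxed free cell). High-curvature features — the rim of
a PTM interconnect window, a convex bump — therefore locally shut down
protrusion, while near-minimal saddle surfaces (mean curvature ≈ 0, as in
a BTM) do not. Integration is explicit Euler on a regular lattice,
restricted to an active region around the cell.

Substrates are generated in-repo: adhesive strips (κ = 5 on / 1 off),
hemisphere arrays, random-close-packed sphere templates inverted into
PTMs (packing built in layers to the RCP fraction ≈ 0.64), the simplified
three-pore "PTM interconnect", matched hyperboloid channels, and
Cahn–Hilliard spinodal structures thresholded at a target domain size
(BTM). Analytics cover centroid displacement and velocity, inertia-tensor
shape eigenvalues, shape energy, mean polarity, curvature maps on the
ρ = 0.5 mesh, aspect ratio, and contact area.

## Worked example

Run the adhesive-strip validation pair from the shell:

```bash
$ phasecell validate --scenario strips
INFO phasecell: aspect ratios: 20um=1.26 50um=1.00
PASS
```

A cell seeded on a 20 μm adhesive strip elongates along it (projected
aspect ratio 1.26), while on a 50 μm strip — wider than the cell — it
spreads isotropically (aspect ratio 1.00): confinement by the adhesive
pattern, not by any imposed direction, sets the shape.

A full run with artifacts (metrics CSV, HDF5 snapshots, STL-exportable
fields, JSON manifest):

```bash
phasecell simulate \
  --config src/phasecell/configs/ptm3.yaml --out runs/ptm3
phasecell analyze --run runs/ptm3 --curvature-stl
```

`runs/ptm3/metrics.csv` contains per-time-unit rows of
`t, x_cm, y_cm, z_cm, r, k11, k22, k33, E_shape, mean_pz, A, V,
aspect_ratio, contact_area, v`; the manifest records every model constant
and the dimensional duration (a standard 500-unit run is 5000 s).

The same machinery is available as a library:

```python
from phasecell.scenarios import build_scenario
from phasecell.dynamics import run_simulation

substrate, state, params, run_kw, info = build_scenario("btm")
traj = run_simulation(state, substrate, params, **run_kw)
print(traj.r[-1])          # net displacement in um
```

### Config schema

A run config is one YAML mapping: `scenario` (one of `free`,
`hemisphere`, `hemisphere-notension`, `strip12/20/50`, `ptm3`,
`hyperboloid`, `btm`), `params` (overrides of the model constants:
`D_rho, D_phi, D_psi, D_p, alpha, kappa_default, lambda_, tau1_inv,
beta, gamma, sigma, mu, theta, omega, epsilon, G, T_memb, f0, dx, dt,
t_end`), `scenario_args` (generator arguments such as `t_end`, widths,
seeds), `sample_every`, `snapshot_every`, `seed`. Examples ship in
`src/phasecell/configs/`.

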