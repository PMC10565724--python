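# Methods

## Model

The cell is a nonconserved phase field ρ on a regular lattice (voxel
centers at `(index + 0.5)·dx`, zero-flux mirror closure on all faces),
coupled to an actin polarity field **p**. The governing equations, their
term-by-term meaning and the sign conventions are documented in
`phasecell.dynamics`; every sign is pinned by a dedicated unit test of
its physical contract (advection translates the cell along **p**;
adhesion extends ρ toward conformal contact; exclusion expels ρ and
**p** from the solid; the interface cubic advances for δ > ½ and
retracts for δ < ½; the polymerization source −β·S points along the
outward normal because ∇ρ points into the cell).

Two reconstruction choices deserve explanation, because the printed
renderings of the governing equations leave them open and the package's
behavior depends on them:

* **Boundary-motion cubic.** We use ω·ρ(1−ρ)(ρ−(1−δ)). Reading the
  cubic's middle root as δ itself makes both bulk phases linearly
  unstable and reverses the volume-restoring direction given
  δ = ½ + μ(V₀−V) − σ|p|²; the reflected root 1−δ is the unique
  arrangement that is bistable, restores volume in the correct
  direction, and reduces to the standard Allen–Cahn cubic ρ(1−ρ)(ρ−½)
  at δ = ½ (matching the double well (ω/4)ρ²(1−ρ)² used in E_shape).
* **Tension factor.** The curvature penalty is decay-only and gates the
  whole source: S = e^(−ζ|c|)·(Ψ[…] + εχ∇ρ), with ζ floored at 0 and
  |c| unsigned. A signed exponent amplifies polymerization on concavely
  conforming membrane, which pins cells onto convex bumps ever harder
  as tension grows — the opposite of the validation behavior — and
  erases the distinction between saddle-curved (mean curvature ≈ 0,
  unpenalized) and spherically curved surfaces that the porous-material
  comparison rests on. Gating only the ε-term leaves the Ψθ source
  feeding a leading edge at full strength regardless of tension, which
  makes redirection at an interconnect rim impossible; gating the full
  source is what curtails the leading edge. For bulge-shaped membrane
  (c < 0) with χ = 1 the factor is identical to the signed form.

## Parameters

All constants are nondimensional (length scale 1 μm, time scale 10 s,
set by τ₁⁻¹ = 0.1 and D_p = 0.2). Defaults in `ModelParams`:

| symbol | meaning | default |
|---|---|---|
| D_ρ, D_Φ, D_Ψ, D_p | diffusivities (cell, substrate, sensing, actin) | 1, 0.5, 4, 0.2 |
| α | advection of the cell with actin | 2 |
| κ | adhesion (spatial maps override; 5 on adhesive strips) | 1 |
| λ | exclusion of cell from substrate | 5 |
| τ₁⁻¹ | actin depolymerization | 0.1 |
| β | actin generation (source prefactor) | 3 |
| γ | myosin symmetry breaking | 0.05 |
| σ | acto-myosin contraction | 0.2 |
| μ | volume-conservation strength | 0.001 |
| θ | substrate pushing/turning ratio | 0.4 |
| ε | bare membrane polymerization weight | 0.34 |
| G | membrane-indicator steepness | 14 |
| T, f₀ | membrane extensibility × tension constant (enter as f₀·T) | 1, 10 |
| ω | interface-cubic strength | 8 |
| dx, dt | lattice spacing, Euler step | 0.5, 0.01 |
| t_end | run duration (500 units = 5000 s) | 500 |

Two constants are not printed anywhere and are this package's own
calibration, fixed once and used for every scenario:

* **ω = 8** sets the diffuse-interface width w₀ = 2√(2D_ρ/ω) ≈ 1 μm.
  With ω = 1 the interface of a 17 μm cell is ~6 μm wide; adhesion
  response, curvature sensing and the weak volume constraint all become
  too soft (free-cell volume drifts ~2.8 %, contact dynamics nearly
  frozen). At ω = 8 the free cell holds its volume to ~1 % over 100
  time units and contact-driven shape dynamics are vigorous, while the
  interface is still resolved at dx ≤ 1.
* **f₀·T = 10** scales the membrane stretch ζ = f₀T·(A−A₀)/A₀. The
  stretch of a substrate-engaged cell is (A−A₀)/A₀ ≈ 0.1–0.2, so
  f₀T = 10 puts ζ at order one — the regime where the curvature penalty
  e^(−ζ|c|) meaningfully discriminates a window rim (|c| ≈ 0.3–0.5 μm⁻¹)
  from a pocket wall (|c| ≈ 0.05–0.2 μm⁻¹). This mirrors the original
  study's own protocol of calibrating the tension term on the
  hemisphere validation case until its effect is significant without
  dominating. "Tension off" means ε = 0 *and* f₀ = 0.

The explicit-Euler stability guard rejects
dt > min(0.2·dx²/max(D_ρ, D_p, 1), 0.4/ω) at construction.

## Numerics

Central second-order differences with mirror closure; 7-point Laplacian.
Curvature is the regularized level-set form c = ∇·(∇ρ/(|∇ρ|+10⁻⁸)),
zeroed where |∇ρ| < 10⁻⁶ (bulk); with ρ ≈ 1 inside, a sphere of radius
R gives c ≈ −2/R (convex-outward negative). Surface area uses the
co-area estimator Σ|∇ρ|ΔV, volume Σρ·ΔV. The step is restricted to the
active region (ρ ≥ 0.01 dilated by 1 μm, refreshed every 10 steps, keyed
to absolute step count so checkpoint/resume is step-identical); the
production path is a fused numba kernel pinned to the per-term numpy
implementation by an exact (1e-13) equivalence test. A step aborts with
a diagnostic if |ρ| exceeds 2 anywhere. The tension exponent is clamped
at −10 as an overflow guard (physical values are ≲ 1).

Substrates are voxelized on a 1 μm build lattice (a voxel is solid if
its center is inside the analytic solid), relaxed into Φ (3 nominal
diffusion steps, D_Φ = 0.5, dt = 0.05) and Ψ (5 steps, D_Ψ = 4) — each
nominal step internally split to respect the 3D FTCS bound, preserving
total diffusion time, mass (exactly) and the [0, 1] range — then
trilinearly interpolated to the simulation lattice. Ψ is floored at Φ
(diffusion alone leaves Ψ below Φ just inside the solid; the sensing
region is defined to contain the substrate).

The Cahn–Hilliard generator uses a semi-implicit cosine-spectral update
(zero-flux; the mean is conserved exactly), interface coefficient 1,
symmetric 50:50 quench from small seeded noise, and an adaptive time
step (0.5, ramped ×1.5 when late-stage coarsening slows, capped at 2.0
where the explicit cubic term destabilizes). Only the stop-time domain
size — the first-moment structure-factor length L = 2π·ΣS/ΣkS — matters
downstream; the run errors if coarsening stalls before the target. The
box must be ≳ 3× the target size or the spectrum saturates.

The packing generator deposits spheres layer by layer (each drop takes
the lowest resting position among 8 lateral candidates), then densifies
by per-sphere gravity descent with rolling while the pair rest-distance
shrinks from 2r toward the floor 2r(1−overlap), stopping when the
Monte-Carlo union volume fraction in the bulk analysis band reaches the
random-close-packing limit 0.64 that the structure is built to achieve;
the achieved fraction, seed and parameters are recorded in `meta`.

## Scenario fixtures

All scenario runs use dx = 1 μm, dt = 0.02, horizons of 150–300 time
units, and boxes of 48–90 μm per side; the 17 μm cube cell (equal-volume
sphere in pore geometries, where a cube cannot be placed without
substrate overlap) starts with unit downward polarity. The PTM
interconnect fixture uses 36 μm pockets with a 32.5 % window; pockets
much smaller than the cell turn the interaction into pure size
exclusion, and a squeezed waist narrower than ~10 μm becomes a
catenoid-like neck whose *mean* curvature cancels — both regimes hide
the curvature mechanism the model exists to probe. The hyperboloid
control matches this fixture's maximum/minimum diameters. The BTM
fixture is an 80 μm box at spinodal domain size 28 μm (the Cahn–Hilliard
run executes on a 2 μm lattice and is refined to the build lattice); the
cell is seeded at the feasible position that maximizes the sensing field
under it — in contact with the internal surfaces, as in the study
protocol. The hemisphere fixture is a single 12 μm bump centered in a
64×64×48 box (a bump lattice with spacing comparable to the cell leaves
no flat region to move onto), with the cell started 4–5 μm off the apex;
outcomes are insensitive to the exact start within that range.

## The synthetic generators vs real materials

The generators emulate the *geometry* of the study's substrates —
curvature distributions, aperture sizes, connectivity — not their
chemistry or mechanics: no fibrous texture, no compliance (substrates
are rigid), no degradation, and the cell model omits nucleus, focal
adhesions and lamellipodial protrusions. Passing scenario tests
therefore demonstrates that geometry alone, through the model's
curvature-gated polymerization, reproduces the qualitative migratory
contrasts; it does not validate predictions about any particular
material's surface chemistry or about absolute cell speeds.

## Analytics choices

Shape eigenvalues are those of the moment-of-inertia tensor of the
uniform ρ ≥ 0.5 solid about its centroid (disk signature
k33 ≈ k22 < k11, ratio k11/k22 → 2 for a thin disk). E_shape integrates
(D_ρ/2)|∇ρ|² + (ω/4)ρ²(1−ρ)² + κ∇Φ·∇ρ; only relative changes are
meaningful. The aspect ratio uses second moments of the 2D projection
(robust to diffuse edges). Contact area is geometric: the area of the
marching-cubes ρ = 0.5 surface whose interpolated sensing field exceeds
Ψ = 0.1 (≈ 1.5 μm from the solid); a Ψ²-weighted integral
systematically undercounts the footprint because the membrane rests at
a finite standoff. The curvature map interpolates the model's own c
field onto the ρ = 0.5 mesh.

## Known limitations

* Flat-substrate crawling is not self-sustaining at the tabulated
  constants (the polarity feedback γ|∇ρ||p| sits below τ₁⁻¹): cells on
  flat or gently curved substrates reach steady states, and sustained
  migration is geometry-fed. Consistent with the strip and hemisphere
  endpoints, but net displacements in porous runs are a few μm to
  ~10 μm, smaller than in the original study.
* The interconnect interaction reproduces the slowing, stopping,
  pocket-confined centroid, energy-peak timing and disk-like shape, but
  not a persistent sign reversal of mean p_z, and a 1–3 μm membrane
  tongue rests across the window plane at steady state (the pocket is
  barely larger than the cell, so the cell must rest on the window
  funnel). With polarity suppressed entirely, the interface energetics
  retract the tongue completely — the energy landscape is right; the
  residual is held by locally regenerated polarity.
* The unsigned curvature penalty suppresses polymerization at concave
  junction rings (e.g. where a bump meets the base plane), which can
  create a barrier to crossing such features.
* At dx = 1 the χ membrane band of a w₀ ≈ 1 μm interface is ~1 voxel
  wide; curvature-gated quantities are noisier there than at dx = 0.5
  (the discretization-robustness check compares outcomes, not values).
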