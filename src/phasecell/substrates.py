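"""Substrate construction: every surface the cell model interacts with.

A substrate starts life as a binary solid mask on a build lattice of
1 μm spacing, is relaxed by brief diffusion into the interaction field Φ
(substrate location) and the wider sensing field Ψ (what an approaching
cell detects before contact), and is then interpolated onto the simulation
lattice.  Generators cover the study's geometries:

* flat slab with a centered adhesive strip (κ = 5 on / 1 off),
* a square lattice of convex hemispherical bumps,
* particle-templated material (PTM): an inverted random close packing of
  equal spheres — spherical pockets joined by narrow interconnect windows,
* the simplified three-pore "PTM interconnect" column,
* a hyperboloid channel matching the PTM's max/min diameters but with a
  gentler throat curvature,
* bijel-templated material (BTM): a bicontinuous spinodal structure from a
  Cahn–Hilliard run, thresholded once the domain size reaches its target.

All generators are deterministic given their seed, which is recorded in
``SubstrateField.meta`` together with the generator name and parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.fft import dctn, idctn
from scipy.spatial import cKDTree

from .fields import laplacian
from .grid import GridSpec

__all__ = [
    "SubstrateField",
    "SpherePacking",
    "relax_substrate",
    "substrate_from_mask",
    "make_flat_with_strip",
    "make_hemisphere_array",
    "pack_spheres_rcp",
    "union_volume_fraction",
    "make_ptm",
    "make_ptm_interconnect",
    "make_hyperboloid",
    "cahn_hilliard_run",
    "characteristic_domain_size",
]

#: build lattice spacing (μm) on which all masks are made and relaxed
BUILD_SPACING = 1.0
#: nominal relaxation time step on the build lattice
RELAX_DT = 0.05
#: (diffusivity, number of nominal steps) for each interaction field
RELAX_SCHEDULE = {"phi": (0.5, 3), "psi": (4.0, 5)}


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class SubstrateField:
    """Diffuse substrate Φ, sensing field Ψ and adhesion map κ(x) on a grid."""

    grid: GridSpec
    phi: np.ndarray
    psi: np.ndarray
    kappa_map: np.ndarray
    mask: np.ndarray | None = None  # binary solid on the build lattice
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid.check_scalar(self.phi, "phi")
        self.grid.check_scalar(self.psi, "psi")
        self.grid.check_scalar(self.kappa_map, "kappa_map")
        if np.any(self.kappa_map <= 0):
            raise ValueError("kappa_map must be > 0 everywhere")
        # cached derived arrays, built lazily
        self._grad_phi: np.ndarray | None = None

    def grad_phi(self) -> np.ndarray:
        from .fields import gradient

        if self._grad_phi is None:
            self._grad_phi = gradient(self.phi, self.grid)
        return self._grad_phi

    @classmethod
    def empty(cls, grid: GridSpec) -> "SubstrateField":
        """Substrate-free environment (free cell)."""
        z = grid.zeros()
        return cls(grid, z, z.copy(), np.ones(grid.shape), None,
                   {"name": "empty"})


@dataclass
class SpherePacking:
    """Centers of a layered random close packing (periodic in x and y)."""

    centers: np.ndarray  # (N, 3) μm
    radius: float
    box: tuple[float, float, float]
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def n_spheres(self) -> int:
        return len(self.centers)


# --------------------------------------------------------------------------
# relaxation of binary masks into diffuse fields
# --------------------------------------------------------------------------

def relax_substrate(mask: np.ndarray, which: str) -> np.ndarray:
    """Diffuse a binary solid mask into the Φ or Ψ interaction field.

    Pure zero-flux diffusion on the build lattice (spacing 1 μm): 3 nominal
    steps of dt = 0.05 at D_Φ = 0.5 for ``which="phi"``, 5 steps at
    D_Ψ = 4 for ``which="psi"``.  Each nominal step is internally split
    into equal substeps obeying the 3D FTCS stability bound
    (D·dt/dx² ≤ 1/6), preserving the nominal total diffusion time; the
    convex stencil keeps the field in [0, 1] and conserves mass exactly.
    """
    if which not in RELAX_SCHEDULE:
        raise ValueError(f"which must be 'phi' or 'psi', got {which!r}")
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("relax_substrate requires a binary {0,1} mask")
    D, n_steps = RELAX_SCHEDULE[which]
    grid = GridSpec(mask.shape, BUILD_SPACING)
    # substeps per nominal step so that D*dt_sub/dx^2 <= 1/6
    n_sub = max(1, math.ceil(6.0 * D * RELAX_DT / BUILD_SPACING**2))
    dt_sub = RELAX_DT / n_sub
    f = mask.astype(float)
    for _ in range(n_steps * n_sub):
        f = f + dt_sub * D * laplacian(f, grid)
    return f


def _interp_to(field_b: np.ndarray, sim_grid: GridSpec) -> np.ndarray:
    """Trilinear interpolation from the build lattice to the simulation grid.

    Both lattices use the voxel-center convention and share the same
    physical extent.
    """
    if sim_grid.spacing == BUILD_SPACING and field_b.shape == sim_grid.shape:
        return field_b.copy()
    coords = [
        ((np.arange(n) + 0.5) * sim_grid.spacing) / BUILD_SPACING - 0.5
        for n in sim_grid.shape
    ]
    mesh = np.meshgrid(*coords, indexing="ij")
    return ndimage.map_coordinates(field_b, mesh, order=1, mode="nearest")


def substrate_from_mask(
    mask: np.ndarray,
    sim_spacing: float = 1.0,
    kappa_map: np.ndarray | None = None,
    kappa_default: float = 1.0,
    meta: dict | None = None,
) -> SubstrateField:
    """Relax a build-lattice binary mask into a full SubstrateField.

    Ψ is floored at Φ after relaxation: diffusion alone makes Ψ smaller
    than Φ just *inside* the solid (it is the smoother field), while the
    sensing region is meant to contain the substrate, so the pointwise
    maximum restores Ψ ≥ Φ without changing the exterior sensing skirt.
    """
    phi_b = relax_substrate(mask, "phi")
    psi_b = relax_substrate(mask, "psi")
    psi_b = np.maximum(psi_b, phi_b)
    shape = tuple(
        int(round(n * BUILD_SPACING / sim_spacing)) for n in mask.shape
    )
    sim_grid = GridSpec(shape, sim_spacing)
    phi = np.clip(_interp_to(phi_b, sim_grid), 0.0, 1.0)
    psi = np.clip(_interp_to(psi_b, sim_grid), 0.0, 1.0)
    psi = np.maximum(psi, phi)
    if kappa_map is None:
        kappa_map = np.full(sim_grid.shape, kappa_default)
    return SubstrateField(sim_grid, phi, psi, kappa_map, mask.astype(np.uint8),
                          dict(meta or {}))


def _voxel_centers(extent: tuple[int, int, int]):
    grid = GridSpec(extent, BUILD_SPACING)
    return grid.meshgrid()


# --------------------------------------------------------------------------
# patterned flat substrates
# --------------------------------------------------------------------------

def make_flat_with_strip(
    strip_width: float,
    kappa_on: float = 5.0,
    kappa_off: float = 1.0,
    extent: tuple[int, int, int] = (56, 72, 40),
    slab_thickness: float = 6.0,
    sim_spacing: float = 1.0,
) -> SubstrateField:
    """Flat slab with a centered adhesive strip running along y.

    κ = ``kappa_on`` on a strip of the given width (μm) centered in x,
    ``kappa_off`` elsewhere; the strip spans the full y length.
    """
    if not strip_width > 0:
        raise ValueError(f"strip_width must be > 0, got {strip_width}")
    x, y, z = _voxel_centers(extent)
    mask = (z < slab_thickness).astype(np.uint8) * np.ones(extent, np.uint8)
    shape = tuple(int(round(n / sim_spacing)) for n in extent)
    sim_grid = GridSpec(shape, sim_spacing)
    xs = sim_grid.meshgrid()[0]
    cx = extent[0] / 2.0
    on = np.abs(xs - cx) < strip_width / 2.0
    kappa = np.where(np.broadcast_to(on, sim_grid.shape), kappa_on, kappa_off)
    return substrate_from_mask(
        mask, sim_spacing, kappa.astype(float),
        meta={"name": "strip", "strip_width": strip_width,
              "kappa_on": kappa_on, "kappa_off": kappa_off,
              "slab_thickness": slab_thickness, "extent": extent},
    )


def make_hemisphere_array(
    radius: float = 12.0,
    bump_spacing: float = 64.0,
    extent: tuple[int, int, int] = (64, 64, 48),
    base_thickness: float = 6.0,
    sim_spacing: float = 1.0,
    lattice_offset: float | None = None,
) -> SubstrateField:
    """Flat base plus hemispherical bumps on a periodic square lattice.

    Bump centers sit on the base top surface at ``lattice_offset`` plus
    multiples of ``bump_spacing`` in x and y (laterally periodic, so the
    pattern is invariant under translation by one bump spacing).  The
    default offset of half a spacing centers one bump in the default
    extent, leaving a flat apron wide enough for the cell to leave the
    bump entirely.
    """
    if lattice_offset is None:
        lattice_offset = bump_spacing / 2.0
    x, y, z = _voxel_centers(extent)
    base = z < base_thickness
    # periodic lateral distance to the nearest bump-lattice point
    dx = np.abs((x - lattice_offset) % bump_spacing)
    dx = np.minimum(dx, bump_spacing - dx)
    dy = np.abs((y - lattice_offset) % bump_spacing)
    dy = np.minimum(dy, bump_spacing - dy)
    r2 = dx**2 + dy**2 + (z - base_thickness) ** 2
    bumps = (r2 < radius**2) & (z >= base_thickness)
    mask = (base | bumps).astype(np.uint8)
    return substrate_from_mask(
        mask, sim_spacing,
        meta={"name": "hemisphere", "radius": radius,
              "bump_spacing": bump_spacing, "base_thickness": base_thickness,
              "extent": extent},
    )


# --------------------------------------------------------------------------
# random close packing (PTM template)
# --------------------------------------------------------------------------

def _drop_height(
    xy: np.ndarray,
    centers: np.ndarray,
    radius: float,
    d_rest: float,
    box_xy: tuple[float, float],
    exclude: int | None = None,
) -> float:
    """Lowest feasible center height at lateral position xy.

    The sphere rests on the floor (z = r) or on the highest supporting
    contact at center distance ``d_rest``; lateral distances use the
    minimum-image convention (periodic x, y).
    """
    z_min = radius
    if len(centers):
        d = centers[:, :2] - xy
        for ax in range(2):
            L = box_xy[ax]
            d[:, ax] -= L * np.round(d[:, ax] / L)
        lat2 = d[:, 0] ** 2 + d[:, 1] ** 2
        near = lat2 < d_rest**2
        if exclude is not None:
            near[exclude] = False
        if near.any():
            support = centers[near, 2] + np.sqrt(d_rest**2 - lat2[near])
            z_min = max(z_min, support.max())
    return z_min


def union_volume_fraction(
    packing: SpherePacking,
    n_points: int = 200_000,
    seed: int = 0,
    z_band: tuple[float, float] | None = None,
) -> float:
    """Monte-Carlo estimate of the volume fraction covered by the spheres.

    Samples uniformly in the (laterally periodic) box restricted to
    ``z_band`` and counts points within ``radius`` of any center.
    """
    Lx, Ly, _ = packing.box
    r = packing.radius
    if z_band is None:
        z_band = _analysis_band(packing)
    rng = np.random.default_rng(seed)
    pts = rng.random((n_points, 3))
    pts[:, 0] *= Lx
    pts[:, 1] *= Ly
    pts[:, 2] = z_band[0] + pts[:, 2] * (z_band[1] - z_band[0])
    tree = cKDTree(_with_lateral_images(packing.centers, (Lx, Ly), r))
    dist, _ = tree.query(pts, k=1)
    return float(np.mean(dist <= r))


def _with_lateral_images(centers, box_xy, r):
    """Append periodic images of centers within r of the lateral faces."""
    out = [centers]
    Lx, Ly = box_xy
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            if sx == 0 and sy == 0:
                continue
            shifted = centers + np.array([sx * Lx, sy * Ly, 0.0])
            keep = (
                (shifted[:, 0] > -r) & (shifted[:, 0] < Lx + r)
                & (shifted[:, 1] > -r) & (shifted[:, 1] < Ly + r)
            )
            if keep.any():
                out.append(shifted[keep])
    return np.concatenate(out, axis=0)


def _analysis_band(packing: SpherePacking) -> tuple[float, float]:
    r = packing.radius
    top = packing.centers[:, 2].max() - 2.0 * r if len(packing.centers) else r
    top = min(top, packing.box[2] - r)
    return (2.0 * r, max(top, 3.0 * r))


def pack_spheres_rcp(
    radius: float,
    box: tuple[float, float, float],
    seed: int,
    overlap_frac: float = 0.35,
    target_fraction: float = 0.64,
    max_sweeps: int = 160,
    n_candidates: int = 8,
) -> SpherePacking:
    """Layered drop-and-settle packing of equal spheres, densified to RCP.

    Spheres are deposited sequentially (each drop picks the lowest resting
    position among ``n_candidates`` lateral candidates — a local energy
    descent), then densification sweeps re-settle every sphere while the
    contact rest distance shrinks from 2r toward the floor
    2r(1 − overlap_frac).  Sweeps stop as soon as the measured union
    volume fraction in the bulk analysis band reaches ``target_fraction``
    (the random-close-packing limit the structure is built to achieve);
    the achieved fraction is recorded in ``meta``.

    Raises ``RuntimeError`` if the fraction stays below 0.60 once the
    rest-distance floor and sweep budget are exhausted.
    """
    Lx, Ly, Lz = box
    if min(Lx, Ly) < 2 * radius:
        raise ValueError("box must be at least one sphere diameter wide")
    rng = np.random.default_rng(seed)
    d_contact = 2.0 * radius
    d_min = d_contact * (1.0 - overlap_frac)
    fill_height = Lz + radius

    centers_list: list[np.ndarray] = []
    centers = np.empty((0, 3))
    # --- sequential layered deposition at hard contact -------------------
    while True:
        best = None
        for _ in range(n_candidates):
            xy = rng.random(2) * (Lx, Ly)
            zc = _drop_height(xy, centers, radius, d_contact, (Lx, Ly))
            if best is None or zc < best[2]:
                best = (xy[0], xy[1], zc)
        if best[2] > fill_height:
            break
        centers_list.append(np.array(best))
        centers = np.array(centers_list)
    packing = SpherePacking(centers, radius, box, seed)

    # --- densification: local gravity descent with rolling ---------------
    # each sphere repeatedly moves down (or diagonally down around its
    # supports) as far as the current rest distance allows; the rest
    # distance shrinks slowly from 2r toward the overlap floor
    def _feasible(i, pos, d):
        if pos[2] < radius:
            return False
        delta = centers[:, :2] - pos[:2]
        for ax in range(2):
            L = (Lx, Ly)[ax]
            delta[:, ax] -= L * np.round(delta[:, ax] / L)
        dist2 = delta[:, 0] ** 2 + delta[:, 1] ** 2 + (centers[:, 2] - pos[2]) ** 2
        dist2[i] = np.inf
        return bool((dist2 >= d * d).all())

    dirs = np.array([
        [0.0, 0.0], [1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0],
        [0.7, 0.7], [-0.7, 0.7], [0.7, -0.7], [-0.7, -0.7],
    ])
    d_rest = d_contact
    frac = union_volume_fraction(packing, seed=seed + 1)
    sweeps = 0
    while frac < target_fraction and sweeps < max_sweeps:
        # slow the compaction near the target so the stop is not overshot
        near = frac > target_fraction - 0.03
        step = (0.015 if near else 0.05) * radius
        d_rest = max(d_min, d_rest * (0.997 if near else 0.985))
        order = np.argsort(centers[:, 2])[::-1]  # settle from the top down
        for i in order:
            for _ in range(40):  # descend until stuck
                moved = False
                for dxy in dirs:
                    cand = centers[i] + np.array(
                        [dxy[0] * step, dxy[1] * step, -step])
                    cand[0] %= Lx
                    cand[1] %= Ly
                    if _feasible(i, cand, d_rest):
                        centers[i] = cand
                        moved = True
                        break
                if not moved:
                    break
        sweeps += 1
        frac = union_volume_fraction(packing, seed=seed + 1)
    frac = union_volume_fraction(packing, n_points=400_000, seed=seed + 2)
    if frac < 0.60:
        raise RuntimeError(
            f"packing densification reached only fraction {frac:.3f} "
            f"(< 0.60) after {sweeps} sweeps"
        )
    packing.meta.update(
        achieved_fraction=frac,
        sweeps=sweeps,
        d_rest_final=d_rest,
        overlap_frac=overlap_frac,
        n_spheres=len(centers),
        target_fraction=target_fraction,
    )
    return packing


def make_ptm(
    packing: SpherePacking,
    sim_spacing: float = 1.0,
    extent: tuple[int, int, int] | None = None,
) -> SubstrateField:
    """Invert a sphere packing into a particle-templated porous solid.

    The sphere union is voxelized on the build lattice (a voxel is pore if
    its center lies inside any sphere) and the phases are switched: solid
    = complement of the pores.  Interconnect windows open wherever two
    spheres overlap.
    """
    Lx, Ly, Lz = packing.box
    if extent is None:
        extent = (int(round(Lx)), int(round(Ly)), int(round(Lz)))
    x, y, z = _voxel_centers(extent)
    r = packing.radius
    tree = cKDTree(_with_lateral_images(packing.centers, (Lx, Ly), r))
    pts = np.stack(np.broadcast_arrays(x, y, z), axis=-1).reshape(-1, 3)
    dist, _ = tree.query(pts, k=1)
    pore = (dist <= r).reshape(extent)
    mask = (~pore).astype(np.uint8)
    return substrate_from_mask(
        mask, sim_spacing,
        meta={"name": "ptm", "radius": r, "seed": packing.seed,
              "box": packing.box, **packing.meta},
    )


def make_ptm_interconnect(
    sphere_diameter: float = 70.0,
    interconnect_frac: float = 0.325,
    margin: float = 8.0,
    sim_spacing: float = 1.0,
) -> SubstrateField:
    """Simplified PTM: three collinear spherical pores stacked along z.

    Center spacing is set so the circular interconnect window diameter is
    ``interconnect_frac × sphere_diameter`` (the physically stable 30–35%
    range by default); the pore column is then inverted to solid.
    """
    if not 0.0 < interconnect_frac <= 0.5:
        raise ValueError(
            f"interconnect_frac must lie in (0, 0.5], got {interconnect_frac}"
        )
    r = sphere_diameter / 2.0
    a = interconnect_frac * r  # window radius
    spacing_z = 2.0 * math.sqrt(r**2 - a**2)
    lateral = int(round(2 * r + 2 * margin))
    height = int(round(2 * r + 2 * spacing_z + 2 * margin))
    extent = (lateral, lateral, height)
    x, y, z = _voxel_centers(extent)
    cx = cy = lateral / 2.0
    cz = height / 2.0
    pore = np.zeros(extent, bool)
    for k in (-1, 0, 1):
        zc = cz + k * spacing_z
        pore |= (x - cx) ** 2 + (y - cy) ** 2 + (z - zc) ** 2 < r**2
    mask = (~pore).astype(np.uint8)
    return substrate_from_mask(
        mask, sim_spacing,
        meta={"name": "ptm3", "sphere_diameter": sphere_diameter,
              "interconnect_frac": interconnect_frac,
              "window_diameter": 2 * a, "center_spacing": spacing_z,
              "pore_centers_z": [cz - spacing_z, cz, cz + spacing_z],
              "center": (cx, cy, cz), "extent": extent},
    )


def make_hyperboloid(
    d_max: float,
    d_min: float,
    length: float,
    margin: float = 8.0,
    sim_spacing: float = 1.0,
) -> SubstrateField:
    """One-sheet hyperboloid pore about z, inverted to solid.

    Pore radius profile r(z)² = (d_min/2)²·(1 + (z − z0)²/b²) with b fixed
    so the pore diameter is ``d_max`` at both ends of ``length``.
    """
    if not d_min < d_max:
        raise ValueError(f"need d_min < d_max, got {d_min} >= {d_max}")
    r_min = d_min / 2.0
    r_max = d_max / 2.0
    b = (length / 2.0) / math.sqrt((r_max / r_min) ** 2 - 1.0)
    lateral = int(round(d_max + 2 * margin))
    height = int(round(length + 2 * margin))
    extent = (lateral, lateral, height)
    x, y, z = _voxel_centers(extent)
    cx = cy = lateral / 2.0
    z0 = height / 2.0
    rad2 = r_min**2 * (1.0 + (z - z0) ** 2 / b**2)
    inside_len = np.abs(z - z0) <= length / 2.0
    pore = ((x - cx) ** 2 + (y - cy) ** 2 < rad2) & inside_len
    # open the channel to the box top and bottom at the end diameter
    ends = ((x - cx) ** 2 + (y - cy) ** 2 < r_max**2) & ~inside_len
    mask = (~(pore | ends)).astype(np.uint8)
    return substrate_from_mask(
        mask, sim_spacing,
        meta={"name": "hyperboloid", "d_max": d_max, "d_min": d_min,
              "length": length, "throat_z": z0, "center": (cx, cy, z0),
              "extent": extent},
    )


# --------------------------------------------------------------------------
# Cahn–Hilliard spinodal structure (BTM template)
# --------------------------------------------------------------------------

def characteristic_domain_size(u: np.ndarray, grid: GridSpec) -> float:
    """First-moment structure-factor length L = 2π·ΣS(k) / Σ k·S(k).

    S(k) is the spherically collected power spectrum of the zero-mean
    field; L estimates the full spinodal period (solid + pore) in μm.
    """
    w = u - u.mean()
    spec = np.abs(np.fft.rfftn(w)) ** 2
    kx = np.fft.fftfreq(u.shape[0], d=grid.spacing) * 2 * np.pi
    ky = np.fft.fftfreq(u.shape[1], d=grid.spacing) * 2 * np.pi
    kz = np.fft.rfftfreq(u.shape[2], d=grid.spacing) * 2 * np.pi
    kmag = np.sqrt(
        kx[:, None, None] ** 2 + ky[None, :, None] ** 2 + kz[None, None, :] ** 2
    )
    sel = kmag > 0
    s_sum = spec[sel].sum()
    ks_sum = (kmag[sel] * spec[sel]).sum()
    if ks_sum == 0:
        raise ValueError("field has no spectral content")
    return float(2.0 * np.pi * s_sum / ks_sum)


def _ch_k2(shape, spacing):
    axes = [
        (np.pi * np.arange(n) / (n * spacing)) ** 2 for n in shape
    ]
    return (
        axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    )


def cahn_hilliard_run(
    grid: GridSpec,
    mobility: float = 1.0,
    seed: int = 0,
    stop_size: float = 32.0,
    kappa_interface: float = 1.0,
    noise_amplitude: float = 0.1,
    check_every: int = 50,
    max_steps: int = 200_000,
    return_field: bool = False,
):
    """Spinodal decomposition of a symmetric binary mixture, stopped by size.

    Conserved order parameter u ∈ [−1, 1] evolved by the Cahn–Hilliard
    equation ∂u/∂t = M∇²(u³ − u − κ∇²u) with a semi-implicit cosine-
    spectral update (zero-flux walls; the k = 0 mode — the mean — is
    untouched, so composition is conserved exactly).  Starts from small
    zero-mean noise (a symmetric 50:50 quench) and stops once the
    characteristic domain size reaches ``stop_size`` μm; returns the
    thresholded u > 0 binary mask (and optionally u itself).

    Raises ``RuntimeError`` if coarsening stalls (< 1% size growth over
    500 consecutive steps after the interface-formation transient).
    """
    if stop_size < 4 * grid.spacing:
        raise ValueError("stop_size must be at least 4 lattice spacings")
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, noise_amplitude, size=grid.shape)
    u -= u.mean()
    k2 = _ch_k2(grid.shape, grid.spacing)
    k4 = k2 * k2

    def _advance(u, dt, n):
        denom = 1.0 + dt * mobility * kappa_interface * k4
        for _ in range(n):
            nl = dctn(u * u * u - u, norm="ortho")
            uhat = dctn(u, norm="ortho")
            uhat = (uhat - dt * mobility * k2 * nl) / denom
            u = idctn(uhat, norm="ortho")
        return u

    # short small-step transient to form interfaces, then large steps;
    # dt ramps up when late-stage coarsening slows (the semi-implicit
    # update stays stable and only the stop-time structure matters)
    u = _advance(u, 0.02, 200)
    dt = 0.5
    dt_max = 2.0  # explicit u^3 term destabilizes beyond this
    steps = 200
    stall_ref = (steps, characteristic_domain_size(u, grid))
    while steps < max_steps:
        u = _advance(u, dt, check_every)
        steps += check_every
        size = characteristic_domain_size(u, grid)
        if size >= stop_size:
            break
        if steps - stall_ref[0] >= 500:
            if size < stall_ref[1] * 1.01:
                dt = min(dt * 1.5, dt_max)
            if size < stall_ref[1] * 1.003 and dt >= dt_max:
                raise RuntimeError(
                    f"coarsening stalled at domain size {size:.2f} μm "
                    f"(target {stop_size} μm) after {steps} steps"
                )
            stall_ref = (steps, size)
    else:
        raise RuntimeError(
            f"domain size did not reach {stop_size} μm in {max_steps} steps"
        )
    mask = (u > 0).astype(np.uint8)
    if return_field:
        return mask, u
    return mask


def make_btm(
    extent: tuple[int, int, int] = (64, 64, 64),
    stop_size: float = 30.0,
    seed: int = 0,
    ch_spacing: float = 2.0,
    sim_spacing: float = 1.0,
) -> SubstrateField:
    """Bijel-templated material: thresholded spinodal structure.

    The Cahn–Hilliard run is performed on a coarser lattice (``ch_spacing``
    μm) — only the stop-time domain size matters downstream — and the
    order parameter is trilinearly refined to the 1 μm build lattice
    before thresholding.
    """
    ch_shape = tuple(max(8, int(round(n / ch_spacing))) for n in extent)
    ch_grid = GridSpec(ch_shape, ch_spacing)
    _, u = cahn_hilliard_run(
        ch_grid, seed=seed, stop_size=stop_size, return_field=True
    )
    build_grid = GridSpec(extent, BUILD_SPACING)
    coords = [
        ((np.arange(n) + 0.5) * BUILD_SPACING) / ch_spacing - 0.5
        for n in extent
    ]
    mesh = np.meshgrid(*coords, indexing="ij")
    u_fine = ndimage.map_coordinates(u, mesh, order=1, mode="nearest")
    mask = (u_fine > 0).astype(np.uint8)
    size = characteristic_domain_size(u, ch_grid)
    return substrate_from_mask(
        mask, sim_spacing,
        meta={"name": "btm", "stop_size": stop_size, "domain_size": size,
              "seed": seed, "ch_spacing": ch_spacing, "extent": extent},
    )


__all__.append("make_btm")
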