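"""Quantification of simulated cell trajectories.

Everything measured on the ρ = 0.5 cell: centroid displacement r(t) and
its centered-difference velocity, inertia-tensor eigenvalues k11 ≥ k22 ≥
k33 (shape classification: sphere-like, disk-like — a thin disk has
k33 ≈ k22 < k11 with k11/k22 → 2 — or fully anisotropic), the shape
energy E_shape (diffuse membrane energy plus the adhesion reward),
membrane curvature maps on the marching-cubes surface, polarity glyphs,
projected aspect ratio, and a diffuse contact-area proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from . import fields as F
from .grid import GridSpec
from .params import ModelParams
from .substrates import SubstrateField

__all__ = [
    "ShapeMetrics",
    "centroid",
    "centroid_displacement",
    "velocity_series",
    "inertia_eigenvalues",
    "shape_energy",
    "mean_pz",
    "curvature_map_mesh",
    "GlyphSet",
    "p_field_glyphs",
    "aspect_ratio_projection",
    "contact_area",
    "snapshot_metrics",
    "metrics_dataframe",
]


@dataclass
class ShapeMetrics:
    """Derived quantities for one snapshot."""

    t: float
    centroid: tuple[float, float, float]
    displacement: float
    k11: float
    k22: float
    k33: float
    E_shape: float
    mean_pz: float
    A: float
    V: float
    aspect_ratio: float
    contact_area: float
    velocity: float = float("nan")

    @property
    def z_cm(self) -> float:
        return self.centroid[2]


def _cell_region(rho: np.ndarray):
    region = rho >= 0.5
    if not region.any():
        raise ValueError("empty cell: no voxel with rho >= 0.5")
    return region


def centroid(rho: np.ndarray, grid: GridSpec) -> np.ndarray:
    """ρ-weighted centroid of the solid bounded by the ρ = 0.5 surface (μm)."""
    region = _cell_region(rho)
    w = np.where(region, rho, 0.0)
    idx = np.indices(grid.shape)
    total = w.sum()
    return np.array([
        ((idx[ax] * w).sum() / total + 0.5) * grid.spacing for ax in range(3)
    ])


def centroid_displacement(
    rhos, grid: GridSpec, times=None
) -> tuple[np.ndarray, np.ndarray]:
    """Displacement r(t) = |centroid(t) − centroid(0)| for a snapshot list."""
    cents = np.array([centroid(r, grid) for r in rhos])
    r = np.linalg.norm(cents - cents[0], axis=1)
    t = np.arange(len(rhos), dtype=float) if times is None else np.asarray(times)
    return t, r


def velocity_series(t: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Centered-difference dr/dt; one-sided at the endpoints.

    Exact for quadratic r(t) at the interior points.
    """
    t = np.asarray(t, float)
    r = np.asarray(r, float)
    if len(t) < 3:
        raise ValueError("velocity_series needs at least 3 samples")
    v = np.empty_like(r)
    v[1:-1] = (r[2:] - r[:-2]) / (t[2:] - t[:-2])
    v[0] = (r[1] - r[0]) / (t[1] - t[0])
    v[-1] = (r[-1] - r[-2]) / (t[-1] - t[-2])
    return v


def inertia_eigenvalues(rho: np.ndarray, grid: GridSpec) -> tuple[float, float, float]:
    """Sorted eigenvalues (k11 ≥ k22 ≥ k33) of the cell's inertia tensor.

    Second-moment (moment-of-inertia) tensor of the uniform-density solid
    bounded by ρ = 0.5, about its centroid: I = Σ (|r|²𝟙 − r⊗r) ΔV.
    The disk signature is k33 ≈ k22 < k11 (largest moment about the
    symmetry axis).
    """
    region = _cell_region(rho)
    pts = (np.argwhere(region) + 0.5) * grid.spacing
    pts = pts - pts.mean(axis=0)
    dV = grid.voxel_volume
    r2 = np.einsum("ij,ij->i", pts, pts)
    eye = np.eye(3) * r2.sum()
    outer = pts.T @ pts
    inertia = (eye - outer) * dV
    vals = np.linalg.eigvalsh(inertia)[::-1]
    return tuple(float(v) for v in vals)


def shape_energy(rho: np.ndarray, substrate: SubstrateField,
                 params: ModelParams) -> float:
    """E_shape = ∫ [ (D_ρ/2)|∇ρ|² + (ω/4)ρ²(1−ρ)² + κ(x)∇Φ·∇ρ ] dV.

    Diffuse membrane energy (gradient + Allen–Cahn double well, the well
    whose derivative matches the interface cubic ω·ρ(1−ρ)(ρ−½) at δ = ½)
    plus the integrated adhesion reward, which is negative where the
    membrane conforms to the substrate (∇Φ·∇ρ < 0 at contact).  Only
    relative changes along a trajectory are meaningful.
    """
    grid = substrate.grid
    g = F.gradient(rho, grid)
    g2 = np.einsum("...i,...i->...", g, g)
    well = 0.25 * params.omega * rho**2 * (1.0 - rho) ** 2
    adh = substrate.kappa_map * np.einsum(
        "...i,...i->...", substrate.grad_phi(), g
    )
    dens = 0.5 * params.D_rho * g2 + well + adh
    return float(dens.sum() * grid.voxel_volume)


def mean_pz(p: np.ndarray, rho: np.ndarray) -> float:
    """ρ-weighted mean z-component of p⃗ over the ρ ≥ 0.5 cell."""
    region = _cell_region(rho)
    w = np.where(region, rho, 0.0)
    return float((p[..., 2] * w).sum() / w.sum())


def curvature_map_mesh(rho: np.ndarray, grid: GridSpec,
                       c_field: np.ndarray | None = None):
    """Marching-cubes mesh of ρ = 0.5 with membrane curvature per vertex.

    Returns ``(mesh, c_vertex)`` where ``mesh`` is a ``trimesh.Trimesh``
    with vertices in μm world coordinates and ``c_vertex`` holds the
    trilinearly interpolated curvature c at each vertex.
    """
    import trimesh

    _cell_region(rho)
    if c_field is None:
        c_field = F.interface_curvature(rho, grid)
    verts, faces, _, _ = measure.marching_cubes(rho, level=0.5)
    c_vertex = ndimage.map_coordinates(c_field, verts.T, order=1,
                                       mode="nearest")
    world = (verts + 0.5) * grid.spacing
    mesh = trimesh.Trimesh(vertices=world, faces=faces, process=False)
    return mesh, c_vertex


@dataclass
class GlyphSet:
    """Block-averaged membrane polarity vectors."""

    positions: np.ndarray  # (n, 3) μm
    vectors: np.ndarray  # (n, 3)
    magnitudes: np.ndarray  # (n,)
    top_mask: np.ndarray  # (n,) bool — the top_n by magnitude


def p_field_glyphs(p: np.ndarray, rho: np.ndarray, grid: GridSpec,
                   stride: int = 3, top_n: int = 100,
                   G: float = 14.0, chi_min: float = 0.1) -> GlyphSet:
    """Average p⃗ over stride³ blocks of the membrane region (χ > χ_min).

    The ``top_n`` glyphs by magnitude are flagged (the display convention
    for the strongest polymerization sites).
    """
    chi = F.membrane_indicator(rho, G)
    memb = chi > chi_min
    if not memb.any():
        raise ValueError("no membrane voxels with chi > chi_min")
    idx = np.argwhere(memb)
    block = idx // stride
    keys, inv = np.unique(block, axis=0, return_inverse=True)
    n = len(keys)
    pos = np.zeros((n, 3))
    vec = np.zeros((n, 3))
    cnt = np.bincount(inv, minlength=n).astype(float)
    for ax in range(3):
        pos[:, ax] = np.bincount(inv, weights=idx[:, ax], minlength=n) / cnt
        vec[:, ax] = np.bincount(
            inv, weights=p[memb][:, ax], minlength=n) / cnt
    pos = (pos + 0.5) * grid.spacing
    mag = np.linalg.norm(vec, axis=1)
    top = np.zeros(n, bool)
    top[np.argsort(mag)[::-1][: min(top_n, n)]] = True
    return GlyphSet(pos, vec, mag, top)


def aspect_ratio_projection(rho: np.ndarray, grid: GridSpec,
                            normal_axis: int = 2) -> float:
    """Major/minor axis ratio of the 2D projection of the ρ ≥ 0.5 cell.

    The solid is projected along ``normal_axis`` (onto the substrate
    plane by default); the ratio is the square root of the ratio of the
    projection's second-moment eigenvalues — robust to diffuse edges,
    unlike a bounding box.
    """
    region = _cell_region(rho)
    mask2d = region.any(axis=normal_axis)
    pts = np.argwhere(mask2d).astype(float)
    pts -= pts.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    vals = np.linalg.eigvalsh(cov)[::-1]
    if vals[1] <= 0:
        return float("inf")
    return float(np.sqrt(vals[0] / vals[1]))


#: sensing-field level bounding the contact shell (~1.5 μm from the solid)
CONTACT_PSI_LEVEL = 0.1


def contact_area(rho: np.ndarray, substrate: SubstrateField,
                 psi_level: float = CONTACT_PSI_LEVEL) -> float:
    """Cell–substrate contact area, in μm².

    Area of the ρ = 0.5 membrane surface lying inside the substrate's
    sensing shell: the marching-cubes mesh faces whose interpolated Ψ
    exceeds ``psi_level`` (Ψ = 0.1 sits roughly 1.5 μm from the solid,
    the range over which the cell senses and adheres).  Zero when the
    cell is far from any substrate; for a cell spread on a flat slab it
    approximates the projected footprint.
    """
    if not (rho.max() > 0.5 > rho.min()):
        return 0.0
    grid = substrate.grid
    verts, faces, _, _ = measure.marching_cubes(rho, level=0.5)
    centroids = verts[faces].mean(axis=1)
    psi_face = ndimage.map_coordinates(substrate.psi, centroids.T, order=1,
                                       mode="nearest")
    tri = verts[faces] * grid.spacing
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    return float(areas[psi_face > psi_level].sum())


def snapshot_metrics(state, substrate: SubstrateField, params: ModelParams,
                     origin=None) -> ShapeMetrics:
    """All per-snapshot metrics for a cell state."""
    grid = state.grid
    rho, p = state.rho, state.p
    cent = centroid(rho, grid)
    disp = 0.0 if origin is None else float(
        np.linalg.norm(cent - np.asarray(origin)))
    k11, k22, k33 = inertia_eigenvalues(rho, grid)
    return ShapeMetrics(
        t=state.t,
        centroid=tuple(cent),
        displacement=disp,
        k11=k11, k22=k22, k33=k33,
        E_shape=shape_energy(rho, substrate, params),
        mean_pz=mean_pz(p, rho),
        A=F.surface_area(rho, grid),
        V=F.cell_volume(rho, grid),
        aspect_ratio=aspect_ratio_projection(rho, grid),
        contact_area=contact_area(rho, substrate),
    )


def metrics_dataframe(traj) -> pd.DataFrame:
    """Trajectory metrics as a tidy DataFrame (velocity filled in)."""
    rows = []
    for t, m in zip(traj.times, traj.metrics):
        rows.append({
            "t": t,
            "x_cm": m.centroid[0], "y_cm": m.centroid[1],
            "z_cm": m.centroid[2],
            "r": m.displacement,
            "k11": m.k11, "k22": m.k22, "k33": m.k33,
            "E_shape": m.E_shape, "mean_pz": m.mean_pz,
            "A": m.A, "V": m.V,
            "aspect_ratio": m.aspect_ratio,
            "contact_area": m.contact_area,
        })
    df = pd.DataFrame(rows)
    if len(df) >= 3:
        df["v"] = velocity_series(df["t"].to_numpy(), df["r"].to_numpy())
    else:
        df["v"] = np.nan
    return df
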