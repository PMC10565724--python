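"""The governing cell model: coupled evolution of ρ (cell) and p⃗ (actin).

∂ρ/∂t = D_ρ∇²ρ − α p⃗·∇ρ − κ(x)∇Φ·∇ρ − λρΦ² + ω·ρ(1−ρ)(ρ−(1−δ))
∂p⃗/∂t = D_p∇²p⃗ − τ₁⁻¹p⃗ − γ(∇ρ·p⃗)p⃗ − Φ²p⃗ − β·S

with the actin source

    S = e^(−ζ|c|) · ( Ψ[(1−θ)P̂(∇ρ) + θ∇ρ] + εχ ∇ρ )

and the local interface setpoint δ = ½ + μ(V₀−V) − σ|p⃗|².  Because ∇ρ
points *into* the cell, −β·S drives polymerization along the outward
normal; near a substrate the source splits between pushing into it (θ∇ρ)
and turning parallel to it (the rotated P̂ component), and everywhere on
the membrane the tension factor e^(−ζ|c|) exponentially *reduces*
polymerization wherever the membrane is strongly bent (high |c|) while
the cell is globally stretched (ζ = f₀T·(A−A₀)/A₀, floored at 0) — the
model's curvature-sensing ingredient.  The penalty is decay-only: both
protrusive bulges and tightly conforming contact membrane are penalized,
while near-minimal (saddle) membrane with |c| ≈ 0 is not.

Sign conventions (each pinned by a unit test of its physical contract):
advection translates the cell along p⃗; −κ∇Φ·∇ρ rewards conformal
contact (the term is positive in the gap between an approaching membrane
and the substrate, extending ρ toward it); −λρΦ² expels the cell from
the solid; the cubic advances the interface for δ > ½ and retracts it
for δ < ½, reducing to the Allen–Cahn form ρ(1−ρ)(ρ−½) at δ = ½.

Explicit Euler in time, restricted each step to the active region (the
ρ ≥ 0.01 support plus a 1 μm buffer); fields outside are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from . import fields as F
from .grid import GridSpec
from .params import ModelParams
from .substrates import SubstrateField

__all__ = [
    "CellState",
    "active_region",
    "delta_field",
    "p_hat_rotate",
    "zeta_value",
    "actin_source",
    "rho_rhs",
    "p_rhs",
    "step",
    "initialize_cell",
    "run_free_cell_reference",
    "run_simulation",
    "Trajectory",
]

#: ρ threshold defining the active-region support
ACTIVE_RHO = 0.01
#: buffer dilation beyond the support, μm
ACTIVE_BUFFER = 1.0
#: |∇Φ| below which the rotation operator degenerates to the identity
PHAT_NORM_FLOOR = 1e-6
#: clamp on the tension exponent ζ|c| (overflow guard; physical values ≲ 1)
TENSION_EXP_CLAMP = 10.0


@dataclass
class CellState:
    """Cell fields on a grid plus the reference volume and surface area."""

    grid: GridSpec
    rho: np.ndarray
    p: np.ndarray
    V0: float
    A0: float
    t: float = 0.0

    def __post_init__(self) -> None:
        self.grid.check_scalar(self.rho, "rho")
        self.grid.check_vector(self.p, "p")

    def copy(self) -> "CellState":
        return CellState(self.grid, self.rho.copy(), self.p.copy(),
                         self.V0, self.A0, self.t)

    @property
    def alive(self) -> bool:
        return bool(np.any(self.rho >= 0.5))


_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def active_region(rho: np.ndarray, grid: GridSpec,
                  buffer: float = ACTIVE_BUFFER) -> np.ndarray:
    """Boolean mask: every voxel with ρ ≥ 0.01 plus a ``buffer`` μm dilation."""
    support = rho >= ACTIVE_RHO
    n_iter = max(1, int(round(buffer / grid.spacing)))
    return ndimage.binary_dilation(support, _STRUCT6, iterations=n_iter)


def delta_field(rho: np.ndarray, p: np.ndarray, V0: float,
                grid: GridSpec, params: ModelParams) -> np.ndarray:
    """Interface setpoint δ = ½ + μ(V₀ − V) − σ|p⃗|².

    Excess volume lowers δ globally (interface retracts); local
    contractility σ|p⃗|² lowers it locally.
    """
    V = F.cell_volume(rho, grid)
    p2 = np.einsum("...i,...i->...", p, p)
    return 0.5 + params.mu * (V0 - V) - params.sigma * p2


def p_hat_rotate(grad_rho: np.ndarray, grad_phi: np.ndarray) -> np.ndarray:
    """Rotate ∇ρ to its substrate-tangential direction, keeping |∇ρ|.

    Broadcasts over leading axes.  Where |∇Φ| < 1e-6 (no substrate
    nearby) the input is returned unchanged; where ∇ρ is exactly normal
    to the surface the result is the zero vector.
    """
    grad_rho = np.asarray(grad_rho, dtype=float)
    grad_phi = np.asarray(grad_phi, dtype=float)
    gp_norm = np.linalg.norm(grad_phi, axis=-1, keepdims=True)
    safe = np.where(gp_norm > 0, gp_norm, 1.0)
    n_hat = grad_phi / safe
    v_dot_n = np.sum(grad_rho * n_hat, axis=-1, keepdims=True)
    tang = grad_rho - v_dot_n * n_hat
    t_norm = np.linalg.norm(tang, axis=-1, keepdims=True)
    v_norm = np.linalg.norm(grad_rho, axis=-1, keepdims=True)
    rotated = np.where(
        t_norm > 1e-12, tang * (v_norm / np.where(t_norm > 0, t_norm, 1.0)), 0.0
    )
    return np.where(gp_norm < PHAT_NORM_FLOOR, grad_rho, rotated)


def zeta_value(A: float, A0: float, params: ModelParams) -> float:
    """Nondimensional membrane stretch ζ = f₀T·(A − A₀)/A₀."""
    return params.f0T * (A - A0) / A0


def actin_source(
    rho: np.ndarray,
    psi: np.ndarray,
    grad_rho: np.ndarray,
    zeta: float,
    c_field: np.ndarray,
    params: ModelParams,
    grad_phi: np.ndarray,
) -> np.ndarray:
    """S = e^(−ζ|c|) · ( Ψ[(1−θ)P̂(∇ρ) + θ∇ρ] + εχ∇ρ ).

    The bare ε-term is added independently of Ψ: membrane tension acts
    on the whole membrane, not only where the cell touches a surface.
    The tension factor e^(−ζ|c|) gates the *entire* polymerization
    source — this is what curtails the leading edge pressed against a
    high-curvature feature.  The exponent is decay-only (ζ floored at 0,
    |c| unsigned), so the factor never exceeds 1.
    """
    th = params.theta
    rotated = p_hat_rotate(grad_rho, grad_phi)
    chi = F.membrane_indicator(rho, params.G)
    expo = np.clip(-max(zeta, 0.0) * np.abs(c_field),
                   -TENSION_EXP_CLAMP, 0.0)
    damp = np.exp(expo)[..., None]
    bare = (
        psi[..., None] * ((1.0 - th) * rotated + th * grad_rho)
        + (params.epsilon * chi)[..., None] * grad_rho
    )
    return damp * bare


def rho_rhs(state: CellState, substrate: SubstrateField,
            params: ModelParams) -> np.ndarray:
    """∂ρ/∂t per the governing equation (see module docstring)."""
    grid = state.grid
    rho, p = state.rho, state.p
    grad_rho = F.gradient(rho, grid)
    lap = F.laplacian(rho, grid)
    delta = delta_field(rho, p, state.V0, grid, params)
    adv = np.einsum("...i,...i->...", p, grad_rho)
    adh = np.einsum("...i,...i->...", substrate.grad_phi(), grad_rho)
    out = (
        params.D_rho * lap
        - params.alpha * adv
        - substrate.kappa_map * adh
        - params.lambda_ * rho * substrate.phi**2
        + params.omega * rho * (1.0 - rho) * (rho - (1.0 - delta))
    )
    if not np.all(np.isfinite(out)):
        _diagnose_nan(
            {"laplacian": lap, "advection": adv, "adhesion": adh,
             "delta": delta, "rho": rho},
        )
    return out


def p_rhs(state: CellState, substrate: SubstrateField, params: ModelParams,
          zeta: float | None = None,
          c_field: np.ndarray | None = None) -> np.ndarray:
    """∂p⃗/∂t per the governing equation (see module docstring)."""
    grid = state.grid
    rho, p = state.rho, state.p
    grad_rho = F.gradient(rho, grid)
    if c_field is None:
        c_field = F.interface_curvature(rho, grid)
    if zeta is None:
        zeta = zeta_value(F.surface_area(rho, grid), state.A0, params)
    S = actin_source(rho, substrate.psi, grad_rho, zeta, c_field, params,
                     substrate.grad_phi())
    lap_p = np.stack(
        [F.laplacian(p[..., i], grid) for i in range(3)], axis=-1
    )
    g_dot_p = np.einsum("...i,...i->...", grad_rho, p)
    out = (
        params.D_p * lap_p
        - params.tau1_inv * p
        - params.gamma * g_dot_p[..., None] * p
        - (substrate.phi**2)[..., None] * p
        - params.beta * S
    )
    if not np.all(np.isfinite(out)):
        _diagnose_nan({"lap_p": lap_p, "source": S, "g_dot_p": g_dot_p})
    return out


def _diagnose_nan(named: dict) -> None:
    bad = [k for k, v in named.items() if not np.all(np.isfinite(v))]
    raise FloatingPointError(
        f"non-finite values in term(s): {', '.join(bad) or 'unknown'}"
    )


def step(state: CellState, substrate: SubstrateField, params: ModelParams,
         mask: np.ndarray | None = None) -> CellState:
    """One explicit-Euler update restricted to the active region (in place).

    Recomputes A, ζ, χ and c for the current fields, advances ρ and p⃗ by
    ``params.dt`` on the active mask only (fields outside unchanged), and
    advances t.  Aborts with a stability diagnostic if |ρ| exceeds 2.
    """
    grid = state.grid
    if mask is None:
        mask = active_region(state.rho, grid)
    c_field = F.interface_curvature(state.rho, grid)
    zeta = zeta_value(F.surface_area(state.rho, grid), state.A0, params)
    drho = rho_rhs(state, substrate, params)
    dp = p_rhs(state, substrate, params, zeta=zeta, c_field=c_field)
    state.rho[mask] += params.dt * drho[mask]
    state.p[mask] += params.dt * dp[mask]
    state.t += params.dt
    m = float(np.max(np.abs(state.rho)))
    if m > 2.0:
        raise FloatingPointError(
            f"integration unstable: max|rho| = {m:.3g} > 2 at t = {state.t:.3f}"
        )
    return state


# --------------------------------------------------------------------------
# initialization
# --------------------------------------------------------------------------

def initialize_cell(
    center: tuple[float, float, float],
    grid: GridSpec,
    edge: float = 17.0,
    p_init_dir: tuple[float, float, float] = (0.0, 0.0, -1.0),
    substrate: SubstrateField | None = None,
    A0: float | None = None,
    shape: str = "cube",
) -> CellState:
    """Place the initial cell: a 17 μm cube (or equal-volume sphere).

    ρ = 1 inside, 0 outside; p⃗ = unit ``p_init_dir`` at every voxel with
    ρ > 0 (unit magnitude reproduces physiologic migration speed).  V₀ is
    recorded from the placed field; A₀ defaults to the free-cell
    reference (computed on demand if not supplied).  Raises if the cell
    overlaps the substrate (Φ > 0.01 anywhere under it).
    """
    x, y, z = grid.meshgrid()
    cx, cy, cz = center
    if shape == "cube":
        h = edge / 2.0
        # half-open bounds: the cube always covers exactly edge/spacing
        # voxel centers per axis regardless of sub-voxel placement
        inside = (
            (x >= cx - h) & (x < cx + h)
            & (y >= cy - h) & (y < cy + h)
            & (z >= cz - h) & (z < cz + h)
        )
    elif shape == "sphere":
        r = edge * (3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)  # equal volume
        inside = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 < r**2
    else:
        raise ValueError(f"unknown initial shape {shape!r}")
    inside = np.broadcast_to(inside, grid.shape)
    rho = inside.astype(float)
    if substrate is not None and np.any(substrate.phi[inside] > 0.01):
        raise ValueError(
            "initial cell overlaps the substrate (phi > 0.01 inside the cell)"
        )
    d = np.asarray(p_init_dir, float)
    norm = np.linalg.norm(d)
    if norm > 0:
        d = d / norm
    p = np.zeros(grid.shape + (3,))
    p[inside] = d
    V0 = F.cell_volume(rho, grid)
    if A0 is None:
        A0 = run_free_cell_reference(
            ModelParams(dx=grid.spacing,
                        dt=min(0.01, 0.19 * grid.spacing**2))
        )[0]
    return CellState(grid, rho, p, V0=V0, A0=A0, t=0.0)


_FREE_CELL_CACHE: dict = {}


def run_free_cell_reference(
    params: ModelParams,
    edge: float = 17.0,
    tol: float = 1e-6,
    max_time: float = 500.0,
    use_fast_path: bool = True,
) -> tuple[float, CellState]:
    """Relax a free cell (p⃗ ≡ 0, no substrate) to its stationary shape.

    Integrates the ρ equation alone until max|∂ρ/∂t| < ``tol``; returns
    the resulting surface area A₀ (the minimum membrane area, reference
    for the stretch ζ) and the steady state.  Results are cached per
    (dx, dt, edge, relevant constants).
    """
    key = (params.dx, params.dt, edge, params.D_rho, params.mu, params.tau1_inv)
    if key in _FREE_CELL_CACHE:
        A0, cached = _FREE_CELL_CACHE[key]
        return A0, cached.copy()
    n = int(round((edge + 14.0) / params.dx))
    grid = GridSpec((n, n, n), params.dx)
    c = n * params.dx / 2.0
    state = initialize_cell((c, c, c), grid, edge=edge,
                            p_init_dir=(0, 0, 0), A0=0.0)
    substrate = SubstrateField.empty(grid)
    if use_fast_path:
        from ._engine import Engine

        eng = Engine(state, substrate, params, freeze_p=True)
        converged = eng.run_until_stationary(tol=tol, max_time=max_time)
        state = eng.state
    else:
        converged = False
        n_steps = int(round(max_time / params.dt))
        mask = active_region(state.rho, grid)
        for i in range(n_steps):
            if i % 20 == 0:
                mask = active_region(state.rho, grid)
            drho = rho_rhs(state, substrate, params)
            state.rho[mask] += params.dt * drho[mask]
            state.t += params.dt
            if i % 50 == 0 and float(np.max(np.abs(drho))) < tol:
                converged = True
                break
    if not converged:
        raise RuntimeError(
            f"free cell failed to reach max|drho/dt| < {tol} "
            f"within {max_time} time units"
        )
    A0 = F.surface_area(state.rho, grid)
    state.A0 = A0
    _FREE_CELL_CACHE[key] = (A0, state.copy())
    return A0, state


# --------------------------------------------------------------------------
# trajectory running
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Metrics time series plus optional field snapshots from one run."""

    times: list = dc_field(default_factory=list)
    metrics: list = dc_field(default_factory=list)  # ShapeMetrics per sample
    snapshots: dict = dc_field(default_factory=dict)  # t -> (rho, p)
    steady_state_time: float | None = None
    termination: str = "t_end"
    params: ModelParams | None = None
    substrate_meta: dict = dc_field(default_factory=dict)
    final_state: CellState | None = None

    def metric(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.metrics])

    @property
    def r(self) -> np.ndarray:
        return self.metric("displacement")


def run_simulation(
    state: CellState,
    substrate: SubstrateField,
    params: ModelParams,
    t_end: float | None = None,
    sample_every: float = 1.0,
    snapshot_every: float | None = None,
    detect_steady: bool = True,
    steady_centroid_tol: float = 1e-3,
    steady_rho_tol: float = 1e-4,
    steady_patience: int = 10,
    progress: bool = False,
) -> Trajectory:
    """Integrate a cell/substrate system and record shape metrics.

    Deterministic for a given initial state, substrate and parameters
    (the model has no stochastic terms).  Metrics are sampled every
    ``sample_every`` time units; optional full-field snapshots every
    ``snapshot_every``.  A steady state is declared when, for
    ``steady_patience`` consecutive unit-time checks, the centroid moved
    less than ``steady_centroid_tol`` μm and max|Δρ| < ``steady_rho_tol``
    — the operational form of "any measurable movement or shape change
    ceases".
    """
    from . import analytics
    from ._engine import Engine

    if t_end is None:
        t_end = params.t_end
    eng = Engine(state, substrate, params)
    traj = Trajectory(params=params, substrate_meta=dict(substrate.meta))

    def sample():
        m = analytics.snapshot_metrics(
            eng.state, substrate, params,
            origin=traj.metrics[0].centroid if traj.metrics else None,
        )
        traj.times.append(eng.state.t)
        traj.metrics.append(m)

    sample()
    if snapshot_every is not None:
        traj.snapshots[state.t] = (state.rho.copy(), state.p.copy())
    n_per_sample = max(1, int(round(sample_every / params.dt)))
    quiet = 0
    last_centroid = traj.metrics[0].centroid
    next_snap = (state.t + snapshot_every) if snapshot_every else np.inf
    while eng.state.t < t_end - 0.5 * params.dt:
        max_drho = eng.advance(n_per_sample)
        sample()
        if progress:
            m = traj.metrics[-1]
            print(f"t={eng.state.t:8.2f} r={m.displacement:7.3f} "
                  f"V={m.V:8.1f} A={m.A:8.1f} pz={m.mean_pz:+.3f}")
        if eng.state.t >= next_snap - 0.5 * params.dt:
            traj.snapshots[eng.state.t] = (
                eng.state.rho.copy(), eng.state.p.copy())
            next_snap += snapshot_every
        centroid = traj.metrics[-1].centroid
        moved = float(np.linalg.norm(np.asarray(centroid)
                                     - np.asarray(last_centroid)))
        last_centroid = centroid
        if detect_steady:
            if (moved < steady_centroid_tol * sample_every
                    and max_drho * sample_every < steady_rho_tol):
                quiet += 1
            else:
                quiet = 0
            if quiet >= steady_patience:
                traj.steady_state_time = eng.state.t
                traj.termination = "steady-state"
                break
    traj.final_state = eng.state
    if snapshot_every is not None and eng.state.t not in traj.snapshots:
        traj.snapshots[eng.state.t] = (
            eng.state.rho.copy(), eng.state.p.copy())
    return traj
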