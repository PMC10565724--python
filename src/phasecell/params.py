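"""Model constants and integration controls.

All values are nondimensional; the model's intrinsic scales are 1 length
unit = 1 μm and 1 time unit = 10 s (set by the actin depolymerization rate
τ₁⁻¹ and the actin diffusivity D_p).  Defaults are the common tabulated constants
of the underlying cell-migration framework.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

__all__ = ["ModelParams", "TIME_SCALE_S", "LENGTH_SCALE_UM"]

#: seconds per nondimensional time unit
TIME_SCALE_S = 10.0
#: μm per nondimensional length unit
LENGTH_SCALE_UM = 1.0


@dataclass(frozen=True)
class ModelParams:
    """Constants of the cell model plus discretization controls.

    Parameters
    ----------
    D_rho, D_phi, D_psi, D_p
        Diffusivities of the cell boundary, substrate boundary, substrate
        sensing boundary, and actin field.
    alpha
        Advection of the cell with actin.
    kappa_default
        Cell–substrate adhesion strength κ (1–3 typical; 5 on adhesive
        strips).  Spatially varying κ(x) maps override this.
    lambda_
        Exclusion of the cell from the substrate.
    D_p, tau1_inv
        Actin diffusion and depolymerization rate (τ₁⁻¹ = 0.1 ⇒ 10 s
        time scale).
    beta
        Actin generation (prefactor of the whole polymerization source).
    gamma
        Symmetry breaking of myosin motors at the cell rear.
    sigma
        Acto-myosin contraction weight on |p⃗|² in δ.
    mu
        Strength of (weak) volume conservation.
    theta
        Ratio of substrate-pushing (∇ρ) vs substrate-turning (P̂∇ρ)
        polymerization, 0 < θ < 1.
    epsilon
        Weight of the bare membrane polymerization term εχ∇ρ in the source.
    omega
        Strength of the interface cubic ω·ρ(1−ρ)(ρ−(1−δ)); sets the
        diffuse-interface width w₀ = 2√(2·D_ρ/ω) (≈ 1 μm at the
        default), the membrane sharpness the curvature term acts on and
        the stiffness of the weak volume constraint.
    G
        Membrane-indicator steepness (membrane width).
    T_memb, f0
        Membrane extensibility and the actin-monomer/thermal-energy
        constant; they enter only as the product f0·T in the membrane
        stretch ζ = f0·T·(A−A0)/A0 that scales the curvature penalty
        e^(−ζ|c|) on the polymerization source.  Setting epsilon = 0 and
        f0 = 0 together disables the membrane-tension extension entirely
        (recovering the tension-free model).
    dx, dt
        Lattice spacing (μm) and explicit-Euler time step.
    t_end
        Total nondimensional simulation time (500 units = 5000 s).
    """

    D_rho: float = 1.0
    D_phi: float = 0.5
    D_psi: float = 4.0
    D_p: float = 0.2
    alpha: float = 2.0
    kappa_default: float = 1.0
    lambda_: float = 5.0
    tau1_inv: float = 0.1
    beta: float = 3.0
    gamma: float = 0.05
    sigma: float = 0.2
    mu: float = 0.001
    theta: float = 0.4
    omega: float = 8.0
    epsilon: float = 0.34
    G: float = 14.0
    T_memb: float = 1.0
    f0: float = 10.0
    dx: float = 0.5
    dt: float = 0.01
    t_end: float = 500.0

    #: explicit-Euler safety factor: dt must be <= STABILITY_FACTOR * dx² / max D
    STABILITY_FACTOR = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < 1.0):
            raise ValueError(f"theta must lie in (0, 1), got {self.theta}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.G <= 0:
            raise ValueError(f"G must be > 0, got {self.G}")
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be > 0")
        bound = self.dt_stability_bound()
        if self.dt > bound:
            raise ValueError(
                f"dt={self.dt} exceeds the explicit-Euler stability bound "
                f"{bound:.4g} (min of {self.STABILITY_FACTOR}*dx^2/max(D_rho, "
                f"D_p, 1) and 2*{self.STABILITY_FACTOR}/omega with "
                f"dx={self.dx}, omega={self.omega}); reduce dt or coarsen dx"
            )

    def dt_stability_bound(self) -> float:
        max_d = max(self.D_rho, self.D_p, 1.0)
        diffusive = self.STABILITY_FACTOR * self.dx**2 / max_d
        reactive = 2.0 * self.STABILITY_FACTOR / max(self.omega, 1e-12)
        return min(diffusive, reactive)

    @property
    def f0T(self) -> float:
        """Composite membrane-stretch coefficient f0·T used in ζ."""
        return self.f0 * self.T_memb

    @property
    def duration_seconds(self) -> float:
        """Dimensional run duration: t_end × 10 s per time unit."""
        return self.t_end * TIME_SCALE_S

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)
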