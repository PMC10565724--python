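"""Driver around the fused step kernel: buffers, active mask, stability."""

from __future__ import annotations

import numpy as np

from . import _kernels
from .dynamics import active_region
from .params import ModelParams
from .substrates import SubstrateField


class Engine:
    """Holds working buffers for a run and advances the state in place.

    The active-region mask (ρ ≥ 0.01 support plus 1 μm buffer) is
    refreshed every ``mask_every`` steps; the cell moves far less than
    the buffer width in that interval at stable time steps.
    """

    def __init__(
        self,
        state,
        substrate: SubstrateField,
        params: ModelParams,
        freeze_p: bool = False,
        full_volume: bool = False,
        mask_every: int = 10,
    ) -> None:
        grid = state.grid
        if substrate.grid.shape != grid.shape:
            raise ValueError(
                f"substrate grid {substrate.grid.shape} does not match "
                f"cell grid {grid.shape}"
            )
        self.state = state
        self.substrate = substrate
        self.params = params
        self.freeze_p = freeze_p
        self.full_volume = full_volume
        self.mask_every = mask_every
        # keyed to absolute step count so checkpoint/resume is step-identical
        self._steps_done = int(round(state.t / params.dt))

        self.rho = np.ascontiguousarray(state.rho)
        p = state.p
        self.px = np.ascontiguousarray(p[..., 0])
        self.py = np.ascontiguousarray(p[..., 1])
        self.pz = np.ascontiguousarray(p[..., 2])
        self._new = [np.empty_like(self.rho) for _ in range(4)]
        self._work = [np.empty_like(self.rho) for _ in range(4)]

        gphi = substrate.grad_phi()
        self.phi = np.ascontiguousarray(substrate.phi)
        self.phi2 = np.ascontiguousarray(substrate.phi**2)
        self.gpx = np.ascontiguousarray(gphi[..., 0])
        self.gpy = np.ascontiguousarray(gphi[..., 1])
        self.gpz = np.ascontiguousarray(gphi[..., 2])
        self.psi = np.ascontiguousarray(substrate.psi)
        self.kappa = np.ascontiguousarray(substrate.kappa_map, dtype=float)
        self._refresh_mask()
        self.A = None
        self.V = None

    def _refresh_mask(self) -> None:
        if self.full_volume:
            self.active = np.ones(self.rho.shape, dtype=np.uint8)
        else:
            self.active = active_region(
                self.rho, self.state.grid
            ).astype(np.uint8)

    def _sync_state(self) -> None:
        self.state.rho = self.rho
        p = np.stack([self.px, self.py, self.pz], axis=-1)
        self.state.p = p

    def advance(self, n_steps: int) -> float:
        """Run ``n_steps`` fused Euler steps; returns max|∂ρ/∂t| of the last."""
        p = self.params
        max_rhs = 0.0
        for _ in range(n_steps):
            if self._steps_done % self.mask_every == 0:
                self._refresh_mask()
            nrho, npx, npy, npz = self._new
            gx, gy, gz, gnorm = self._work
            A, V, max_rhs, max_abs = _kernels.fused_step(
                self.rho, self.px, self.py, self.pz,
                nrho, npx, npy, npz,
                gx, gy, gz, gnorm,
                self.phi, self.phi2, self.gpx, self.gpy, self.gpz,
                self.psi, self.kappa,
                self.active,
                p.dx, p.dt,
                p.D_rho, p.D_p, p.alpha, p.lambda_, p.beta, p.gamma,
                p.sigma, p.mu, p.tau1_inv,
                p.theta, p.omega, p.epsilon, p.G, p.f0T,
                self.state.V0, self.state.A0,
                self.freeze_p,
            )
            self.A, self.V = A, V
            self._new = [self.rho, self.px, self.py, self.pz]
            self.rho, self.px, self.py, self.pz = nrho, npx, npy, npz
            self.state.t += p.dt
            self._steps_done += 1
            if max_abs > 2.0:
                self._sync_state()
                raise FloatingPointError(
                    f"integration unstable: max|rho| = {max_abs:.3g} > 2 "
                    f"at t = {self.state.t:.3f}"
                )
        self._sync_state()
        return max_rhs

    def run_until_stationary(
        self, tol: float = 1e-6, max_time: float = 500.0, check_every: int = 50
    ) -> bool:
        t0 = self.state.t
        while self.state.t - t0 < max_time:
            max_rhs = self.advance(check_every)
            if max_rhs < tol:
                return True
        return False
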