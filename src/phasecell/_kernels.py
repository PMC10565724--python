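"""Fused numba stencil kernel for the explicit-Euler step.

One call performs a full ρ/p⃗ update: a first pass computes ∇ρ, |∇ρ|,
the global surface area A and volume V (and copies the fields through),
then a second pass over the active region evaluates every term of the
governing equations and writes the Euler update.  Mirror (zero-flux)
closure is applied by clamping neighbor indices, matching the
edge-padded numpy operators in ``fields`` exactly; an equivalence test
pins this kernel to the per-term numpy implementation in ``dynamics``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

EPS_NORM = 1e-8
GRAD_FLOOR = 1e-6
PHAT_NORM_FLOOR = 1e-6
TENSION_EXP_CLAMP = 10.0


@njit(cache=True, fastmath=False)
def fused_step(
    rho, px, py, pz,
    nrho, npx, npy, npz,
    gx, gy, gz, gnorm,
    phi, phi2, gpx, gpy, gpz, psi, kappa,
    active,
    h, dt,
    D_rho, D_p, alpha, lam, beta, gamma, sigma, mu, tau1_inv,
    theta, omega, eps_w, G, f0T,
    V0, A0,
    freeze_p,
):
    nx, ny, nz = rho.shape
    inv2h = 0.5 / h
    invh2 = 1.0 / (h * h)
    dV = h * h * h

    # ---- pass A: gradient of rho, surface area, volume, copy-through ----
    A = 0.0
    V = 0.0
    for i in range(nx):
        im = i - 1 if i > 0 else 0
        ip = i + 1 if i < nx - 1 else nx - 1
        for j in range(ny):
            jm = j - 1 if j > 0 else 0
            jp = j + 1 if j < ny - 1 else ny - 1
            for k in range(nz):
                km = k - 1 if k > 0 else 0
                kp = k + 1 if k < nz - 1 else nz - 1
                a = (rho[ip, j, k] - rho[im, j, k]) * inv2h
                b = (rho[i, jp, k] - rho[i, jm, k]) * inv2h
                c = (rho[i, j, kp] - rho[i, j, km]) * inv2h
                gx[i, j, k] = a
                gy[i, j, k] = b
                gz[i, j, k] = c
                gn = np.sqrt(a * a + b * b + c * c)
                gnorm[i, j, k] = gn
                A += gn
                V += rho[i, j, k]
                nrho[i, j, k] = rho[i, j, k]
                npx[i, j, k] = px[i, j, k]
                npy[i, j, k] = py[i, j, k]
                npz[i, j, k] = pz[i, j, k]
    A *= dV
    V *= dV
    zeta = f0T * (A - A0) / A0 if A0 > 0.0 else 0.0
    if zeta < 0.0:
        zeta = 0.0
    dv_glob = 0.5 + mu * (V0 - V)

    # ---- pass B: all terms, Euler update on the active region ----------
    max_rhs = 0.0
    max_abs_rho = 0.0
    for i in range(nx):
        im = i - 1 if i > 0 else 0
        ip = i + 1 if i < nx - 1 else nx - 1
        for j in range(ny):
            jm = j - 1 if j > 0 else 0
            jp = j + 1 if j < ny - 1 else ny - 1
            for k in range(nz):
                if not active[i, j, k]:
                    continue
                km = k - 1 if k > 0 else 0
                kp = k + 1 if k < nz - 1 else nz - 1

                r0 = rho[i, j, k]
                lap_rho = (
                    rho[ip, j, k] + rho[im, j, k]
                    + rho[i, jp, k] + rho[i, jm, k]
                    + rho[i, j, kp] + rho[i, j, km]
                    - 6.0 * r0
                ) * invh2

                a = gx[i, j, k]
                b = gy[i, j, k]
                c = gz[i, j, k]
                gn = gnorm[i, j, k]

                # curvature: divergence of the regularized unit gradient
                if gn < GRAD_FLOOR:
                    curv = 0.0
                else:
                    curv = (
                        gx[ip, j, k] / (gnorm[ip, j, k] + EPS_NORM)
                        - gx[im, j, k] / (gnorm[im, j, k] + EPS_NORM)
                        + gy[i, jp, k] / (gnorm[i, jp, k] + EPS_NORM)
                        - gy[i, jm, k] / (gnorm[i, jm, k] + EPS_NORM)
                        + gz[i, j, kp] / (gnorm[i, j, kp] + EPS_NORM)
                        - gz[i, j, km] / (gnorm[i, j, km] + EPS_NORM)
                    ) * inv2h

                p0x = px[i, j, k]
                p0y = py[i, j, k]
                p0z = pz[i, j, k]
                p2 = p0x * p0x + p0y * p0y + p0z * p0z
                delta = dv_glob - sigma * p2

                adv = p0x * a + p0y * b + p0z * c
                adh = gpx[i, j, k] * a + gpy[i, j, k] * b + gpz[i, j, k] * c
                rhs_rho = (
                    D_rho * lap_rho
                    - alpha * adv
                    - kappa[i, j, k] * adh
                    - lam * r0 * phi2[i, j, k]
                    + omega * r0 * (1.0 - r0) * (r0 - (1.0 - delta))
                )
                nrho[i, j, k] = r0 + dt * rhs_rho
                ar = abs(rhs_rho)
                if ar > max_rhs:
                    max_rhs = ar
                an = abs(nrho[i, j, k])
                if an > max_abs_rho:
                    max_abs_rho = an

                if freeze_p:
                    continue

                # P-hat rotation of grad rho about the substrate normal
                npx_ = gpx[i, j, k]
                npy_ = gpy[i, j, k]
                npz_ = gpz[i, j, k]
                np_norm = np.sqrt(npx_ * npx_ + npy_ * npy_ + npz_ * npz_)
                if np_norm < PHAT_NORM_FLOOR:
                    rx, ry, rz = a, b, c
                else:
                    nhx = npx_ / np_norm
                    nhy = npy_ / np_norm
                    nhz = npz_ / np_norm
                    vdn = a * nhx + b * nhy + c * nhz
                    tx = a - vdn * nhx
                    ty = b - vdn * nhy
                    tz = c - vdn * nhz
                    tn = np.sqrt(tx * tx + ty * ty + tz * tz)
                    if tn > 1e-12:
                        scale = gn / tn
                        rx, ry, rz = tx * scale, ty * scale, tz * scale
                    else:
                        rx, ry, rz = 0.0, 0.0, 0.0

                th = np.tanh(G * (r0 - 0.5))
                chi = 1.0 - th * th
                expo = -zeta * abs(curv)
                if expo < -TENSION_EXP_CLAMP:
                    expo = -TENSION_EXP_CLAMP
                damp = np.exp(expo)
                wt = eps_w * chi
                ps = psi[i, j, k]
                sx = damp * (ps * ((1.0 - theta) * rx + theta * a) + wt * a)
                sy = damp * (ps * ((1.0 - theta) * ry + theta * b) + wt * b)
                sz = damp * (ps * ((1.0 - theta) * rz + theta * c) + wt * c)

                lap_px = (
                    px[ip, j, k] + px[im, j, k] + px[i, jp, k] + px[i, jm, k]
                    + px[i, j, kp] + px[i, j, km] - 6.0 * p0x
                ) * invh2
                lap_py = (
                    py[ip, j, k] + py[im, j, k] + py[i, jp, k] + py[i, jm, k]
                    + py[i, j, kp] + py[i, j, km] - 6.0 * p0y
                ) * invh2
                lap_pz = (
                    pz[ip, j, k] + pz[im, j, k] + pz[i, jp, k] + pz[i, jm, k]
                    + pz[i, j, kp] + pz[i, j, km] - 6.0 * p0z
                ) * invh2

                gdp = a * p0x + b * p0y + c * p0z
                decay = tau1_inv + gamma * gdp + phi2[i, j, k]
                npx[i, j, k] = p0x + dt * (
                    D_p * lap_px - decay * p0x - beta * sx
                )
                npy[i, j, k] = p0y + dt * (
                    D_p * lap_py - decay * p0y - beta * sy
                )
                npz[i, j, k] = p0z + dt * (
                    D_p * lap_pz - decay * p0z - beta * sz
                )

    return A, V, max_rhs, max_abs_rho
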