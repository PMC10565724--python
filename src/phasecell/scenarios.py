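"""Canonical study scenarios: substrate + placement + parameters.

Each scenario reproduces one of the cell–substrate systems the model was
built to study, at desk-scale problem sizes (1 μm lattice, boxes up to
~80–90 μm, horizons of 150–300 time units):

* ``hemisphere`` / ``hemisphere-notension`` — validation case: a cell
  landing just off the apex of a 12 μm hemispherical bump, with the
  membrane-tension term on or off.  Without tension the cell recenters
  and settles atop the bump; with tension it refuses to settle there.
* ``strip12`` / ``strip20`` / ``strip50`` — flat substrate with a
  centered adhesive strip (κ = 5 on, 1 off); elongation along the strip
  decreases with strip width.
* ``ptm3`` — the simplified particle-templated-material interconnect:
  three stacked spherical pores, the cell seeded low in the middle
  pocket with p⃗ = −e_z so it interrogates the lower window.
* ``hyperboloid`` — channel with the same maximum/minimum diameters as
  ``ptm3`` but the gentle throat curvature of a one-sheet hyperboloid.
* ``btm`` — bijel-templated material: a bicontinuous spinodal structure,
  the cell seeded into a snug pore in contact with the internal
  (saddle-curved) surfaces.

"Tension off" disables both pieces of the membrane-tension extension
(ε = 0 and f₀ = 0), recovering the tension-free predecessor model.
"""

from __future__ import annotations

import numpy as np

from . import dynamics as dyn
from . import substrates as subf
from .params import ModelParams

__all__ = ["SCENARIOS", "build_scenario", "scenario_params",
           "lowest_axial_placement", "snuggest_pore_placement"]

#: defaults shared by all desk-scale scenario runs (1 μm lattice)
SCENARIO_DX = 1.0
SCENARIO_DT = 0.02


def scenario_params(tension: bool = True, **overrides) -> ModelParams:
    kw = dict(dx=SCENARIO_DX, dt=SCENARIO_DT)
    if not tension:
        kw.update(epsilon=0.0, f0=0.0)
    kw.update(overrides)
    return ModelParams(**kw)


def lowest_axial_placement(substrate, xy, z_lo, z_hi, A0, shape="sphere",
                           step=0.5):
    """Lowest overlap-free cell placement on a vertical line."""
    for z in np.arange(z_lo, z_hi + step / 2, step):
        try:
            return dyn.initialize_cell((xy[0], xy[1], z), substrate.grid,
                                       A0=A0, substrate=substrate, shape=shape)
        except ValueError:
            continue
    raise ValueError("no overlap-free placement found on the axis segment")


def snuggest_pore_placement(substrate, A0, shape="sphere", margin=16,
                            stride=4):
    """Feasible placement maximizing mean sensing field under the cell.

    Emulates seeding a cell into a porous material in contact with the
    internal surfaces: among all overlap-free positions on a coarse
    lattice, pick the one whose cell volume sees the most Ψ.
    """
    nx, ny, nz = substrate.grid.shape
    best = None
    for z in range(margin, nz - margin + 1, stride):
        for x in range(margin, nx - margin + 1, stride):
            for y in range(margin, ny - margin + 1, stride):
                try:
                    st = dyn.initialize_cell((x, y, z), substrate.grid, A0=A0,
                                             substrate=substrate, shape=shape)
                except ValueError:
                    continue
                score = float(substrate.psi[st.rho > 0.5].mean())
                if best is None or score > best[0]:
                    best = (score, (x, y, z))
    if best is None:
        raise ValueError("no overlap-free placement found in the pore space")
    return dyn.initialize_cell(best[1], substrate.grid, A0=A0,
                               substrate=substrate, shape=shape)


# --------------------------------------------------------------------------
# builders
# --------------------------------------------------------------------------

def _hemisphere(tension: bool, offset=(4.0, 2.0), radius=12.0,
                t_end=200.0, **overrides):
    params = scenario_params(tension=tension, **overrides)
    sub = subf.make_hemisphere_array(radius=radius, extent=(64, 64, 48))
    A0, _ = dyn.run_free_cell_reference(params)
    apex = (32.0, 32.0)
    state = dyn.initialize_cell(
        (apex[0] + offset[0], apex[1] + offset[1], 28.5), sub.grid,
        A0=A0, substrate=sub, shape="cube",
    )
    info = {"apex": apex, "bump_radius": radius}
    return sub, state, params, {"t_end": t_end}, info


def _strip(width: float, t_end=200.0, **overrides):
    params = scenario_params(**overrides)
    sub = subf.make_flat_with_strip(width, extent=(56, 72, 40))
    A0, _ = dyn.run_free_cell_reference(params)
    state = dyn.initialize_cell((28.0, 36.0, 17.0), sub.grid, A0=A0,
                                substrate=sub, shape="cube")
    return sub, state, params, {"t_end": t_end}, {"strip_width": width}


def _ptm3(sphere_diameter=36.0, t_end=250.0, **overrides):
    params = scenario_params(**overrides)
    sub = subf.make_ptm_interconnect(sphere_diameter, 0.325)
    A0, _ = dyn.run_free_cell_reference(params)
    cz = sub.meta["center"][2]
    spacing_z = sub.meta["center_spacing"]
    z_window = cz - spacing_z / 2.0
    c = sub.meta["center"]
    state = lowest_axial_placement(sub, (c[0], c[1]), z_window + 8.0,
                                   cz + 2.0, A0)
    info = {"z_window_lower": z_window, "z_window_upper": cz + spacing_z / 2,
            "pocket_center_z": cz,
            "window_diameter": sub.meta["window_diameter"]}
    return sub, state, params, {"t_end": t_end}, info


def _hyperboloid(d_max=36.0, d_min=None, length=40.0, t_end=200.0,
                 **overrides):
    params = scenario_params(**overrides)
    if d_min is None:
        d_min = 0.325 * d_max  # matched to the ptm3 window
    sub = subf.make_hyperboloid(d_max=d_max, d_min=d_min, length=length)
    A0, _ = dyn.run_free_cell_reference(params)
    z0 = sub.meta["throat_z"]
    c = sub.meta["center"]
    state = lowest_axial_placement(sub, (c[0], c[1]), z0 + 4.0,
                                   sub.grid.extent[2] - 12.0, A0)
    return sub, state, params, {"t_end": t_end}, {"throat_z": z0}


def _btm(extent=(80, 80, 80), stop_size=28.0, seed=3, t_end=250.0,
         **overrides):
    params = scenario_params(**overrides)
    sub = subf.make_btm(extent=extent, stop_size=stop_size, seed=seed)
    A0, _ = dyn.run_free_cell_reference(params)
    state = snuggest_pore_placement(sub, A0)
    return sub, state, params, {"t_end": t_end}, \
        {"domain_size": sub.meta["domain_size"]}


def _free(t_end=20.0, box=32, **overrides):
    """Substrate-free cell with the standard downward polarity kick."""
    params = scenario_params(**overrides)
    from .grid import GridSpec
    from .substrates import SubstrateField

    grid = GridSpec((box, box, box), SCENARIO_DX)
    sub = SubstrateField.empty(grid)
    A0, _ = dyn.run_free_cell_reference(params)
    c = box * SCENARIO_DX / 2.0
    state = dyn.initialize_cell((c, c, c), grid, A0=A0)
    return sub, state, params, {"t_end": t_end, "detect_steady": False}, {}


SCENARIOS = {
    "free": lambda **kw: _free(**kw),
    "hemisphere": lambda **kw: _hemisphere(True, **kw),
    "hemisphere-notension": lambda **kw: _hemisphere(False, **kw),
    "strip12": lambda **kw: _strip(12.0, **kw),
    "strip20": lambda **kw: _strip(20.0, **kw),
    "strip50": lambda **kw: _strip(50.0, **kw),
    "ptm3": lambda **kw: _ptm3(**kw),
    "hyperboloid": lambda **kw: _hyperboloid(**kw),
    "btm": lambda **kw: _btm(**kw),
}


def build_scenario(name: str, **overrides):
    """Build (substrate, initial state, params, run kwargs, info) by name."""
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        )
    return SCENARIOS[name](**overrides)
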