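"""Deterministic miniature substrates for tests and validation runs.

``fixture_suite`` materializes every study geometry at desk scale
(lattice 1 μm, boxes ≤ ~90 μm per side) into a directory of HDF5 files.
Identical seeds give byte-identical files (HDF5 written without
timestamps).
"""

from __future__ import annotations

from pathlib import Path

from . import io as pio
from . import substrates as subf

__all__ = ["fixture_suite", "FIXTURE_BUILDERS"]


FIXTURE_BUILDERS = {
    "hemisphere": lambda seed: subf.make_hemisphere_array(
        radius=12.0, extent=(64, 64, 48)),
    "strip20": lambda seed: subf.make_flat_with_strip(
        20.0, extent=(56, 72, 40)),
    "ptm3": lambda seed: subf.make_ptm_interconnect(36.0, 0.325),
    "hyperboloid": lambda seed: subf.make_hyperboloid(
        d_max=36.0, d_min=0.325 * 36.0, length=40.0),
    "btm": lambda seed: subf.make_btm(
        extent=(80, 80, 80), stop_size=28.0, seed=seed),
}


def fixture_suite(seed: int, outdir) -> dict[str, Path]:
    """Build every miniature scenario substrate; returns name → file path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, builder in FIXTURE_BUILDERS.items():
        sub = builder(seed)
        sub.meta.setdefault("seed", seed)
        path = outdir / f"{name}.h5"
        pio.save_substrate(path, sub)
        paths[name] = path
    return paths
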