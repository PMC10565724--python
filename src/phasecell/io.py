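"""File formats, checkpointing and run artifacts.

HDF5 for fields (self-describing, partial reads), CSV for metrics time
series, JSON for run manifests, binary STL for meshes.  All writes are
atomic (write to a temporary file in the same directory, then rename),
so an aborted run never leaves a corrupt artifact.  HDF5 files are
written without modification timestamps so identical content gives
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import h5py
import numpy as np

from . import __version__
from .grid import GridSpec
from .params import ModelParams, TIME_SCALE_S
from .substrates import SubstrateField

__all__ = [
    "save_fields",
    "load_fields",
    "save_substrate",
    "load_substrate",
    "save_checkpoint",
    "load_checkpoint",
    "write_manifest",
    "config_hash",
    "export_stl",
    "write_metrics_csv",
]


@contextmanager
def _atomic(path, mode="wb"):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".tmp")
    os.close(fd)
    try:
        yield tmp
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _write_grid_attrs(group, grid: GridSpec) -> None:
    group.attrs["shape"] = grid.shape
    group.attrs["spacing"] = grid.spacing
    group.attrs["boundary"] = grid.boundary


def _read_grid_attrs(group) -> GridSpec:
    return GridSpec(tuple(int(n) for n in group.attrs["shape"]),
                    float(group.attrs["spacing"]))


def save_fields(path, grid: GridSpec, **fields) -> None:
    """Write named arrays with grid metadata to an HDF5 file."""
    with _atomic(path) as tmp:
        with h5py.File(tmp, "w", track_order=True) as f:
            _write_grid_attrs(f, grid)
            for name, arr in fields.items():
                f.create_dataset(name, data=arr, compression="gzip",
                                 compression_opts=4, track_times=False)


def load_fields(path) -> tuple[GridSpec, dict]:
    with h5py.File(path, "r") as f:
        grid = _read_grid_attrs(f)
        fields = {name: f[name][()] for name in f.keys()}
    return grid, fields


def save_substrate(path, substrate: SubstrateField) -> None:
    with _atomic(path) as tmp:
        with h5py.File(tmp, "w", track_order=True) as f:
            _write_grid_attrs(f, substrate.grid)
            for name in ("phi", "psi", "kappa_map"):
                f.create_dataset(name, data=getattr(substrate, name),
                                 compression="gzip", compression_opts=4,
                                 track_times=False)
            if substrate.mask is not None:
                f.create_dataset("mask", data=substrate.mask,
                                 compression="gzip", compression_opts=4,
                                 track_times=False)
            f.attrs["meta"] = json.dumps(substrate.meta, sort_keys=True,
                                         default=_json_default)


def load_substrate(path) -> SubstrateField:
    with h5py.File(path, "r") as f:
        grid = _read_grid_attrs(f)
        mask = f["mask"][()] if "mask" in f else None
        sub = SubstrateField(
            grid, f["phi"][()], f["psi"][()], f["kappa_map"][()],
            mask, json.loads(f.attrs["meta"]),
        )
    return sub


def save_checkpoint(path, state, config_hash_value: str = "") -> None:
    """Persist a CellState so a run can resume bit-identically."""
    with _atomic(path) as tmp:
        with h5py.File(tmp, "w", track_order=True) as f:
            _write_grid_attrs(f, state.grid)
            f.create_dataset("rho", data=state.rho, track_times=False)
            f.create_dataset("p", data=state.p, track_times=False)
            f.attrs["V0"] = state.V0
            f.attrs["A0"] = state.A0
            f.attrs["t"] = state.t
            f.attrs["config_hash"] = config_hash_value


def load_checkpoint(path):
    from .dynamics import CellState

    with h5py.File(path, "r") as f:
        grid = _read_grid_attrs(f)
        state = CellState(grid, f["rho"][()], f["p"][()],
                          V0=float(f.attrs["V0"]), A0=float(f.attrs["A0"]),
                          t=float(f.attrs["t"]))
        h = str(f.attrs["config_hash"])
    return state, h


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a canonicalized config mapping."""
    blob = json.dumps(config, sort_keys=True, default=_json_default)
    return hashlib.sha256(blob.encode()).hexdigest()


def write_manifest(path, params: ModelParams, config: dict,
                   substrate_meta: dict, termination: str,
                   steady_state_time=None, extra: dict | None = None) -> None:
    """JSON run manifest: everything needed to reproduce the run.

    Reports both nondimensional and dimensional duration (1 time unit =
    10 s, so the standard 500-unit run corresponds to 5000 s).
    """
    manifest = {
        "code_version": __version__,
        "config_hash": config_hash(config),
        "config": config,
        "params": params.to_dict(),
        "substrate": substrate_meta,
        "termination": termination,
        "steady_state_time": steady_state_time,
        "t_end": params.t_end,
        "time_scale_s": TIME_SCALE_S,
        "duration_seconds": params.duration_seconds,
    }
    if extra:
        manifest.update(extra)
    with _atomic(path) as tmp:
        Path(tmp).write_text(
            json.dumps(manifest, indent=2, sort_keys=True,
                       default=_json_default) + "\n"
        )


def write_metrics_csv(path, traj) -> None:
    from .analytics import metrics_dataframe

    df = metrics_dataframe(traj)
    with _atomic(path) as tmp:
        df.to_csv(tmp, index=False, float_format="%.10g")


def export_stl(rho: np.ndarray, grid: GridSpec, path, level: float = 0.5):
    """Export the ρ = level isosurface as a watertight binary STL mesh.

    Vertex coordinates are in μm world coordinates (voxel-center
    convention).  Raises ``ValueError`` when the isosurface is empty.
    Returns the mesh.
    """
    import trimesh
    from skimage import measure

    if not (rho.max() > level > rho.min()):
        raise ValueError(
            f"empty isosurface: level {level} outside field range "
            f"[{rho.min():.3g}, {rho.max():.3g}]"
        )
    verts, faces, _, _ = measure.marching_cubes(rho, level=level)
    mesh = trimesh.Trimesh(vertices=(verts + 0.5) * grid.spacing,
                           faces=faces, process=False)
    path = Path(path)
    with _atomic(path) as tmp:
        data = mesh.export(file_type="stl")
        Path(tmp).write_bytes(data)
    return mesh
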