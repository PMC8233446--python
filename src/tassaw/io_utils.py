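"""Writers: tidy trajectory CSV, legacy-ASCII VTK structured grids, JSON summary."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from tassaw import __version__
from tassaw.tracing import Trajectory


class OutputError(RuntimeError):
    pass


def ensure_writable(directory) -> Path:
    d = Path(directory)
    try:
        d.mkdir(parents=True, exist_ok=True)
        probe = d / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OutputError(f"output directory {d} is not writable: {exc}")
    return d


def trajectories_to_frame(trajectories: Mapping[str, Trajectory]) -> pd.DataFrame:
    """One row per saved sample: time, particle id, kinematics, forces."""
    frames = []
    for label, tr in trajectories.items():
        frames.append(pd.DataFrame({
            "time_s": tr.times, "particle": label,
            "x_m": tr.positions[:, 0], "y_m": tr.positions[:, 1],
            "z_m": tr.positions[:, 2],
            "vx_m_s": tr.velocities[:, 0], "vy_m_s": tr.velocities[:, 1],
            "vz_m_s": tr.velocities[:, 2],
            "Frad_x_N": tr.f_rad[:, 0], "Frad_y_N": tr.f_rad[:, 1],
            "Frad_z_N": tr.f_rad[:, 2],
            "Fdrag_x_N": tr.f_drag[:, 0], "Fdrag_y_N": tr.f_drag[:, 1],
            "Fdrag_z_N": tr.f_drag[:, 2],
        }))
    return pd.concat(frames, ignore_index=True)


def write_trajectories_csv(path, trajectories: Mapping[str, Trajectory],
                           seed: int | None = None) -> None:
    path = Path(path)
    header = f"# tassaw {__version__}"
    if seed is not None:
        header += f" seed={seed}"
    with path.open("w") as fh:
        fh.write(header + "\n")
        trajectories_to_frame(trajectories).to_csv(fh, index=False)


def read_trajectories_csv(path) -> pd.DataFrame:
    # round_trip parser: CSV re-read reproduces the arrays bit-exactly
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_vtk_structured(path, origin, spacing, arrays: Mapping[str, np.ndarray],
                         title: str = "tassaw field") -> None:
    """Write point-data arrays on a regular grid as legacy-ASCII VTK.

    ``arrays`` values share one shape (nx, ny, nz) (scalars) or
    (nx, ny, nz, 3) (vectors); complex arrays are split into ``_re``/``_im``.
    """
    shapes = {v.shape[:3] for v in arrays.values()}
    if len(shapes) != 1:
        raise OutputError("all arrays must share one grid shape")
    nx, ny, nz = shapes.pop()
    flat: dict[str, np.ndarray] = {}
    for name, arr in arrays.items():
        if np.iscomplexobj(arr):
            flat[name + "_re"] = np.real(arr)
            flat[name + "_im"] = np.imag(arr)
        else:
            flat[name] = np.asarray(arr, dtype=float)

    lines = ["# vtk DataFile Version 3.0", title, "ASCII",
             "DATASET STRUCTURED_POINTS",
             f"DIMENSIONS {nx} {ny} {nz}",
             f"ORIGIN {origin[0]:.9e} {origin[1]:.9e} {origin[2]:.9e}",
             f"SPACING {spacing[0]:.9e} {spacing[1]:.9e} {spacing[2]:.9e}",
             f"POINT_DATA {nx * ny * nz}"]
    for name, arr in flat.items():
        if arr.ndim == 3:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            vals = arr.transpose(2, 1, 0).ravel()
            lines.extend(f"{v:.9e}" for v in vals)
        elif arr.ndim == 4 and arr.shape[3] == 3:
            lines.append(f"VECTORS {name} double")
            vecs = arr.transpose(2, 1, 0, 3).reshape(-1, 3)
            lines.extend(f"{v[0]:.9e} {v[1]:.9e} {v[2]:.9e}" for v in vecs)
        else:
            raise OutputError(f"array {name!r} has unsupported shape {arr.shape}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_structured(path) -> dict:
    """Minimal legacy-VTK reader used for structural round-trip validation."""
    text = Path(path).read_text().splitlines()
    if not text[0].startswith("# vtk DataFile"):
        raise OutputError("not a legacy VTK file")
    if text[3].strip() != "DATASET STRUCTURED_POINTS":
        raise OutputError("unsupported VTK dataset type")
    dims = tuple(int(v) for v in text[4].split()[1:4])
    origin = tuple(float(v) for v in text[5].split()[1:4])
    spacing = tuple(float(v) for v in text[6].split()[1:4])
    npts = int(text[7].split()[1])
    nx, ny, nz = dims
    if npts != nx * ny * nz:
        raise OutputError("POINT_DATA count mismatch")
    arrays = {}
    i = 8
    while i < len(text):
        tok = text[i].split()
        if not tok:
            i += 1
            continue
        if tok[0] == "SCALARS":
            name = tok[1]
            i += 2  # skip LOOKUP_TABLE
            vals = np.array([float(text[i + j]) for j in range(npts)])
            arrays[name] = vals.reshape(nz, ny, nx).transpose(2, 1, 0)
            i += npts
        elif tok[0] == "VECTORS":
            name = tok[1]
            i += 1
            vals = np.array([[float(x) for x in text[i + j].split()]
                             for j in range(npts)])
            arrays[name] = vals.reshape(nz, ny, nx, 3).transpose(2, 1, 0, 3)
            i += npts
        else:
            raise OutputError(f"unexpected VTK token {tok[0]!r}")
    return {"dimensions": dims, "origin": origin, "spacing": spacing,
            "arrays": arrays}


def write_summary_json(path, summary: dict, seed: int | None = None) -> None:
    out = dict(summary)
    out.setdefault("software_version", __version__)
    if seed is not None:
        out.setdefault("seed", seed)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(out, indent=2, default=default,
                                     allow_nan=True) + "\n")
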