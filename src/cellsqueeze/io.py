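"""Writers for run artifacts: CSV tables, legacy-VTK fields/meshes, manifests.

CSV is the canonical tabular format and legacy ASCII VTK the field/mesh
format; both are universally readable.  Every run directory receives a
manifest (JSON) holding the configuration snapshot, seeds, package
versions, and provenance, sufficient to re-run the job reproducibly.
"""

from __future__ import annotations

import datetime
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .entry import EntryMetrics, EntryTrace
from .units import SimulationConfig


def write_manifest(destination, config: SimulationConfig, *,
                   device: str | None = None,
                   params_provenance: str | None = None,
                   extra: dict | None = None) -> Path:
    """Write the run manifest; returns the manifest path."""
    import cellsqueeze
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.asdict(),
        "seed": config.seed,
        "temperature_K": config.temperature,
        "device": device,
        "params_provenance": params_provenance,
        "versions": {
            "cellsqueeze": getattr(cellsqueeze, "__version__", "unknown"),
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "timestamp": datetime.datetime.now(datetime.timezone.utc)
                     .isoformat(timespec="seconds"),
    }
    if extra:
        manifest.update(extra)
    path = dest / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def write_trace_csv(trace: EntryTrace, path) -> Path:
    """Trace time series: time_ms, x_centroid_um, length_um, Q_uL_per_h."""
    path = Path(path)
    df = pd.DataFrame({
        "time_ms": trace.time_ms,
        "x_centroid_um": trace.x_centroid_um,
        "lead_x_um": trace.lead_x_um,
        "trail_x_um": trace.trail_x_um,
        "length_um": trace.length_um,
        "Q_uL_per_h": trace.flow_rate,
        "volume_um3": trace.volume_um3,
    })
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_trace_csv(path) -> EntryTrace:
    df = pd.read_csv(path)
    return EntryTrace(
        time_ms=df["time_ms"].to_numpy(),
        x_centroid_um=df["x_centroid_um"].to_numpy(),
        lead_x_um=df["lead_x_um"].to_numpy(),
        trail_x_um=df["trail_x_um"].to_numpy(),
        length_um=df["length_um"].to_numpy(),
        flow_rate=df["Q_uL_per_h"].to_numpy(),
        volume_um3=df["volume_um3"].to_numpy(),
        complete=True, meta={})


def write_metrics_csv(metrics: EntryMetrics | list, path) -> Path:
    path = Path(path)
    if isinstance(metrics, EntryMetrics):
        metrics = [metrics]
    df = pd.DataFrame([vars(m) for m in metrics])
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_ga_log_csv(history: pd.DataFrame, path) -> Path:
    """Convergence log with columns generation, K_b, K_v, K_a, K_l, VR, Error."""
    path = Path(path)
    cols = ["generation", "K_b", "K_v", "K_a", "K_l", "VR", "Error"]
    path.parent.mkdir(parents=True, exist_ok=True)
    history[cols].to_csv(path, index=False)
    return path


def write_vtk_structured(path, origin, spacing, fields: dict) -> Path:
    """Legacy ASCII VTK structured-points file with point-data fields.

    ``fields`` maps name -> array of shape (nx, ny, nz) (scalar) or
    (3, nx, ny, nz) (vector).
    """
    path = Path(path)
    shape = None
    for arr in fields.values():
        s = arr.shape[-3:]
        if shape is None:
            shape = s
        elif s != shape:
            raise ValueError("all fields must share one grid shape")
    nx, ny, nz = shape
    lines = ["# vtk DataFile Version 3.0", "cellsqueeze field snapshot",
             "ASCII", "DATASET STRUCTURED_POINTS",
             f"DIMENSIONS {nx} {ny} {nz}",
             f"ORIGIN {origin[0]} {origin[1]} {origin[2]}",
             f"SPACING {spacing} {spacing} {spacing}",
             f"POINT_DATA {nx * ny * nz}"]
    for name, arr in fields.items():
        if arr.ndim == 3:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            flat = arr.transpose(2, 1, 0).ravel()
            lines.extend(f"{v:.9g}" for v in flat)
        else:
            lines.append(f"VECTORS {name} double")
            vecs = arr.transpose(3, 2, 1, 0).reshape(-1, 3)
            lines.extend(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}" for v in vecs)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")
    return path


def write_vtk_polydata(path, vertices, faces, point_scalars: dict | None =
                       None) -> Path:
    """Legacy ASCII VTK polydata (triangulated surface) with vertex scalars."""
    path = Path(path)
    lines = ["# vtk DataFile Version 3.0", "cellsqueeze membrane snapshot",
             "ASCII", "DATASET POLYDATA",
             f"POINTS {len(vertices)} double"]
    lines.extend(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}" for v in vertices)
    lines.append(f"POLYGONS {len(faces)} {4 * len(faces)}")
    lines.extend(f"3 {f[0]} {f[1]} {f[2]}" for f in faces)
    if point_scalars:
        lines.append(f"POINT_DATA {len(vertices)}")
        for name, arr in point_scalars.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.9g}" for v in np.asarray(arr).ravel())
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")
    return path


def write_device_vtk(geometry, path) -> Path:
    """Device mask snapshot (1 = wall) for inspection in any VTK viewer."""
    return write_vtk_structured(
        path, origin=(0.5 * geometry.dx,) * 3, spacing=geometry.dx,
        fields={"wall": geometry.solid.astype(float)})


def write_snapshots_vtk(trace: EntryTrace, faces, destination) -> list[Path]:
    """Write each recorded membrane snapshot as a VTK polydata file."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    paths = []
    for idx, (t_ms, verts) in enumerate(trace.snapshots):
        paths.append(write_vtk_polydata(
            dest / f"membrane_{idx:05d}_{t_ms:.4f}ms.vtk", verts, faces))
    return paths
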