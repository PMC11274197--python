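"""File I/O: VTK export, YAML configs, CSV traces, run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circulation import BeatTrace

__all__ = ["write_vtk_unstructured", "write_trace_csv", "load_config",
           "save_config", "write_manifest"]


def write_vtk_unstructured(path, points, cells, point_data=None,
                           title="apexfree mesh"):
    """Write a hexahedral mesh as a legacy-ASCII VTK unstructured grid.

    ``point_data`` maps names to per-point scalars (n,) or vectors (n, 3).
    """
    points = np.asarray(points, float)
    cells = np.asarray(cells, int)
    lines = ["# vtk DataFile Version 3.0", title, "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {len(points)} double"]
    lines += [" ".join(f"{c:.10g}" for c in p) for p in points]
    lines.append(f"CELLS {len(cells)} {len(cells) * 9}")
    lines += ["8 " + " ".join(str(i) for i in c) for c in cells]
    lines.append(f"CELL_TYPES {len(cells)}")
    lines += ["12"] * len(cells)
    if point_data:
        lines.append(f"POINT_DATA {len(points)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.10g}" for v in arr]
            else:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{c:.10g}" for c in v) for v in arr]
    Path(path).write_text("\n".join(lines) + "\n")


def write_trace_csv(trace: BeatTrace, path):
    """Per-step beat trace as CSV (t, P_lv, V_lv, P_art, P_la, Q_mv, Q_av,
    x_root, x_apex)."""
    df = pd.DataFrame({
        "t": trace.t, "p_lv": trace.p_lv, "v_lv": trace.v_lv,
        "p_art": trace.p_art, "p_la": trace.p_la,
        "q_mv": trace.q_mv, "q_av": trace.q_av,
        "x_root": trace.x_root, "x_apex": trace.x_apex})
    df.to_csv(path, index=False)
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(cfg: dict, path):
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def write_manifest(path, config: dict, extra: dict | None = None):
    """Run manifest: config hash, package/platform versions, extras."""
    from . import __version__
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "apexfree_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
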