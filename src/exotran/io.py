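"""Output writers: legacy-VTK structured grids, CSV monitors, run manifests.

All files are plain text.  Field files use the legacy VTK STRUCTURED_POINTS
format with cell data, readable by ParaView/VisIt; floats are printed with
17 significant digits so a read-back reproduces the in-memory float64
bitwise.  Every file header records SI units, the 2-D out-of-plane depth
convention and the run seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .geometry import Grid
from .transport import TransportHistory

__all__ = [
    "write_vtk",
    "read_vtk",
    "write_monitors_csv",
    "write_outputs",
]

_FMT = "%.17g"


def _header_comment(grid: Grid, seed: int | None) -> str:
    d = grid.spec
    return (
        f"exotran field; SI units; coordinates={d.coordinates}; "
        f"depth={d.depth:g} m (2-D fields are per out-of-plane depth); "
        f"seed={seed}"
    )


def write_vtk(
    path: str | Path,
    grid: Grid,
    cell_data: dict[str, np.ndarray],
    seed: int | None = None,
) -> Path:
    """Write cell-centered fields as a legacy VTK structured-points file."""
    path = Path(path)
    nx, ny = grid.nx, grid.ny
    lines = [
        "# vtk DataFile Version 3.0",
        _header_comment(grid, seed),
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} 1",
        f"ORIGIN {_FMT % grid.xf[0]} {_FMT % grid.yf[0]} 0",
        f"SPACING {_FMT % grid.dx} {_FMT % grid.dy} 1",
        f"CELL_DATA {nx * ny}",
    ]
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        if arr.shape != (nx, ny):
            raise ConfigurationError(
                f"field {name!r} has shape {arr.shape}, expected {(nx, ny)}"
            )
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK cell ordering: x fastest
        flat = arr.T.ravel()
        lines.extend(_FMT % v for v in flat)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vtk(path: str | Path) -> dict[str, np.ndarray]:
    """Read back a field file written by :func:`write_vtk`."""
    tokens = Path(path).read_text().splitlines()
    it = iter(tokens)
    dims = None
    fields: dict[str, np.ndarray] = {}
    for line in it:
        if line.startswith("DIMENSIONS"):
            _, a, b, _ = line.split()
            dims = (int(a) - 1, int(b) - 1)
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            next(it)  # LOOKUP_TABLE
            n = dims[0] * dims[1]
            vals = np.array([float(next(it)) for _ in range(n)])
            fields[name] = vals.reshape(dims[1], dims[0]).T
    return fields


def write_monitors_csv(
    path: str | Path,
    history: TransportHistory,
    seed: int | None = None,
    extra_header: str = "",
) -> Path:
    """Write monitor time series as RFC-4180 CSV with a comment header."""
    path = Path(path)
    df = pd.DataFrame({"time_s": history.times, **history.monitors})
    header = (
        f"# exotran monitors; SI units; seed={seed}"
        + (f"; {extra_header}" if extra_header else "")
        + "\n"
    )
    with open(path, "w", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format=_FMT, lineterminator="\n")
    return path


def write_outputs(
    out_dir: str | Path,
    grid: Grid,
    fields: dict[str, np.ndarray],
    history: TransportHistory | None = None,
    summary: dict | None = None,
    config_dict: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Write a complete run output set and its manifest; returns manifest path.

    Produces ``fields.vtk``, optional ``monitors.csv`` and ``summary.json``,
    plus ``manifest.json`` listing every file with a SHA-256 digest and the
    hash of the configuration that produced them.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fields:
        written.append(write_vtk(out / "fields.vtk", grid, fields, seed=seed))
    if history is not None:
        written.append(write_monitors_csv(out / "monitors.csv", history, seed=seed))
    if summary is not None:
        p = out / "summary.json"
        p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written.append(p)
    cfg_hash = None
    if config_dict is not None:
        cfg_hash = hashlib.sha256(
            json.dumps(config_dict, sort_keys=True, default=str).encode()
        ).hexdigest()
    manifest = {
        "seed": seed,
        "config_sha256": cfg_hash,
        "files": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in written
        },
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return mpath
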