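"""File formats: MRC2014 volumes/stacks, STAR-dialect tables, TSV, YAML config.

Volumes and image stacks travel as MRC2014 mode 2 (32-bit float) with the
voxel size in the header, via gemmi.  Metadata tables use a minimal STAR
dialect — one ``data_`` block, ``loop_`` columns with underscore-prefixed
names — chosen for interoperability with common cryo-EM tooling, with a TSV
fallback.  Every table written carries a provenance header (tool version,
seed, config hash) as STAR comments.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import VolumeGrid


def write_volume(path: str | Path, volume: VolumeGrid) -> None:
    """Write a volume (or stack) as MRC2014 mode 2 with its voxel size."""
    path = Path(path)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(volume.data, dtype=np.float32))
    nz, ny, nx = volume.data.shape
    vs = volume.voxel_size
    m.grid.unit_cell = gemmi.UnitCell(nz * vs, ny * vs, nx * vs, 90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header(2, True)
    m.write_ccp4_map(str(path))


def read_volume(path: str | Path) -> VolumeGrid:
    """Read an MRC2014 mode 2 volume; errors name any unsupported mode."""
    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse MRC file {path}: {exc}") from exc
    mode = m.header_i32(4)
    if mode != 2:
        raise ValueError(f"unsupported MRC mode {mode} in {path}; expected mode 2 (float32)")
    data = np.array(m.grid, copy=True)
    voxel = m.grid.unit_cell.a / m.grid.shape[0]
    return VolumeGrid(data, float(voxel))


def write_stack(path: str | Path, stack: np.ndarray, pixel_size: float) -> None:
    """Write an image stack (n, y, x) as a 3D MRC mode-2 array."""
    path = Path(path)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(stack, dtype=np.float32))
    n, ny, nx = stack.shape
    m.grid.unit_cell = gemmi.UnitCell(n * pixel_size, ny * pixel_size, nx * pixel_size,
                                      90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header(2, True)
    m.write_ccp4_map(str(path))


def read_stack(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an image stack written by :func:`write_stack`."""
    m = gemmi.read_ccp4_map(str(path))
    if m.header_i32(4) != 2:
        raise ValueError(f"unsupported MRC mode {m.header_i32(4)} in {path}")
    data = np.array(m.grid, copy=True)
    pixel = m.grid.unit_cell.b / m.grid.shape[1]
    return data, float(pixel)


# --- STAR-dialect tables --------------------------------------------------


def write_star(path: str | Path, table: pd.DataFrame, block: str = "particles",
               provenance: dict | None = None) -> None:
    """Write a table as a single-block, loop-style STAR file."""
    path = Path(path)
    lines = []
    for key, val in (provenance or {}).items():
        lines.append(f"# {key}: {val}")
    lines += [f"data_{block}", "", "loop_"]
    for i, col in enumerate(table.columns, start=1):
        lines.append(f"_{col} #{i}")
    for _, row in table.iterrows():
        lines.append("  ".join(_star_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def _star_fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return f"{v:.6f}"
    return str(v)


def read_star(path: str | Path) -> pd.DataFrame:
    """Read a single-block loop-style STAR file back into a DataFrame."""
    path = Path(path)
    columns: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("data_"):
            continue
        if line == "loop_":
            in_loop = True
            continue
        if in_loop and line.startswith("_"):
            columns.append(line.split()[0].lstrip("_"))
            continue
        if in_loop and columns:
            rows.append(line.split())
    if not columns:
        raise ValueError(f"no loop block found in {path}")
    df = pd.DataFrame(rows, columns=columns)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            pass
    return df


def write_tsv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- configuration --------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML key-value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration for provenance stamping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance(seed: int, config: dict) -> dict:
    return {"tool": f"helixsub {__version__}", "seed": seed,
            "config_hash": config_hash(config)}
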