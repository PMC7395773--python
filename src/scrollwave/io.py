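"""Plain-text configs, run manifests, mesh and table I/O.

Configs are flat ``key = value`` text files (units documented per key
in the docs); labeled meshes are written as legacy-VTK ASCII
unstructured grids with named point/cell data arrays (fiber, h, layer,
region, gel) readable by standard visualization tools; metric tables
are tab-delimited text.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np

from .geometry import LabeledMesh

__all__ = [
    "parse_config",
    "write_config",
    "RunManifest",
    "write_vtk",
    "read_vtk",
    "write_table",
]


class ConfigError(ValueError):
    pass


def _coerce(raw: str):
    raw = raw.strip()
    low = raw.lower()
    if low in ("true", "false"):
        return low == "true"
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        pass
    if "," in raw:
        return [_coerce(p) for p in raw.split(",")]
    return raw


def parse_config(path_or_text, allowed_keys=None) -> dict:
    """Parse a flat ``key = value`` config; '#' starts a comment.

    Unknown keys are rejected by name when ``allowed_keys`` is given.
    """
    p = Path(path_or_text) if "\n" not in str(path_or_text) else None
    text = p.read_text() if p is not None and p.exists() else str(path_or_text)
    out = {}
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {ln}: expected 'key = value', got {line!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if not key:
            raise ConfigError(f"line {ln}: empty key")
        out[key] = _coerce(val)
    if allowed_keys is not None:
        unknown = sorted(set(out) - set(allowed_keys))
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    return out


def write_config(cfg: dict, path) -> None:
    lines = []
    for k, v in cfg.items():
        if isinstance(v, (list, tuple, np.ndarray)):
            v = ",".join(str(x) for x in v)
        lines.append(f"{k} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


class RunManifest:
    """Reproducibility record: config echo, seeds, versions, outputs."""

    def __init__(self, command: str, config: dict, seed: int):
        from . import __version__
        self.data = {
            "command": command,
            "version": __version__,
            "seed": int(seed),
            "config": _jsonable(config),
            "outputs": [],
            "log": [],
        }

    def add_output(self, path, kind: str) -> None:
        self.data["outputs"].append({"path": str(path), "kind": kind})

    def log(self, message: str, **kv) -> None:
        self.data["log"].append({"message": message, **_jsonable(kv)})

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.data, indent=2, default=str))


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist() if obj.size <= 64 else f"<array shape={obj.shape}>"
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# Legacy-VTK ASCII unstructured grids
# ---------------------------------------------------------------------------

_VTK_CELL = {2: 3, 3: 5, 4: 10}          # nloc -> VTK line/triangle/tetra
_VTK_CELL_INV = {3: 2, 5: 3, 10: 4}


def write_vtk(mesh: LabeledMesh, path) -> None:
    """Write a labeled mesh as a legacy-VTK ASCII unstructured grid."""
    nodes3 = np.zeros((mesh.n_nodes, 3))
    nodes3[:, : mesh.dim] = mesh.nodes
    fib3 = np.zeros((mesh.n_nodes, 3))
    fib3[:, : mesh.dim] = mesh.fibers
    elems = mesh.elements
    nloc = elems.shape[1]
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nscrollwave labeled mesh\n"
                "ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(f, nodes3, fmt="%.10g")
        f.write(f"CELLS {mesh.n_elements} {mesh.n_elements * (nloc + 1)}\n")
        np.savetxt(f, np.column_stack([np.full(mesh.n_elements, nloc), elems]),
                   fmt="%d")
        f.write(f"CELL_TYPES {mesh.n_elements}\n")
        np.savetxt(f, np.full(mesh.n_elements, _VTK_CELL[nloc]), fmt="%d")
        f.write(f"POINT_DATA {mesh.n_nodes}\n")
        f.write("SCALARS h double 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, mesh.h, fmt="%.10g")
        f.write("SCALARS layer int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, mesh.layer, fmt="%d")
        f.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, mesh.region, fmt="%d")
        if mesh.transmural_phi is not None:
            f.write("SCALARS transmural_phi double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, mesh.transmural_phi, fmt="%.10g")
        f.write("VECTORS fiber double\n")
        np.savetxt(f, fib3, fmt="%.10g")
        f.write(f"CELL_DATA {mesh.n_elements}\n")
        f.write("SCALARS gel int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, mesh.gel.astype(int), fmt="%d")


def read_vtk(path) -> LabeledMesh:
    """Read a mesh previously written by :func:`write_vtk`."""
    with open(path) as f:
        tokens = f.read().split("\n")
    i = 0

    def seek(prefix):
        nonlocal i
        while i < len(tokens) and not tokens[i].startswith(prefix):
            i += 1
        if i >= len(tokens):
            raise ValueError(f"missing {prefix} section")
        return tokens[i].split()

    hdr = seek("POINTS")
    n = int(hdr[1]); i += 1
    nodes = np.loadtxt(tokens[i:i + n]).reshape(n, 3)
    i += n
    hdr = seek("CELLS")
    m = int(hdr[1]); i += 1
    cells = np.loadtxt(tokens[i:i + m], dtype=np.int64).reshape(m, -1)
    nloc = int(cells[0, 0])
    elems = cells[:, 1:1 + nloc]
    i += m
    hdr = seek("CELL_TYPES"); i += 1
    dim = {2: 1, 3: 2, 4: 3}[nloc]
    i += m

    def read_scalar(name, dtype=float):
        nonlocal i
        seek(f"SCALARS {name}")
        i += 2
        arr = np.loadtxt(tokens[i:i + n], dtype=dtype)
        i += n
        return arr

    h = read_scalar("h")
    layer = read_scalar("layer", np.int64)
    region = read_scalar("region", np.int64)
    save_i = i
    try:
        phi = read_scalar("transmural_phi")
    except ValueError:
        phi = None
        i = save_i
    seek("VECTORS fiber"); i += 1
    fibers = np.loadtxt(tokens[i:i + n]).reshape(n, 3)[:, :dim]
    i += n
    seek("CELL_DATA")
    i += 1
    seek("SCALARS gel")
    i += 2
    gel = np.loadtxt(tokens[i:i + m], dtype=np.int64).astype(bool)
    return LabeledMesh(nodes=nodes[:, :dim], elements=elems, fibers=fibers,
                       h=h, layer=layer, region=region, gel=gel,
                       transmural_phi=phi)


def write_table(path, columns: dict, float_fmt: str = "%.6g") -> None:
    """Write named columns as a tab-delimited text table with a header."""
    names = list(columns)
    arrs = [np.asarray(columns[k]) for k in names]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("columns must have equal length")
    with open(path, "w") as f:
        f.write("\t".join(names) + "\n")
        for row in zip(*arrs):
            f.write("\t".join(float_fmt % v if isinstance(v, (float, np.floating))
                    else str(v) for v in row) + "\n")
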