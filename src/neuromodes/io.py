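"""Readers and writers: OFF meshes, delimited text, HDF5 containers, config.

Delimited text uses '.' decimals, '#'-prefixed comment/header lines, and 17
significant digits (lossless for float64).  HDF5 containers carry a
``schema`` attribute; readers refuse files written by a future major
version.  All writers round-trip bit-exactly at their declared precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import yaml

from .domain import SpatialDomain
from .mesh import TriangleMesh
from .simulate import ActivityTimeSeries

__all__ = [
    "read_mesh_off", "write_mesh_off", "read_mesh_gifti",
    "read_matrix_text", "write_matrix_text",
    "read_matrix_h5", "write_matrix_h5",
    "read_timeseries_text", "write_timeseries_text",
    "read_timeseries_h5", "write_timeseries_h5",
    "write_modes_h5", "read_modes_h5",
    "load_config",
]

SCHEMA = "neuromodes-1.0"
FMT = "%.17g"


def _check_schema(attrs) -> None:
    schema = attrs.get("schema", SCHEMA)
    if isinstance(schema, bytes):
        schema = schema.decode()
    major = str(schema).rsplit("-", 1)[-1].split(".")[0]
    ours = SCHEMA.rsplit("-", 1)[-1].split(".")[0]
    if int(major) > int(ours):
        raise ValueError(f"file schema {schema} is newer than supported "
                         f"{SCHEMA}")


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def write_mesh_off(mesh: TriangleMesh, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_mesh_off(path: str | Path) -> TriangleMesh:
    """Parse an OFF mesh with line-numbered diagnostics."""
    path = Path(path)
    lines = path.read_text().splitlines()
    tokens: list[tuple[int, str]] = []
    for ln, line in enumerate(lines, start=1):
        body = line.split("#", 1)[0].strip()
        if body:
            tokens.append((ln, body))
    if not tokens or tokens[0][1].upper() != "OFF":
        raise ValueError(f"{path}:1: not an OFF file (missing 'OFF' header)")
    if len(tokens) < 2:
        raise ValueError(f"{path}: missing count line")
    ln, counts = tokens[1]
    try:
        nv, nf, _ = (int(x) for x in counts.split())
    except ValueError as exc:
        raise ValueError(f"{path}:{ln}: malformed count line {counts!r}") from exc
    body = tokens[2:]
    if len(body) < nv + nf:
        raise ValueError(f"{path}: expected {nv} vertices + {nf} faces, "
                         f"found {len(body)} data lines")
    verts = np.empty((nv, 3))
    for i in range(nv):
        ln, line = body[i]
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: vertex line needs 3 coordinates")
        try:
            verts[i] = [float(p) for p in parts[:3]]
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: bad vertex coordinates") from exc
    faces = np.empty((nf, 3), dtype=np.int64)
    for i in range(nf):
        ln, line = body[nv + i]
        parts = line.split()
        try:
            n = int(parts[0])
            idx = [int(p) for p in parts[1:1 + n]]
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{ln}: malformed face line") from exc
        if n != 3:
            raise ValueError(f"{path}:{ln}: face {i} has {n} vertices; "
                             "only triangles are supported")
        for v in idx:
            if not 0 <= v < nv:
                raise ValueError(f"{path}:{ln}: face {i} references missing "
                                 f"vertex {v} (have {nv})")
        faces[i] = idx
    return TriangleMesh(vertices=verts, faces=faces)


def read_mesh_gifti(path: str | Path) -> TriangleMesh:
    """Read a GIfTI surface (optional; requires nibabel)."""
    import nibabel as nib

    img = nib.load(str(path))
    verts = faces = None
    for arr in img.darrays:
        code = arr.intent
        if code == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            verts = np.asarray(arr.data, dtype=float)
        elif code == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            faces = np.asarray(arr.data, dtype=np.int64)
    if verts is None or faces is None:
        raise ValueError(f"{path}: GIfTI file lacks a pointset/triangle pair")
    return TriangleMesh(vertices=verts, faces=faces)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_matrix_text(matrix: np.ndarray, path: str | Path,
                      unit: str = "dimensionless",
                      area_weights: np.ndarray | None = None) -> None:
    matrix = np.asarray(matrix)
    path = Path(path)
    header = [f"# K={matrix.shape[0]}", f"# unit={unit}"]
    if np.iscomplexobj(matrix):
        header.append("# complex=interleaved")
        flat = np.empty((matrix.shape[0], 2 * matrix.shape[1]))
        flat[:, 0::2] = matrix.real
        flat[:, 1::2] = matrix.imag
        matrix = flat
    if area_weights is not None:
        header.append("# area_weights=" + " ".join(FMT % w
                                                   for w in area_weights))
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, matrix, fmt=FMT)


def read_matrix_text(path: str | Path
                     ) -> tuple[np.ndarray, dict[str, Any]]:
    path = Path(path)
    meta: dict[str, Any] = {}
    for line in path.read_text().splitlines():
        if not line.startswith("#"):
            break
        body = line[1:].strip()
        if "=" in body:
            key, val = body.split("=", 1)
            meta[key.strip()] = val.strip()
    mat = np.loadtxt(path, comments="#", ndmin=2)
    if meta.get("complex") == "interleaved":
        mat = mat[:, 0::2] + 1j * mat[:, 1::2]
    if "area_weights" in meta:
        meta["area_weights"] = np.array(
            [float(x) for x in meta["area_weights"].split()])
    if "K" in meta:
        meta["K"] = int(meta["K"])
        if mat.shape[0] != meta["K"]:
            raise ValueError(f"{path}: header K={meta['K']} but "
                             f"{mat.shape[0]} rows found")
    return mat, meta


def write_matrix_h5(matrix: np.ndarray, path: str | Path,
                    unit: str = "dimensionless",
                    frequencies: np.ndarray | None = None,
                    area_weights: np.ndarray | None = None,
                    symmetric: bool | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["schema"] = SCHEMA
        fh.attrs["units"] = unit
        if symmetric is not None:
            fh.attrs["symmetric_flag"] = bool(symmetric)
        fh.create_dataset("matrix", data=np.asarray(matrix))
        if frequencies is not None:
            fh.create_dataset("frequencies", data=np.asarray(frequencies))
        if area_weights is not None:
            fh.create_dataset("area_weights", data=np.asarray(area_weights))


def read_matrix_h5(path: str | Path) -> tuple[np.ndarray, dict[str, Any]]:
    with h5py.File(path, "r") as fh:
        _check_schema(fh.attrs)
        meta = {k: fh.attrs[k] for k in fh.attrs}
        mat = fh["matrix"][...]
        for key in ("frequencies", "area_weights"):
            if key in fh:
                meta[key] = fh[key][...]
    return mat, meta


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

def write_timeseries_text(ts: ActivityTimeSeries, path: str | Path) -> None:
    path = Path(path)
    data = np.column_stack([ts.times, ts.values.T])
    with path.open("w") as fh:
        fh.write(f"# K={ts.n_channels}\n# dt={ts.dt:.17g}\n# unit=s^-1\n")
        fh.write("# columns=time," +
                 ",".join(f"ch{i}" for i in range(ts.n_channels)) + "\n")
        np.savetxt(fh, data, fmt=FMT)


def read_timeseries_text(path: str | Path) -> ActivityTimeSeries:
    data = np.loadtxt(path, comments="#", ndmin=2)
    meta: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.startswith("#"):
            break
        body = line[1:].strip()
        if "=" in body:
            k, v = body.split("=", 1)
            meta[k.strip()] = v.strip()
    t = data[:, 0]
    dt = float(meta.get("dt", t[1] - t[0] if t.size > 1 else 1.0))
    return ActivityTimeSeries(values=data[:, 1:].T, dt=dt, t0=float(t[0]),
                              provenance="loaded")


def write_timeseries_h5(ts: ActivityTimeSeries, path: str | Path,
                        seed: int | None = None,
                        model_hash: str | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["schema"] = SCHEMA
        fh.attrs["dt"] = ts.dt
        fh.attrs["t0"] = ts.t0
        if seed is not None:
            fh.attrs["seed"] = seed
        if model_hash is not None:
            fh.attrs["model_hash"] = model_hash
        fh.create_dataset("values", data=ts.values)
        fh.create_dataset("time", data=ts.times)


def read_timeseries_h5(path: str | Path) -> ActivityTimeSeries:
    with h5py.File(path, "r") as fh:
        _check_schema(fh.attrs)
        values = fh["values"][...]
        dt = float(fh.attrs["dt"])
        t0 = float(fh.attrs.get("t0", 0.0))
    return ActivityTimeSeries(values=values, dt=dt, t0=t0,
                              provenance="loaded")


# ---------------------------------------------------------------------------
# mode sets
# ---------------------------------------------------------------------------

def write_modes_h5(path: str | Path, modes: np.ndarray,
                   eigenvalues: np.ndarray,
                   lm_index: list[tuple[int, int]] | None = None,
                   radius: float | None = None,
                   convention: str = "condon-shortley") -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["schema"] = SCHEMA
        fh.attrs["convention"] = convention
        if radius is not None:
            fh.attrs["radius"] = radius
        fh.create_dataset("modes", data=np.asarray(modes))
        fh.create_dataset("eigenvalues", data=np.asarray(eigenvalues))
        if lm_index is not None:
            fh.create_dataset("lm_index",
                              data=np.asarray(lm_index, dtype=np.int64))


def read_modes_h5(path: str | Path) -> dict[str, Any]:
    with h5py.File(path, "r") as fh:
        _check_schema(fh.attrs)
        out: dict[str, Any] = {k: fh.attrs[k] for k in fh.attrs}
        out["modes"] = fh["modes"][...]
        out["eigenvalues"] = fh["eigenvalues"][...]
        if "lm_index" in fh:
            out["lm_index"] = [tuple(p) for p in fh["lm_index"][...]]
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

KNOWN_KEYS = {
    "domain", "mesh", "model", "simulation", "window", "recovery",
    "output", "verbosity", "seed",
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML/JSON run config; unknown top-level keys are rejected."""
    path = Path(path)
    text = path.read_text()
    cfg = (json.loads(text) if path.suffix == ".json"
           else yaml.safe_load(text))
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(cfg) - KNOWN_KEYS
    if unknown:
        raise ValueError(
            f"{path}: unknown config keys {sorted(unknown)}; "
            f"known keys are {sorted(KNOWN_KEYS)}")
    return cfg
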