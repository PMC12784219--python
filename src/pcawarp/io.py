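"""Readers and writers: meshes, point tables, head directories, model bundles.

Conventions: all coordinates on disk are millimetres; heads and proxies are
stored in the CTF frame.  Meshes use 0-based indexing in memory; the OBJ
1-based convention is handled by the format layer (trimesh).  Point tables
are CSV with columns ``label,x,y,z``; the labels NAS, LPA, RPA are reserved
for fiducials.
"""

from __future__ import annotations

import hashlib
import json
from io import BytesIO
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .mesh import Fiducials, HeadModel, SurfaceMesh, TISSUES
from .shape_model import ShapeModel
from .warp import ScalpProxy

_FORMATS = (".obj", ".ply", ".stl")
FIDUCIAL_LABELS = ("NAS", "LPA", "RPA")

BUNDLE_VERSION = 1


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

def read_mesh(path: str | Path, tissue: str = "other") -> SurfaceMesh:
    """Read an OBJ/PLY/STL surface mesh (mm).  Polygons are triangulated."""
    path = Path(path)
    if path.suffix.lower() not in _FORMATS:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")
    tm = trimesh.load_mesh(path, process=False)
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise ValueError(f"no geometry in {path}")
        tm = geoms[0]
    return SurfaceMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces), tissue)


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a surface mesh; format follows the file extension."""
    path = Path(path)
    if path.suffix.lower() not in _FORMATS:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")
    tm = trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False)
    tm.export(path)


# ---------------------------------------------------------------------------
# Point tables
# ---------------------------------------------------------------------------

def read_points(path: str | Path, require_fiducials: bool = False):
    """Read a labelled point CSV.

    Returns ``(points, labels, fiducials)`` where fiducials is ``None``
    unless all of NAS/LPA/RPA are present; fiducial rows are excluded from
    ``points``.
    """
    df = pd.read_csv(path)
    needed = {"label", "x", "y", "z"}
    if not needed.issubset(df.columns):
        raise ValueError(f"point table must have columns {sorted(needed)}")
    is_fid = df["label"].isin(FIDUCIAL_LABELS)
    fid = None
    if is_fid.any():
        fid_rows = df[is_fid].set_index("label")
        if not all(l in fid_rows.index for l in FIDUCIAL_LABELS):
            raise ValueError("incomplete fiducials: need all of NAS, LPA, RPA")
        fid = Fiducials(*[fid_rows.loc[l, ["x", "y", "z"]].to_numpy(float)
                          for l in FIDUCIAL_LABELS])
    elif require_fiducials:
        raise ValueError("point table lacks the fiducial labels NAS/LPA/RPA")
    rest = df[~is_fid]
    return rest[["x", "y", "z"]].to_numpy(float), rest["label"].tolist(), fid


def write_points(
    path: str | Path,
    points: np.ndarray,
    labels: list[str] | None = None,
    fiducials: Fiducials | None = None,
) -> None:
    points = np.atleast_2d(np.asarray(points, float))
    labels = labels or [f"P{i+1:03d}" for i in range(len(points))]
    rows = []
    if fiducials is not None:
        for lab, p in zip(FIDUCIAL_LABELS, fiducials.as_array()):
            rows.append({"label": lab, "x": p[0], "y": p[1], "z": p[2]})
    for lab, p in zip(labels, points):
        rows.append({"label": lab, "x": p[0], "y": p[1], "z": p[2]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_proxy(path: str | Path, provenance: str = "electrodes") -> ScalpProxy:
    """Read a scalp proxy from a point CSV (fiducials required) or a mesh file."""
    path = Path(path)
    if path.suffix.lower() in _FORMATS:
        mesh = read_mesh(path)
        fid_csv = path.with_suffix(".csv")
        if not fid_csv.exists():
            raise ValueError(
                f"mesh proxy needs a fiducial table next to it: {fid_csv}"
            )
        _, _, fid = read_points(fid_csv, require_fiducials=True)
        return ScalpProxy(mesh.vertices, fid, "mesh")
    pts, labels, fid = read_points(path, require_fiducials=True)
    return ScalpProxy(pts, fid, provenance, labels)


# ---------------------------------------------------------------------------
# Head directories
# ---------------------------------------------------------------------------

def write_headmodel(head: HeadModel, directory: str | Path, fmt: str = "obj") -> None:
    """Write the four shells as ``<tissue>.<fmt>`` plus ``fiducials.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for shell in head.shells:
        write_mesh(shell, directory / f"{shell.tissue}.{fmt}")
    write_points(directory / "fiducials.csv", np.empty((0, 3)),
                 [], head.fiducials)


def read_headmodel(directory: str | Path, coord_system: str = "ctf") -> HeadModel:
    directory = Path(directory)
    shells = []
    for tissue in TISSUES:
        for ext in _FORMATS:
            p = directory / f"{tissue}{ext}"
            if p.exists():
                shells.append(read_mesh(p, tissue))
                break
        else:
            raise FileNotFoundError(f"missing {tissue} mesh in {directory}")
    _, _, fid = read_points(directory / "fiducials.csv", require_fiducials=True)
    return HeadModel(shells, fid, coord_system)


# ---------------------------------------------------------------------------
# Shape-model bundles
# ---------------------------------------------------------------------------

def _array_checksum(arrays: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for name in sorted(arrays):
        h.update(name.encode())
        h.update(np.ascontiguousarray(arrays[name]).tobytes())
    return h.hexdigest()


def save_bundle(model: ShapeModel, path: str | Path) -> None:
    """Serialize a shape model to a single .npz archive with checksum."""
    arrays = {
        "mean": model.mean,
        "components": model.components,
        "singular_values": model.singular_values,
        "triangles": model.triangles,
    }
    if model.scale is not None:
        arrays["scale"] = model.scale
    meta = {
        "format_version": BUNDLE_VERSION,
        "v_count": model.v_count,
        "tissue_order": list(model.tissue_order),
        "normalization": model.normalization,
        "n_train": model.n_train,
        "checksum": _array_checksum(arrays),
    }
    np.savez_compressed(path, metadata=json.dumps(meta), **arrays)


def load_bundle(path: str | Path) -> ShapeModel:
    """Load a shape-model bundle; refuses on checksum or shape mismatch."""
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["metadata"]))
        arrays = {k: npz[k] for k in npz.files if k != "metadata"}
    if meta.get("format_version") != BUNDLE_VERSION:
        raise ValueError("unsupported bundle version")
    expected = meta["checksum"]
    if _array_checksum(arrays) != expected:
        raise ValueError("bundle checksum mismatch: file corrupted")
    model = ShapeModel(
        mean=arrays["mean"],
        components=arrays["components"],
        singular_values=arrays["singular_values"],
        v_count=int(meta["v_count"]),
        triangles=arrays["triangles"],
        normalization=meta["normalization"],
        scale=arrays.get("scale"),
        n_train=int(meta["n_train"]),
        tissue_order=tuple(meta["tissue_order"]),
    )
    # invariant check: orthonormal components
    gram = model.components @ model.components.T
    if not np.allclose(gram, np.eye(model.n_comp), atol=1e-6):
        raise ValueError("bundle components are not orthonormal")
    return model
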