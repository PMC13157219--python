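"""Point-cloud file I/O: ASCII PLY (vertex-only), plain XYZ, and NPY.

PLY files carry labels as an integer scalar vertex property ``label``;
for NPY/XYZ an optional parallel ``<stem>.labels.npy`` file is used.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .cloud import PointCloud

__all__ = ["load_cloud", "save_cloud"]

_FORMATS = ("ply", "xyz", "npy")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown point-cloud format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def load_cloud(path: str | os.PathLike, format: str | None = None) -> PointCloud:
    """Read a point cloud from PLY / XYZ / NPY.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` with a
    line number for malformed records.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "npy":
        pts = np.load(path)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"{path}: NPY cloud must be (N, 3), got {pts.shape}")
        labels = None
        lbl_path = path.with_suffix(".labels.npy")
        if lbl_path.exists():
            labels = np.load(lbl_path)
        return PointCloud(pts.astype(np.float64), labels=labels)
    if fmt == "xyz":
        return _load_xyz(path)
    return _load_ply(path)


def _load_xyz(path: Path) -> PointCloud:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 coordinates, got {len(parts)}")
            try:
                rows.append([float(v) for v in parts[:3]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable coordinate ({exc})") from exc
    if not rows:
        raise ValueError(f"{path}: empty XYZ file (a cloud needs at least one point)")
    return PointCloud(np.array(rows, dtype=np.float64))


def _load_ply(path: Path) -> PointCloud:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ValueError(f"{path}:1: not an ASCII PLY file (missing 'ply' magic)")
    n_vertex = None
    props: list[str] = []
    body_at = None
    for i, line in enumerate(lines[1:], start=2):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format" and tok[1] != "ascii":
            raise ValueError(f"{path}:{i}: only ascii PLY is supported")
        if tok[0] == "element" and tok[1] == "vertex":
            n_vertex = int(tok[2])
        elif tok[0] == "element":
            raise ValueError(f"{path}:{i}: unsupported element {tok[1]!r} (vertex-only PLY)")
        elif tok[0] == "property" and n_vertex is not None:
            props.append(tok[-1])
        elif tok[0] == "end_header":
            body_at = i
            break
    if n_vertex is None or body_at is None:
        raise ValueError(f"{path}: malformed PLY header")
    for axis in "xyz":
        if axis not in props:
            raise ValueError(f"{path}: vertex element lacks property {axis!r}")
    body = [ln for ln in lines[body_at:] if ln.strip()]
    if len(body) < n_vertex:
        raise ValueError(
            f"{path}:{body_at + len(body) + 1}: expected {n_vertex} vertex records, got {len(body)}"
        )
    cols = {name: j for j, name in enumerate(props)}
    pts = np.empty((n_vertex, 3))
    labels = np.empty(n_vertex, dtype=np.int64) if "label" in cols else None
    for r in range(n_vertex):
        tok = body[r].split()
        if len(tok) != len(props):
            raise ValueError(f"{path}:{body_at + r + 1}: expected {len(props)} fields, got {len(tok)}")
        pts[r] = [float(tok[cols["x"]]), float(tok[cols["y"]]), float(tok[cols["z"]])]
        if labels is not None:
            labels[r] = int(tok[cols["label"]])
    return PointCloud(pts, labels=labels)


def save_cloud(cloud: PointCloud, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a point cloud as PLY / XYZ / NPY (labels preserved where possible)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "npy":
        np.save(path, cloud.points)
        if cloud.labels is not None:
            np.save(path.with_suffix(".labels.npy"), cloud.labels)
        return
    if fmt == "xyz":
        np.savetxt(path, cloud.points, fmt="%.9g")
        return
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(cloud)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        if cloud.labels is not None:
            fh.write("property int label\n")
        fh.write("end_header\n")
        for i, p in enumerate(cloud.points):
            row = f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}"
            if cloud.labels is not None:
                row += f" {cloud.labels[i]}"
            fh.write(row + "\n")
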