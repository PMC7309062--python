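"""Core domain types and file I/O for potential mapping data.

A study unit is a triangulated surface mesh (torso or epicardium) together
with one biopotential time signal per mesh node.  All node and sample
indices are 0-based; sample intervals are half-open ``[start, end)``.
Signals are in mV, coordinates in mm.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

UNIPOLAR = "unipolar"
BIPOLAR = "bipolar"


class MeshParseError(ValueError):
    """Raised when a mesh file cannot be parsed; names the offending line."""


class MeshValidationError(ValueError):
    """Raised when parsed mesh data violates the mesh invariants."""


class RecordingSchemaError(ValueError):
    """Raised when an HDF5 recording lacks a required dataset or attribute."""


@dataclasses.dataclass
class SurfaceMesh:
    """Triangulated surface: ``node_coords`` (V, 3) in mm, ``triangles`` (F, 3).

    Every triangle index must be a valid node index and no triangle may
    repeat a vertex.
    """

    node_coords: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.node_coords = np.asarray(self.node_coords, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.node_coords.ndim != 2 or self.node_coords.shape[1] != 3:
            raise MeshValidationError(
                f"node_coords must be (V, 3), got {self.node_coords.shape}"
            )
        if self.triangles.size == 0:
            self.triangles = self.triangles.reshape(0, 3)
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshValidationError(
                f"triangles must be (F, 3), got {self.triangles.shape}"
            )
        n = self.node_count
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= n:
                bad = int(np.argmax((self.triangles < 0) | (self.triangles >= n)))
                raise MeshValidationError(
                    f"triangle vertex index out of range [0, {n}) near face "
                    f"{bad // 3}"
                )
            degenerate = (
                (self.triangles[:, 0] == self.triangles[:, 1])
                | (self.triangles[:, 1] == self.triangles[:, 2])
                | (self.triangles[:, 0] == self.triangles[:, 2])
            )
            if degenerate.any():
                raise MeshValidationError(
                    f"degenerate triangle (repeated vertex) at face "
                    f"{int(np.argmax(degenerate))}"
                )

    @property
    def node_count(self) -> int:
        return self.node_coords.shape[0]

    @property
    def triangle_count(self) -> int:
        return self.triangles.shape[0]


@dataclasses.dataclass
class PotentialRecording:
    """Per-node time signals (mV): ``signals`` is (node, sample).

    ``kind`` is "unipolar" or "bipolar"; ``mesh_ref`` ties the rows to a
    mesh; ``meta`` carries free-form provenance (e.g. the bipolar delay).
    """

    signals: np.ndarray
    fs: float
    kind: str = UNIPOLAR
    mesh_ref: str = ""
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.kind not in (UNIPOLAR, BIPOLAR):
            raise ValueError(f"kind must be 'unipolar' or 'bipolar', got {self.kind!r}")

    @property
    def node_count(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


@dataclasses.dataclass
class BeatAnnotation:
    """Per-node depolarization fiducials and half-open beat windows.

    ``fiducials[i]`` is a strictly increasing array of sample indices of
    the detected (or ground-truth) depolarization peaks of node ``i``;
    ``beat_windows[i][m] = (start, end)`` brackets beat ``m`` and contains
    its fiducial.
    """

    fiducials: list[np.ndarray]
    beat_windows: list[list[tuple[int, int]]]

    def __post_init__(self) -> None:
        self.fiducials = [np.asarray(f, dtype=np.int64) for f in self.fiducials]
        for i, f in enumerate(self.fiducials):
            if f.size > 1 and not (np.diff(f) > 0).all():
                raise ValueError(f"fiducials of node {i} not strictly increasing")
        for i, (f, wins) in enumerate(zip(self.fiducials, self.beat_windows)):
            for m, (s, e) in enumerate(wins):
                if not (s <= f[m] < e):
                    raise ValueError(
                        f"node {i} beat {m}: window ({s}, {e}) does not "
                        f"contain fiducial {f[m]}"
                    )


# ---------------------------------------------------------------------------
# Mesh I/O: ASCII OFF and PLY
# ---------------------------------------------------------------------------


def _meaningful_lines(text: str):
    """Yield (1-based line number, stripped line) skipping blanks/comments."""
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            yield ln, line


def _read_off(path: Path) -> SurfaceMesh:
    lines = list(_meaningful_lines(path.read_text()))
    if not lines or lines[0][1] != "OFF":
        raise MeshParseError(f"{path}: line 1: expected 'OFF' header")
    try:
        counts = lines[1][1].split()
        n_v, n_f = int(counts[0]), int(counts[1])
    except (IndexError, ValueError):
        raise MeshParseError(
            f"{path}: line {lines[1][0] if len(lines) > 1 else 2}: "
            "expected 'V F E' counts"
        ) from None
    body = lines[2:]
    if len(body) < n_v + n_f:
        raise MeshParseError(f"{path}: truncated file: expected {n_v} vertices "
                             f"and {n_f} faces")
    coords = np.empty((n_v, 3), dtype=float)
    for i in range(n_v):
        ln, line = body[i]
        parts = line.split()
        if len(parts) < 3:
            raise MeshParseError(f"{path}: line {ln}: expected 3 coordinates")
        try:
            coords[i] = [float(p) for p in parts[:3]]
        except ValueError:
            raise MeshParseError(f"{path}: line {ln}: bad coordinate") from None
    tris = np.empty((n_f, 3), dtype=np.int64)
    for j in range(n_f):
        ln, line = body[n_v + j]
        parts = line.split()
        try:
            k = int(parts[0])
            idx = [int(p) for p in parts[1 : 1 + k]]
        except (IndexError, ValueError):
            raise MeshParseError(f"{path}: line {ln}: bad face record") from None
        if k != 3 or len(idx) != 3:
            raise MeshParseError(
                f"{path}: line {ln}: only triangular faces supported (got {k})"
            )
        tris[j] = idx
    return SurfaceMesh(coords, tris)


def _write_off(mesh: SurfaceMesh, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.node_count} {mesh.triangle_count} 0\n")
        for x, y, z in mesh.node_coords:
            fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
        for a, b, c in mesh.triangles:
            fh.write(f"3 {a} {b} {c}\n")


def _read_ply(path: Path) -> SurfaceMesh:
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise MeshParseError(f"{path}: line 1: expected 'ply' magic")
    n_v = n_f = None
    elements: list[tuple[str, int]] = []
    i = 1
    for i, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if line.startswith("format"):
            if "ascii" not in line:
                raise MeshParseError(f"{path}: line {i}: only ASCII PLY supported")
        elif line.startswith("element"):
            parts = line.split()
            try:
                elements.append((parts[1], int(parts[2])))
            except (IndexError, ValueError):
                raise MeshParseError(f"{path}: line {i}: bad element record") from None
        elif line == "end_header":
            break
    else:
        raise MeshParseError(f"{path}: missing end_header")
    for name, count in elements:
        if name == "vertex":
            n_v = count
        elif name == "face":
            n_f = count
    if n_v is None or n_f is None:
        raise MeshParseError(f"{path}: header lacks vertex/face elements")
    body_start = i  # 0-based index of first data line (line i+1, 1-based)
    body = lines[body_start:]
    if len(body) < n_v + n_f:
        raise MeshParseError(f"{path}: truncated: expected {n_v} vertices and "
                             f"{n_f} faces")
    coords = np.empty((n_v, 3), dtype=float)
    for v in range(n_v):
        ln = body_start + v + 1
        parts = body[v].split()
        if len(parts) < 3:
            raise MeshParseError(f"{path}: line {ln}: expected 3 coordinates")
        try:
            coords[v] = [float(p) for p in parts[:3]]
        except ValueError:
            raise MeshParseError(f"{path}: line {ln}: bad coordinate") from None
    tris = np.empty((n_f, 3), dtype=np.int64)
    for f in range(n_f):
        ln = body_start + n_v + f + 1
        parts = body[n_v + f].split()
        try:
            k = int(parts[0])
            idx = [int(p) for p in parts[1 : 1 + k]]
        except (IndexError, ValueError):
            raise MeshParseError(f"{path}: line {ln}: bad face record") from None
        if k != 3:
            raise MeshParseError(
                f"{path}: line {ln}: only triangular faces supported (got {k})"
            )
        tris[f] = idx
    return SurfaceMesh(coords, tris)


def _write_ply(mesh: SurfaceMesh, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.node_count}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {mesh.triangle_count}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("end_header\n")
        for x, y, z in mesh.node_coords:
            fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
        for a, b, c in mesh.triangles:
            fh.write(f"3 {a} {b} {c}\n")


def read_mesh(path) -> SurfaceMesh:
    """Read a triangulated mesh from an ASCII OFF or PLY file."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".off":
        return _read_off(path)
    if suffix == ".ply":
        return _read_ply(path)
    raise ValueError(f"unsupported mesh format {suffix!r} (use .off or .ply)")


def write_mesh(mesh: SurfaceMesh, path) -> None:
    """Write a mesh as ASCII OFF or PLY; inverse of :func:`read_mesh`."""
    if mesh.node_count == 0:
        raise MeshValidationError("refusing to write an empty mesh")
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".off":
        _write_off(mesh, path)
    elif suffix == ".ply":
        _write_ply(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format {suffix!r} (use .off or .ply)")


# ---------------------------------------------------------------------------
# Recording I/O: HDF5 container + CSV convenience
# ---------------------------------------------------------------------------


def write_recording(rec: PotentialRecording, path) -> None:
    """Write a recording to HDF5: dataset ``signals``, attrs ``fs``, ``kind``,
    ``mesh_ref`` (plus any ``meta`` entries prefixed ``meta_``).

    Dataset timestamps are disabled so byte content is reproducible.
    """
    with h5py.File(path, "w") as fh:
        fh.create_dataset("signals", data=rec.signals, track_times=False)
        fh.attrs["fs"] = float(rec.fs)
        fh.attrs["kind"] = rec.kind
        fh.attrs["mesh_ref"] = rec.mesh_ref
        for key, val in rec.meta.items():
            fh.attrs[f"meta_{key}"] = val


def read_recording(path) -> PotentialRecording:
    """Read a recording written by :func:`write_recording` (lossless)."""
    with h5py.File(path, "r") as fh:
        if "signals" not in fh:
            raise RecordingSchemaError(f"{path}: missing dataset 'signals'")
        for attr in ("fs", "kind", "mesh_ref"):
            if attr not in fh.attrs:
                raise RecordingSchemaError(f"{path}: missing attribute '{attr}'")
        signals = fh["signals"][()]
        kind = fh.attrs["kind"]
        mesh_ref = fh.attrs["mesh_ref"]
        if isinstance(kind, bytes):
            kind = kind.decode()
        if isinstance(mesh_ref, bytes):
            mesh_ref = mesh_ref.decode()
        meta = {
            k[len("meta_"):]: (v.item() if isinstance(v, np.generic) else v)
            for k, v in fh.attrs.items()
            if k.startswith("meta_")
        }
        return PotentialRecording(
            signals, float(fh.attrs["fs"]), str(kind), str(mesh_ref), meta
        )


def read_recording_csv(path, fs: float, kind: str = UNIPOLAR,
                       mesh_ref: str = "") -> PotentialRecording:
    """Convenience reader: CSV with one node per row, no header."""
    import pandas as pd

    signals = pd.read_csv(path, header=None).to_numpy(dtype=float)
    return PotentialRecording(signals, fs, kind, mesh_ref)


def write_region_labels(labels: Sequence[str], path) -> None:
    """JSON sidecar mapping node index (as string) to region name."""
    Path(path).write_text(
        json.dumps({str(i): str(lab) for i, lab in enumerate(labels)}, indent=0)
    )


def read_region_labels(path) -> list[str]:
    data = json.loads(Path(path).read_text())
    return [data[str(i)] for i in range(len(data))]


# ---------------------------------------------------------------------------
# Adjacency
# ---------------------------------------------------------------------------


def build_adjacency(mesh: SurfaceMesh) -> list[np.ndarray]:
    """Per-node sorted neighbor lists: k is a neighbor of i iff they share a
    triangle edge.  Symmetric by construction; all-empty if no triangles."""
    neighbors: list[set[int]] = [set() for _ in range(mesh.node_count)]
    for a, b, c in mesh.triangles:
        a, b, c = int(a), int(b), int(c)
        neighbors[a].update((b, c))
        neighbors[b].update((a, c))
        neighbors[c].update((a, b))
    return [np.array(sorted(s), dtype=np.int64) for s in neighbors]
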