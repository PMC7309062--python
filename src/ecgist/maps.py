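"""Amplitude maps, clinical voltage classification, mesh paths and M-modes.

The M-mode stacks the time signals of an ordered node path over the mesh,
turning the spatial-temporal structure of a potential map into a single
2-D display.  Paths are reproducible shortest hop-count routes between
endpoints (lowest-index tie-breaking); an explicit node list can be passed
instead.
"""
from __future__ import annotations

import dataclasses
from collections import deque

import numpy as np

from .bipolar import peak_to_peak
from .data_model import (
    BIPOLAR,
    UNIPOLAR,
    BeatAnnotation,
    PotentialRecording,
    SurfaceMesh,
    build_adjacency,
)

#: Clinical peak-to-peak voltage thresholds (mV) used in electrophysiological
#: studies to separate infarcted from healthy tissue.
UNIPOLAR_SCAR_MAX_MV = 3.0
UNIPOLAR_HEALTHY_MIN_MV = 5.0
BIPOLAR_SCAR_MAX_MV = 0.5
BIPOLAR_HEALTHY_MIN_MV = 1.5


@dataclasses.dataclass
class MModeSlice:
    """Signals stacked along a mesh path (row order = path order)."""

    path: np.ndarray      # ordered node indices
    signals: np.ndarray   # (len(path), T)

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=np.int64)
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.signals.shape[0] != self.path.size:
            raise ValueError("one signal row per path node required")


def amplitude_map(rec: PotentialRecording,
                  annotation: BeatAnnotation) -> np.ndarray:
    """Per-node peak-to-peak amplitude (mV) of the first beat window.

    Nodes without any detected beat get NaN.
    """
    values = np.full(rec.node_count, np.nan)
    for i in range(rec.node_count):
        wins = annotation.beat_windows[i]
        if not wins:
            continue
        start, end = wins[0]
        values[i] = peak_to_peak(rec.signals[i, int(start):int(end)])
    return values


def classify_by_amplitude(value_mV: float, kind: str = UNIPOLAR) -> str:
    """Clinical voltage classification of one node.

    Unipolar: <= 3 mV scar, 3-5 mV (open interval) border, >= 5 mV
    healthy.  Bipolar: < 0.5 mV scar, [0.5, 1.5] mV border, > 1.5 mV
    healthy.  Valve tissue also presents below 3 mV (far-field), so an
    amplitude-only rule cannot separate valve from scar; the "scar" label
    here means scar-or-valve.
    """
    if not np.isfinite(value_mV) or value_mV < 0:
        raise ValueError(f"amplitude must be a finite non-negative mV value, "
                         f"got {value_mV}")
    if kind == UNIPOLAR:
        if value_mV <= UNIPOLAR_SCAR_MAX_MV:
            return "scar"
        if value_mV >= UNIPOLAR_HEALTHY_MIN_MV:
            return "healthy"
        return "border"
    if kind == BIPOLAR:
        if value_mV < BIPOLAR_SCAR_MAX_MV:
            return "scar"
        if value_mV > BIPOLAR_HEALTHY_MIN_MV:
            return "healthy"
        return "border"
    raise ValueError(f"kind must be 'unipolar' or 'bipolar', got {kind!r}")


def mesh_path(mesh: SurfaceMesh, start: int, end: int) -> np.ndarray:
    """Shortest hop-count path between two nodes over the mesh adjacency.

    Deterministic: BFS visits sorted neighbor lists, so each node keeps
    its lowest-index predecessor.  Disconnected endpoints are an error.
    """
    n = mesh.node_count
    if not (0 <= start < n and 0 <= end < n):
        raise ValueError(f"endpoints must be valid node indices, got "
                         f"{start}, {end}")
    if start == end:
        return np.array([start], dtype=np.int64)
    adjacency = build_adjacency(mesh)
    pred = np.full(n, -1, dtype=np.int64)
    seen = np.zeros(n, dtype=bool)
    seen[start] = True
    queue = deque([start])
    while queue:
        u = queue.popleft()
        if u == end:
            break
        for v in adjacency[u]:
            v = int(v)
            if not seen[v]:
                seen[v] = True
                pred[v] = u
                queue.append(v)
    if not seen[end]:
        raise ValueError(f"no path between nodes {start} and {end}")
    path = [end]
    while path[-1] != start:
        path.append(int(pred[path[-1]]))
    return np.array(path[::-1], dtype=np.int64)


def extract_mmode(signals, path) -> MModeSlice:
    """Ordered stack of per-node signals along a path.

    ``signals`` may be a :class:`PotentialRecording` or any (node, value)
    matrix (e.g. per-node estimator traces).  Reversing the path reverses
    the row order.
    """
    path = np.asarray(path, dtype=np.int64)
    matrix = signals.signals if isinstance(signals, PotentialRecording) \
        else np.atleast_2d(np.asarray(signals, dtype=float))
    if path.size and (path.min() < 0 or path.max() >= matrix.shape[0]):
        raise ValueError("path refers to nodes without signals")
    return MModeSlice(path, matrix[path])


def mmode_to_csv(slice_: MModeSlice, path) -> None:
    """CSV export: first column the node index, then the samples."""
    import pandas as pd

    frame = pd.DataFrame(slice_.signals)
    frame.insert(0, "node", slice_.path)
    frame.to_csv(path, index=False)


def render_mmode(slice_: MModeSlice, fs: float, out_path,
                 title: str = "M-mode") -> None:
    """Waterfall rendering of an M-mode slice (static PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.arange(slice_.signals.shape[1]) / fs
    span = np.abs(slice_.signals).max() or 1.0
    fig, ax = plt.subplots(figsize=(8, 6))
    for row, (node, sig) in enumerate(zip(slice_.path, slice_.signals)):
        ax.plot(t, sig / span + row, lw=0.7)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("path position (node order)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
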