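"""Bipolar electrogram synthesis from unipolar potential maps.

The bipolar potential at mesh node i is the difference between its
unipolar signal and the delayed unipolar signal of a chosen adjacent node
k:

    beta_i[t] = v_i[t] - v_k[t - alpha]

with alpha a fixed sample delay (default 40 samples, ~20 ms at 2048 Hz)
and k the neighbor whose first-beat peak-to-peak amplitude is maximal.
The delayed signal is zero-padded over the first alpha samples; those
samples are excluded from amplitude measurements downstream.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .data_model import BIPOLAR, BeatAnnotation, PotentialRecording, SurfaceMesh, build_adjacency

MAX_AMPLITUDE = "max_amplitude"


@dataclasses.dataclass
class BipolarConfig:
    alpha_samples: int = 40
    neighbor_criterion: str = MAX_AMPLITUDE

    def __post_init__(self) -> None:
        if self.alpha_samples < 0:
            raise ValueError("alpha_samples must be >= 0")
        if self.neighbor_criterion != MAX_AMPLITUDE:
            raise ValueError(
                f"unknown neighbor criterion {self.neighbor_criterion!r}"
            )


def peak_to_peak(window: np.ndarray) -> float:
    """max - min of a signal window (mV)."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty window")
    return float(window.max() - window.min())


def _first_beat_slice(rec: PotentialRecording, node: int,
                      annotation: BeatAnnotation | None) -> slice:
    if annotation is not None and len(annotation.beat_windows[node]):
        start, end = annotation.beat_windows[node][0]
        return slice(int(start), int(end))
    return slice(None)


def select_neighbor(node: int, rec: PotentialRecording,
                    adjacency: Sequence[np.ndarray],
                    criterion: str = MAX_AMPLITUDE,
                    annotation: BeatAnnotation | None = None) -> int:
    """Adjacent node with the largest first-beat peak-to-peak amplitude.

    Deterministic: exact amplitude ties break toward the lowest node
    index (neighbor lists are sorted).  Without an annotation the whole
    signal is used as the measurement window.
    """
    if criterion != MAX_AMPLITUDE:
        raise ValueError(f"unknown neighbor criterion {criterion!r}")
    neighbors = adjacency[node]
    if len(neighbors) == 0:
        raise ValueError(f"node {node} has no neighbors; cannot form a bipolar pair")
    best_node, best_amp = -1, -np.inf
    for k in neighbors:
        amp = peak_to_peak(rec.signals[k, _first_beat_slice(rec, int(k), annotation)])
        if amp > best_amp:
            best_node, best_amp = int(k), amp
    return best_node


def compute_bipolar(node: int, rec: PotentialRecording,
                    adjacency: Sequence[np.ndarray],
                    cfg: BipolarConfig | None = None,
                    annotation: BeatAnnotation | None = None,
                    neighbor: int | None = None) -> np.ndarray:
    """Bipolar signal of one node: ``v_i[t] - v_k[t - alpha]``.

    The neighbor is fixed per node (selected once on the first beat).  The
    first ``alpha`` samples subtract a zero-padded neighbor signal.
    """
    cfg = cfg or BipolarConfig()
    alpha = cfg.alpha_samples
    if alpha >= rec.n_samples:
        raise ValueError(
            f"alpha_samples={alpha} must be below signal length {rec.n_samples}"
        )
    if neighbor is None:
        neighbor = select_neighbor(node, rec, adjacency,
                                   cfg.neighbor_criterion, annotation)
    v_i = rec.signals[node]
    v_k = rec.signals[neighbor]
    delayed = np.zeros_like(v_k)
    if alpha == 0:
        delayed[:] = v_k
    else:
        delayed[alpha:] = v_k[:-alpha]
    return v_i - delayed


def compute_bipolar_map(rec: PotentialRecording, mesh: SurfaceMesh,
                        cfg: BipolarConfig | None = None,
                        annotation: BeatAnnotation | None = None
                        ) -> PotentialRecording:
    """Whole-mesh bipolar recording (one signal per node, order preserved).

    The output metadata records the delay, the criterion and the selected
    neighbor of each node.  Per-node failures propagate with the node
    index in the message.
    """
    cfg = cfg or BipolarConfig()
    adjacency = build_adjacency(mesh)
    out = np.empty_like(rec.signals)
    chosen = np.empty(rec.node_count, dtype=np.int64)
    for i in range(rec.node_count):
        try:
            k = select_neighbor(i, rec, adjacency, cfg.neighbor_criterion,
                                annotation)
            chosen[i] = k
            out[i] = compute_bipolar(i, rec, adjacency, cfg, annotation,
                                     neighbor=k)
        except ValueError as exc:
            raise ValueError(f"bipolar computation failed at node {i}: {exc}") from exc
    meta = dict(rec.meta)
    meta.update(alpha_samples=cfg.alpha_samples,
                neighbor_criterion=cfg.neighbor_criterion,
                neighbors=chosen.tolist())
    return PotentialRecording(out, rec.fs, BIPOLAR, rec.mesh_ref, meta)
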