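"""Synthetic ECGI generator: meshes, region layouts, and per-node electrograms.

The generator stands in for clinical body-surface / epicardial potential
maps.  It produces a closed triangulated sphere, labels edge-connected
regions (scar, border, valve, healthy), and synthesizes per-node
quasi-periodic electrograms whose peak-to-peak amplitude and fragmentation
follow the clinical voltage conventions for infarcted tissue:
unipolar scar <= 3 mV, border 3-5 mV, healthy >= 5 mV, valve < 3 mV
(far-field).  T-wave alternans of known magnitude, sinusoidal baseline
drift and broadband noise can be layered on with full ground truth.

Conventions
-----------
* The alternans magnitude ``delta_uV`` is HALF the even/odd T-amplitude
  difference: even beats carry T - delta, odd beats T + delta.  The
  Temporal Method then recovers exactly delta, and the MMA maximum
  alternans magnitude equals 2*delta.
* All randomness flows through one ``numpy`` generator seeded per call.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import ConvexHull
from scipy.special import ndtr  # normal CDF

from .data_model import (
    BeatAnnotation,
    PotentialRecording,
    SurfaceMesh,
    build_adjacency,
)

REGIONS = ("scar", "border", "valve", "healthy")

#: Region-typical waveform morphology.  Depolarization is a difference of
#: Gaussians (dominant positive peak at the fiducial); the T wave is a wider
#: Gaussian.  Scar/border/valve add narrow low-amplitude deflections
#: ("fragmentation").  Values are qualitative stand-ins chosen to mimic
#: clinical descriptions: healthy EGMs are clean and biphasic, scar EGMs
#: fragmented with inverted repolarization, valve EGMs wide far-field humps.
_REGION_MORPHOLOGY = {
    "healthy": dict(dep_width_ms=10.0, neg_frac=0.55, t_frac=0.30, t_sign=+1.0,
                    t_width_ms=50.0),
    "border": dict(dep_width_ms=13.0, neg_frac=0.65, t_frac=0.25, t_sign=+1.0,
                   t_width_ms=45.0),
    "scar": dict(dep_width_ms=17.0, neg_frac=0.75, t_frac=0.20, t_sign=-1.0,
                 t_width_ms=40.0),
    "valve": dict(dep_width_ms=30.0, neg_frac=0.30, t_frac=0.35, t_sign=-1.0,
                  t_width_ms=70.0),
}


@dataclasses.dataclass
class RegionLayout:
    """Per-node region labels plus the seed node of each grown region."""

    labels: np.ndarray  # array of region-name strings, one per node
    seed_nodes: dict[str, int]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        unknown = set(self.labels) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown region labels: {sorted(unknown)}")

    def nodes_of(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.labels == region)


@dataclasses.dataclass
class SynthConfig:
    """Study conditions of the synthetic recordings.

    Amplitudes are peak-to-peak ranges in mV per region (uniformly drawn,
    spatially smoothed); ``alternans_delta_uV`` is half the even/odd
    T-amplitude difference in microvolts; noise/drift model broadband
    measurement noise and respiration-scale baseline wander.
    """

    node_count: int = 502
    fs: float = 2048.0
    n_beats: int = 8
    rr_interval_s: float = 1.0
    first_beat_s: float = 0.35
    tail_s: float = 0.6
    region_amplitudes: dict = dataclasses.field(default_factory=lambda: {
        "scar": (1.0, 2.8), "border": (3.3, 4.7),
        "valve": (0.8, 2.5), "healthy": (5.5, 9.0),
    })
    fragmentation_deflections: dict = dataclasses.field(default_factory=lambda: {
        "scar": 3, "border": 2, "valve": 4, "healthy": 0,
    })
    alternans_delta_uV: float = 0.0
    t_peak_offset_s: float = 0.25
    t_alt_width_s: float = 0.05
    noise_sd_uV: float = 10.0
    drift_amp_mV: float = 0.2
    drift_freq_hz: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beats < 2:
            raise ValueError("n_beats must be >= 2 (alternans needs pairs)")
        if self.fs <= 30.0:
            raise ValueError("fs must exceed twice the 15 Hz low-pass cutoff")
        amp = self.region_amplitudes
        if not (max(amp["scar"]) <= min(amp["border"]) <= max(amp["border"])
                <= min(amp["healthy"])):
            raise ValueError(
                "region amplitude ranges must satisfy scar < border < healthy"
            )
        if self.alternans_delta_uV < 0:
            raise ValueError("alternans_delta_uV must be >= 0")

    @property
    def n_samples(self) -> int:
        dur = self.first_beat_s + (self.n_beats - 1) * self.rr_interval_s + self.tail_s
        return int(dur * self.fs)


# ---------------------------------------------------------------------------
# Mesh generation
# ---------------------------------------------------------------------------


def _icosahedron() -> np.ndarray:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    return verts / np.linalg.norm(verts, axis=1, keepdims=True)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = golden * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix gives a Haar-random orthogonal matrix.
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def generate_sphere_mesh(node_count: int, seed: int = 0,
                         radius_mm: float = 40.0) -> SurfaceMesh:
    """Closed triangulated sphere with ``node_count`` nodes (Euler char 2).

    ``node_count == 12`` returns the regular icosahedron; larger counts use
    a Fibonacci lattice under a seeded random rotation (which leaves the
    hull topology unchanged, so meshes from the same count share degree
    statistics) triangulated by its convex hull.
    """
    if node_count < 12:
        raise ValueError(f"node_count must be >= 12, got {node_count}")
    rng = np.random.default_rng(seed)
    pts = _icosahedron() if node_count == 12 else _fibonacci_sphere(node_count)
    pts = pts @ _random_rotation(rng).T
    hull = ConvexHull(pts)
    tris = hull.simplices.copy()
    # orient faces outward (sphere centered at the origin)
    v0, v1, v2 = pts[tris[:, 0]], pts[tris[:, 1]], pts[tris[:, 2]]
    normals = np.cross(v1 - v0, v2 - v0)
    flip = np.einsum("ij,ij->i", normals, v0) < 0
    tris[flip] = tris[flip][:, ::-1]
    return SurfaceMesh(pts * radius_mm, tris)


# ---------------------------------------------------------------------------
# Region layout
# ---------------------------------------------------------------------------


def _bfs_hops(adjacency: Sequence[np.ndarray], source: int) -> np.ndarray:
    """Hop distance from ``source`` to every node (-1 if unreachable)."""
    dist = np.full(len(adjacency), -1, dtype=np.int64)
    dist[source] = 0
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adjacency[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    nxt.append(int(v))
        frontier = nxt
    return dist


def assign_regions(mesh: SurfaceMesh, seeds: Mapping[str, int],
                   radii: Mapping[str, int]) -> RegionLayout:
    """Grow regions by breadth-first hop radius around seed nodes.

    Each named region claims all nodes within ``radii[region]`` hops of its
    seed; overlaps resolve by priority valve > scar > border, and unclaimed
    nodes are healthy.  ``border`` may share the scar seed implicitly (give
    it a radius but no seed) so that nested radii yield a border annulus
    around the scar; explicitly duplicated seed nodes are an error.
    """
    explicit = list(seeds.values())
    if len(set(explicit)) != len(explicit):
        raise ValueError(f"overlapping seed nodes: {sorted(seeds.items())}")
    seeds = dict(seeds)
    if "border" in radii and "border" not in seeds and "scar" in seeds:
        seeds["border"] = seeds["scar"]

    adjacency = build_adjacency(mesh)
    labels = np.asarray(["healthy"] * mesh.node_count, dtype=object)
    # paint lowest priority first so higher priorities overwrite
    for region in ("border", "scar", "valve"):
        if region not in seeds or region not in radii:
            continue
        seed = int(seeds[region])
        if not 0 <= seed < mesh.node_count:
            raise ValueError(f"seed node {seed} out of range for region {region}")
        dist = _bfs_hops(adjacency, seed)
        labels[(dist >= 0) & (dist <= int(radii[region]))] = region
    return RegionLayout(labels, {r: int(n) for r, n in seeds.items()})


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------


def smooth_node_field(rng: np.random.Generator,
                      adjacency: Sequence[np.ndarray],
                      n_iter: int = 8) -> np.ndarray:
    """Zero-mean, unit-SD random field that varies smoothly across the mesh
    (iid normals diffused over the adjacency)."""
    x = rng.standard_normal(len(adjacency))
    for _ in range(n_iter):
        means = np.array([x[nb].mean() if nb.size else x[i]
                          for i, nb in enumerate(adjacency)])
        x = 0.5 * (x + means)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _node_template(t: np.ndarray, morph: dict, frag_count: int,
                   frag_offsets: np.ndarray, frag_amps: np.ndarray) -> np.ndarray:
    """Unit-p2p single-beat template on time axis ``t`` (s).

    The dominant absolute peak is shifted onto t = 0 so ground-truth
    fiducials coincide with what an amplitude peak detector finds; T-wave
    and fragmentation amplitudes are scaled relative to that peak so the
    depolarization always dominates.
    """
    w = morph["dep_width_ms"] / 1000.0
    sep = 1.5 * w
    wave = _gauss(t, 0.0, w) - morph["neg_frac"] * _gauss(t, sep, 1.3 * w)
    dep_peak = np.abs(wave).max()
    wave += (morph["t_sign"] * morph["t_frac"] * dep_peak
             * _gauss(t, morph["t_peak_offset_s"], morph["t_width_ms"] / 1000.0))
    for j in range(frag_count):
        wave += frag_amps[j] * dep_peak * _gauss(t, frag_offsets[j], 0.005)
    zero_idx = int(np.argmin(np.abs(t)))
    wave = np.roll(wave, zero_idx - int(np.argmax(np.abs(wave))))
    p2p = wave.max() - wave.min()
    return wave / p2p


def synthesize_recording(mesh: SurfaceMesh, layout: RegionLayout,
                         cfg: SynthConfig
                         ) -> tuple[PotentialRecording, BeatAnnotation]:
    """Noiseless per-node electrograms with exact ground-truth fiducials.

    Each node repeats one beat template at ``rr_interval_s`` spacing; the
    template's peak-to-peak amplitude is drawn from the node's region range
    (spatially smoothed so neighbors match), and morphology parameters are
    the region's base values under small spatially correlated jitter.
    Alternans, drift and noise are added separately so that this stage is a
    pure function of (mesh, layout, cfg.rng_seed).
    """
    if len(layout.labels) != mesh.node_count:
        raise ValueError("layout does not match mesh node count")
    rng = np.random.default_rng(cfg.rng_seed)
    adjacency = build_adjacency(mesh)
    n_nodes = mesh.node_count
    fs = cfg.fs

    # smooth fields drive amplitude and morphology jitter
    amp_field = ndtr(smooth_node_field(rng, adjacency))      # ~U(0,1), smooth
    jitter_fields = {
        key: smooth_node_field(rng, adjacency)
        for key in ("dep_width_ms", "t_frac", "t_width_ms", "frag")
    }
    frag_base_amps = rng.uniform(0.12, 0.22, size=8) * np.where(
        np.arange(8) % 2 == 0, 1.0, -1.0
    )

    fiducials = np.array(
        [int((cfg.first_beat_s + m * cfg.rr_interval_s) * fs)
         for m in range(cfg.n_beats)],
        dtype=np.int64,
    )
    n_samples = cfg.n_samples
    pre = int(0.30 * fs)   # template span before / after the fiducial
    post = int(0.55 * fs)
    t_axis = (np.arange(-pre, post)) / fs

    signals = np.zeros((n_nodes, n_samples))
    for i in range(n_nodes):
        region = str(layout.labels[i])
        morph = dict(_REGION_MORPHOLOGY[region])
        morph["t_peak_offset_s"] = cfg.t_peak_offset_s
        morph["dep_width_ms"] *= 1.0 + 0.08 * jitter_fields["dep_width_ms"][i]
        morph["t_frac"] *= 1.0 + 0.08 * jitter_fields["t_frac"][i]
        morph["t_width_ms"] *= 1.0 + 0.08 * jitter_fields["t_width_ms"][i]
        frag_count = int(cfg.fragmentation_deflections.get(region, 0))
        frag_offsets = (np.linspace(0.035, 0.115, max(frag_count, 1))
                        + 0.004 * jitter_fields["frag"][i])
        template = _node_template(t_axis, morph, frag_count, frag_offsets,
                                  frag_base_amps)
        lo, hi = cfg.region_amplitudes[region]
        amp = lo + (hi - lo) * amp_field[i]
        beat = amp * template
        for fid in fiducials:
            start, end = fid - pre, fid + post
            signals[i, start:end] += beat

    rec = PotentialRecording(signals, fs, "unipolar", meta={"synthetic": 1})
    windows = [(int(f - pre), int(min(f + post, n_samples))) for f in fiducials]
    ann = BeatAnnotation([fiducials.copy() for _ in range(n_nodes)],
                         [list(windows) for _ in range(n_nodes)])
    return rec, ann


def inject_alternans(rec: PotentialRecording, annotation: BeatAnnotation,
                     delta_uV: float,
                     node_subset: Sequence[int] | None = None,
                     t_offset_s: float = 0.25,
                     t_width_s: float = 0.05) -> PotentialRecording:
    """Every-other-beat T-wave alternation of half-difference ``delta_uV``.

    Even-indexed beats (0-based) get the T amplitude lowered by delta and
    odd beats raised by delta, via a unit-peak Gaussian wave centered
    ``t_offset_s`` after each fiducial.  Depolarization is untouched; the
    even/odd T-segment means then differ by exactly 2*delta before noise.
    """
    if delta_uV < 0:
        raise ValueError(f"delta_uV must be >= 0, got {delta_uV}")
    signals = rec.signals.copy()
    if delta_uV == 0:
        return dataclasses.replace(rec, signals=signals)
    nodes = (range(rec.node_count) if node_subset is None
             else [int(i) for i in node_subset])
    delta_mV = delta_uV / 1000.0
    fs = rec.fs
    half = int(4 * t_width_s * fs)
    for i in nodes:
        for m, fid in enumerate(annotation.fiducials[i]):
            center = int(fid + t_offset_s * fs)
            start = max(0, center - half)
            end = min(rec.n_samples, center + half)
            if start >= end:
                continue
            t = (np.arange(start, end) - center) / fs
            wave = delta_mV * np.exp(-0.5 * (t / t_width_s) ** 2)
            signals[i, start:end] += wave if m % 2 else -wave
    return dataclasses.replace(rec, signals=signals)


def add_artifacts(rec: PotentialRecording, cfg: SynthConfig) -> PotentialRecording:
    """Add sinusoidal baseline drift and white noise (seeded, reproducible).

    Drift: ``drift_amp_mV`` at ``drift_freq_hz`` (<= 0.5 Hz, below the
    alternans band) with a random phase per node.  Noise: iid Gaussian with
    SD ``noise_sd_uV``.  Zero amplitudes leave the recording unchanged.
    """
    if cfg.drift_freq_hz > 0.5:
        raise ValueError("drift_freq_hz must be <= 0.5 Hz (baseline band)")
    rng = np.random.default_rng(cfg.rng_seed + 1)
    signals = rec.signals.copy()
    t = np.arange(rec.n_samples) / rec.fs
    if cfg.drift_amp_mV > 0:
        phases = rng.uniform(0, 2 * np.pi, size=rec.node_count)
        signals += cfg.drift_amp_mV * np.sin(
            2 * np.pi * cfg.drift_freq_hz * t[None, :] + phases[:, None]
        )
    if cfg.noise_sd_uV > 0:
        signals += (cfg.noise_sd_uV / 1000.0) * rng.standard_normal(signals.shape)
    return dataclasses.replace(rec, signals=signals)
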