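"""End-to-end orchestration: simulate -> preprocess -> bipolar -> cluster
-> TWA -> maps, with seeded reproducibility and a checksummed manifest.

Single-process execution; per-node loops are independent and order-stable,
so a run is a pure function of its configuration.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bipolar import BipolarConfig, compute_bipolar_map
from .clustering import ClusterConfig, cluster_map, kmeans_fit
from .data_model import write_mesh, write_recording, write_region_labels
from .maps import amplitude_map, classify_by_amplitude
from .preprocess import (
    PreprocessConfig,
    extract_beat_window,
    lowpass_filter,
    preprocess_recording,
)
from .synthetic import (
    RegionLayout,
    SynthConfig,
    assign_regions,
    add_artifacts,
    generate_sphere_mesh,
    inject_alternans,
    synthesize_recording,
)
from .twa import TWAConfig, twa_map

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Nested stage configurations plus the run seed.

    ``region_seeds`` / ``region_radii`` define the planted layout (node
    indices and BFS hop radii); ``alternans_nodes`` selects where TWA is
    injected ("none", "all", a region name, or an explicit index list).
    """

    synth: SynthConfig = dataclasses.field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    bipolar: BipolarConfig = dataclasses.field(default_factory=BipolarConfig)
    cluster: ClusterConfig = dataclasses.field(default_factory=ClusterConfig)
    twa: TWAConfig = dataclasses.field(default_factory=TWAConfig)
    region_seeds: dict = dataclasses.field(default_factory=lambda: {"scar": 0, "valve": 1})
    region_radii: dict = dataclasses.field(default_factory=lambda: {
        "scar": 3, "border": 5, "valve": 3})
    alternans_nodes: str | list = "none"
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        for key, sub in (("synth", SynthConfig), ("preprocess", PreprocessConfig),
                         ("bipolar", BipolarConfig), ("cluster", ClusterConfig),
                         ("twa", TWAConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub_kwargs = dict(kwargs[key])
                if key == "synth" and "region_amplitudes" in sub_kwargs:
                    sub_kwargs["region_amplitudes"] = {
                        r: tuple(v) for r, v in sub_kwargs["region_amplitudes"].items()
                    }
                if key == "twa" and "noise_band" in sub_kwargs:
                    sub_kwargs["noise_band"] = tuple(sub_kwargs["noise_band"])
                kwargs[key] = sub(**sub_kwargs)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _alternans_subset(spec, layout: RegionLayout) -> list[int] | None:
    if isinstance(spec, str):
        if spec == "all":
            return None  # inject everywhere
        if spec == "none":
            return []
        return layout.nodes_of(spec).tolist()
    return [int(i) for i in spec]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and return (and write) the run manifest.

    The manifest echoes the configuration, the package version and the
    SHA-256 checksum of every artifact, so a rerun with the echoed
    configuration reproduces the checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    synth = dataclasses.replace(config.synth, rng_seed=config.seed)
    cluster_cfg = dataclasses.replace(config.cluster, rng_seed=config.seed + 1)

    artifacts: dict[str, Path] = {}

    log.info("stage simulate: %d nodes, %d beats", synth.node_count, synth.n_beats)
    mesh = generate_sphere_mesh(synth.node_count, seed=config.seed)
    layout = assign_regions(mesh, config.region_seeds, config.region_radii)
    rec, annotation = synthesize_recording(mesh, layout, synth)
    subset = _alternans_subset(config.alternans_nodes, layout)
    if synth.alternans_delta_uV > 0 and (subset is None or subset):
        rec = inject_alternans(rec, annotation, synth.alternans_delta_uV,
                               subset, synth.t_peak_offset_s, synth.t_alt_width_s)
    rec = add_artifacts(rec, synth)
    artifacts["mesh"] = outdir / "mesh.ply"
    write_mesh(mesh, artifacts["mesh"])
    artifacts["recording"] = outdir / "recording.h5"
    write_recording(rec, artifacts["recording"])
    artifacts["regions"] = outdir / "regions.json"
    write_region_labels(list(layout.labels), artifacts["regions"])

    log.info("stage preprocess")
    # baseline-removed signals keep the sharp depolarization (amplitude
    # maps, bipolar synthesis); the low-passed copy feeds clustering/TWA
    debased, annotation = preprocess_recording(rec, config.preprocess,
                                               annotation, apply_lowpass=False)
    clean = dataclasses.replace(debased, signals=lowpass_filter(
        debased.signals, rec.fs, config.preprocess.lowpass_cutoff_hz,
        config.preprocess.filter_order))
    artifacts["clean"] = outdir / "clean.h5"
    write_recording(clean, artifacts["clean"])

    log.info("stage bipolar: alpha=%d", config.bipolar.alpha_samples)
    bipolar = compute_bipolar_map(debased, mesh, config.bipolar, annotation)
    artifacts["bipolar"] = outdir / "bipolar.h5"
    write_recording(bipolar, artifacts["bipolar"])

    log.info("stage cluster: K=%d metric=%s", cluster_cfg.K, cluster_cfg.metric)
    windows = np.stack([
        extract_beat_window(clean.signals[i], annotation.fiducials[i][0],
                            clean.fs, config.preprocess)[0]
        for i in range(clean.node_count)
    ])
    fit = kmeans_fit(windows, cluster_cfg)
    labels, components = cluster_map(fit, mesh)
    pd.DataFrame({"node": np.arange(labels.size), "label": labels}).to_csv(
        outdir / "cluster_labels.csv", index=False)
    pd.DataFrame(fit.centroids).to_csv(outdir / "cluster_centroids.csv",
                                       index=False)
    artifacts["cluster_labels"] = outdir / "cluster_labels.csv"
    artifacts["cluster_centroids"] = outdir / "cluster_centroids.csv"

    log.info("stage twa")
    twa_frames = {}
    for method in ("tm", "sm", "mma"):
        result = twa_map(clean, annotation, mesh, method, config.preprocess,
                         config.twa)
        frame = pd.DataFrame({"node": np.arange(result.markers.size),
                              "marker_uV": result.markers})
        if result.k_scores is not None:
            frame["k_score"] = result.k_scores
        path = outdir / f"twa_{method}.csv"
        frame.to_csv(path, index=False)
        artifacts[f"twa_{method}"] = path
        twa_frames[method] = frame

    log.info("stage maps")
    amps = amplitude_map(debased, annotation)
    classes = [classify_by_amplitude(a, debased.kind) if np.isfinite(a) else "missing"
               for a in amps]
    pd.DataFrame({"node": np.arange(amps.size), "amplitude_mV": amps,
                  "class": classes, "true_region": list(layout.labels)}).to_csv(
        outdir / "amplitude_map.csv", index=False)
    artifacts["amplitude_map"] = outdir / "amplitude_map.csv"

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "cluster_components": components,
        "artifacts": {
            name: {"path": str(path.name), "sha256": _sha256(path)}
            for name, path in sorted(artifacts.items())
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
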