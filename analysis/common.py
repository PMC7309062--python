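"""Shared study definitions for the analysis scripts.

One synthetic "infarction" study stands in for the clinical epicardial
maps: a 502-node sphere with a scar patch, a border ring around it, a
valve patch, and healthy tissue elsewhere, sampled at 2048 Hz.
"""
from pathlib import Path

import ecgist as e

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def make_infarction_study(seed: int = 1, n_nodes: int = 502, n_beats: int = 8,
                          delta_uV: float = 0.0, noisy: bool = True):
    """Mesh, region layout, config, recording and ground-truth annotation.

    ``delta_uV`` > 0 injects T-wave alternans into the scar patch.
    """
    mesh = e.generate_sphere_mesh(n_nodes, seed=seed)
    layout = e.assign_regions(mesh, {"scar": 0, "valve": n_nodes // 2},
                              {"scar": 3, "border": 5, "valve": 3})
    cfg = e.SynthConfig(node_count=n_nodes, n_beats=n_beats, rng_seed=seed)
    rec, ann = e.synthesize_recording(mesh, layout, cfg)
    if delta_uV > 0:
        rec = e.inject_alternans(rec, ann, delta_uV,
                                 node_subset=layout.nodes_of("scar"))
    if noisy:
        rec = e.add_artifacts(rec, cfg)
    return mesh, layout, cfg, rec, ann
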