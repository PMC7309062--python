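"""Per-node T-wave alternans maps: alternans-positive vs control.

Runs all three estimators (temporal, spectral, MMA) on two studies built
from the same mesh and morphology: a "control" with no alternans and an
"LQTS-like" study with 40 uV injected in the scar patch, both with 32
beats (the spectral method needs several noise-band bins, so short
records are underpowered), broadband noise and baseline drift.  Reports
the in-patch vs out-of-patch marker separation and the fraction of
spectrally significant nodes (K > 3).
"""
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, make_infarction_study  # noqa: E402

import ecgist as e  # noqa: E402


def marker_table(mesh, clean, ann, patch_mask, study):
    rows = []
    for method in ("tm", "sm", "mma"):
        result = e.twa_map(clean, ann, mesh, method)
        row = {
            "study": study, "method": method,
            "in_patch_median_uV": round(float(np.nanmedian(result.markers[patch_mask])), 2),
            "outside_median_uV": round(float(np.nanmedian(result.markers[~patch_mask])), 2),
            "outside_q90_uV": round(float(np.nanquantile(result.markers[~patch_mask], 0.9)), 2),
        }
        if result.k_scores is not None:
            finite = np.isfinite(result.k_scores)
            row["frac_k_gt3"] = round(float(np.mean(result.k_scores[finite] > 3)), 3)
        rows.append(row)
    return rows


def main() -> None:
    rows = []
    for study, delta in (("control", 0.0), ("lqts_like", 40.0)):
        mesh, layout, cfg, rec, ann = make_infarction_study(
            seed=2, n_beats=32, delta_uV=delta)
        clean, ann = e.preprocess_recording(rec, annotation=ann)
        patch = np.isin(np.arange(mesh.node_count), layout.nodes_of("scar"))
        rows += marker_table(mesh, clean, ann, patch, study)
    frame = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    frame.to_csv(RESULTS / "04_twa_markers.csv", index=False)
    print(frame.to_string(index=False))
    print("\nIn the alternans-positive study the in-patch markers should "
          "clear the outside 90th percentile for every estimator; in the "
          "control the two are indistinguishable.")


if __name__ == "__main__":
    main()
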