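# ecgist

Spatial–temporal analysis of electrocardiographic-imaging (ECGI)
potential maps: electrogram morphology clustering, bipolar-electrogram
synthesis, and per-node T-wave alternans (TWA) estimation on triangulated
body-surface and epicardial meshes.

ECGI systems estimate hundreds of unipolar electrograms (EGMs) on the
epicardium from dense torso recordings.  Electrophysiologists, however,
reason in terms of bipolar EGMs, voltage-based tissue classes (scar,
border zone, healthy) and repolarization instability markers.  This
package bridges the two: it takes a node × time potential matrix plus its
surface mesh and produces

* **bipolar EGMs** via a digital operator: β(s̄ᵢ, t) = v(s̄ᵢ, t) −
  v(s̄ₖ, t − α), where s̄ₖ is the mesh neighbor of s̄ᵢ with the largest
  first-beat peak-to-peak amplitude and α = 40 samples (≈ 20 ms at
  2048 Hz);
* **regionalizations** by K-means over per-node beat waveforms under four
  distances — L2 (‖x−c‖₂², centroid = mean), L1 (|x−c|₁, centroid =
  coordinate-wise median), cosine (1 − cos(x,c), centroid = mean of
  unit-normalized members) and correlation (1 − corr(x,c), centroid =
  mean of centered unit-norm members);
* **TWA markers** per node from the beat-by-sample repolarization matrix
  M = [x₀ᵀ; …; x_{M−1}ᵀ] = [s₀, …, s_{N−1}]:
  * *Spectral Method*: aggregate periodogram P(f) over cycles/beat,
    K-score = (P(0.5) − μ_noise)/σ_noise with noise statistics from
    [0.33, 0.49) cycles/beat; K > 3 is the usual significance level;
    V_alt = P(0.5) − μ_noise;
  * *Modified Moving Average*: recursive even/odd estimates
    x̂ₘ = x̂ₘ₋₂ + hₘ₋₂ with a limited update h, alternant waves
    v_l = x̂₂ₗ₋₁ − x̂₂ₗ₋₂ and magnitudes V_l = maxₙ|v_l|;
  * *Temporal Method*: V_alt = ½ maxₙ |x̄_odd − x̄_even| from the
    even/odd sample-mean templates;
* **maps and M-modes**: first-beat peak-to-peak amplitude maps, clinical
  voltage classification (unipolar: scar ≤ 3 mV, border 3–5 mV, healthy
  ≥ 5 mV; bipolar: < 0.5, 0.5–1.5, > 1.5 mV), shortest mesh paths and
  stacked-signal M-mode slices.

Because clinical ECGI datasets are not redistributable, the package ships
a synthetic generator (`ecgist.synthetic`) that produces closed
triangulated spheres, planted scar/border/valve/healthy regions with the
voltage structure above, injected alternans of known magnitude, baseline
drift and broadband noise — with exact ground truth for every quantity
the analyses estimate.

## Worked example

```bash
python analysis/02_cluster_regionalization.py
```

clusters the first-beat waveforms of a 502-node synthetic infarction
study (noisy, 2048 Hz) and prints:

```
     metric  K   ari  components_per_cluster
         l1  4 0.453                       6
         l2  4 0.452                       5
     cosine  4 0.925                       4
correlation  4 0.945                       4
     cosine  3 0.649                       1
     cosine  5 0.486                       8
     cosine  6 0.482                       8
```

`ari` is the adjusted Rand index against the planted regions and
`components_per_cluster` the worst cluster's number of edge-connected
mesh patches.  The scale/offset-invariant distances (cosine,
correlation) recover the planted anatomy almost exactly, while the
amplitude-driven L1/L2 distances split it into disconnected fragments —
electrogram *shape*, not amplitude, carries the regional information.

`analysis/04_twa_maps.py` compares the three TWA estimators on a control
study and on one with a 40 µV alternans half-difference injected in the
scar patch (32 beats, noise and drift):

```
    study method  in_patch_median_uV  outside_median_uV  outside_q90_uV  frac_k_gt3
  control     tm                2.47               2.46            3.08
  control     sm                0.00               0.00            0.00        0.00
  control    mma               24.86              25.69           34.58
lqts_like     tm               39.73               2.46            3.08
lqts_like     sm            14314.44               0.00            0.00        0.07
lqts_like    mma               85.55              25.69           34.58
```

The temporal method recovers the injected 40 µV nearly exactly inside
the patch against a ~3 µV floor elsewhere; the spectral K-score flags
7% of nodes — the patch itself (35/502 ≈ 7%) — and none in the control;
MMA reads ≈ 2δ = 80 µV in the patch, clearly above its out-of-patch
noise floor.

The same stages are scriptable via the CLI:

```bash
ecgi-st simulate --nodes 502 --seed 1 --delta-uv 30 --out run/
ecgi-st twa --recording run/recording.h5 --mesh run/mesh.ply --method sm --out run/twa_sm.csv
ecgi-st run --seed 1 --out run/full   # simulate → preprocess → bipolar → cluster → twa → maps
```

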