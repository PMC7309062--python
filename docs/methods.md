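# Methods

This note documents the models, conventions and numerical choices behind
`ecgist`, and what the synthetic studies do and do not establish.

## Data model and conventions

A study is a triangulated surface mesh (node coordinates in mm,
triangles as index triples) plus one potential signal per node, in mV,
at a common sampling rate (2048 Hz throughout the shipped studies).  All
node and sample indices are 0-based; sample intervals are half-open
`[start, end)`; every time-to-index conversion truncates, so a 0.3 s
window at 2048 Hz is `int(0.3 * 2048) = 614` samples and the clustering
window places its peak at index `int(0.33 * 2048) = 675`.  Mesh
adjacency is shared-triangle-edge adjacency; it is symmetric by
construction and is the substrate for neighbor selection, region
growing, cluster-component diagnostics and shortest paths (breadth-first
search with lowest-index tie-breaking, so paths are reproducible).

Recordings round-trip losslessly through an HDF5 container (`signals`
dataset; `fs`, `kind`, `mesh_ref` attributes; dataset timestamps
disabled so files are byte-reproducible), meshes through ASCII OFF/PLY.

## Synthetic generator

The generator emulates the statistical structure the analyses assume,
not cardiac biophysics.  Spheres come from a Fibonacci lattice under a
seeded random rotation, triangulated by its convex hull (Euler
characteristic 2; 12 nodes returns the regular icosahedron).  Regions
grow by BFS hop radius around seed nodes with priority valve > scar >
border; a border radius without its own seed grows around the scar seed,
yielding the border annulus of infarct anatomy.

Each node repeats one beat template: depolarization as a difference of
Gaussians whose dominant absolute peak is shifted exactly onto the
fiducial sample (so ground-truth fiducials coincide with what a peak
detector finds), a wider T-wave Gaussian 0.25 s later, and — in
scar/border/valve — extra 5 ms deflections emulating fragmentation.
T-wave and fragmentation amplitudes are scaled relative to the measured
depolarization peak (T at 20–35% depending on region) so depolarization
always dominates detection.  Peak-to-peak amplitude is drawn per node
from its region's range — defaults scar 1.0–2.8 mV, border 3.3–4.7 mV,
valve 0.8–2.5 mV, healthy 5.5–9.0 mV, respecting the clinical unipolar
bands — after mapping a spatially smoothed Gaussian field through the
normal CDF, so neighbors vary smoothly.  Morphology parameters get ±8%
spatially correlated jitter via the same diffusion-smoothed fields.
Region-distinct *shapes* (widths, T polarity, fragmentation), not just
amplitudes, are what make the clustering study meaningful: cosine and
correlation distances are amplitude-blind by design.

**Alternans convention.** `delta_uV` is *half* the even/odd T-amplitude
difference: even-indexed beats (0-based; beat 0 is even) receive
−δ·g(t), odd beats +δ·g(t), with g a unit-peak Gaussian (width 50 ms)
centered 0.25 s after each fiducial.  Consequently the Temporal Method
recovers exactly δ and the MMA magnitudes equal 2δ on stationary
alternation — the factor of two is intentional and tested.

Artifacts are additive and seeded: sinusoidal baseline drift (default
0.2 mV at 0.3 Hz, random phase per node — below the 0.3–15 Hz alternans
band) and white noise (default SD 10 µV, the scale at which spectral
detection is conventionally exercised).

What the generator does **not** model: conduction, activation sequences
(no inter-node delays, so the bipolar delay α never aligns two real
wavefronts), beat-to-beat rate variability, nonstationary or
phase-reversing alternans, electrode noise correlation, and the
regularization bias of real inverse solutions.  Passing tests therefore
establish correctness of the estimators and pipelines under their own
assumptions, not clinical performance.

## Preprocessing

The conditioning chain is: beat detection → per-beat spline baseline
removal → zero-phase low-pass.

* **Beat detection** finds local maxima of |signal| separated by a
  200 ms refractory period and accepts those exceeding 0.4 × an
  exponentially averaged recent peak amplitude (EWMA weight 0.2, seeded
  from the strongest peak of the first 2 s) — scale-invariant by
  construction.  Detection runs on a zero-phase 0.5–40 Hz band-limited
  copy: baseline wander shifts the threshold and broadband noise
  fragments peaks otherwise; returned indices refer to the original
  grid.
* **Baseline removal** fits a cubic spline through per-beat isoelectric
  levels (median of ±25 ms around each knot) and subtracts it, holding
  the spline at its edge values outside the knot span.  Knots default to
  150 ms before each fiducial: mid-diastole is quiet on both raw and
  filtered signals, whereas a knot just before the QRS sits inside the
  ~1/cutoff-wide smear that a 15 Hz zero-phase filter makes of the
  depolarization, which would subtract real signal on reprocessed data.
  Fewer than 4 knots (cubic spline underdetermined) falls back to linear
  detrending with a logged warning.
* **Low-pass**: 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`), cutoff 15 Hz — the top of the alternans band.  Zero
  phase, passband tones preserved within 1%, ≥ 20 dB at 3× cutoff.
  The filter necessarily flattens the sharp depolarization, so
  peak-to-peak amplitude maps, voltage classification and bipolar
  synthesis run on the baseline-removed but *unfiltered* signals
  (`apply_lowpass=False`), while clustering windows and TWA segments use
  the filtered ones.
* **Windows.**  Clustering observations are single 1.25 s beat windows
  with the absolute peak at 0.33 s (edge beats zero-padded and flagged).
  Repolarization segments are 300 ms windows starting 60 ms after the
  fiducial (the offset is configurable; nothing downstream is sensitive
  to it on synthetic data); incomplete segments are dropped because the
  even/odd algebra needs complete beats, and fewer than 2 usable beats
  is an error.
* **Alignment** maximizes the dot product of each segment with the
  pointwise-median template over circular shifts within ±20 ms,
  breaking exact ties toward the smaller |lag|.

## Bipolar operator

β[t] = v_i[t] − v_k[t − α] with α = 40 samples by default.  The neighbor
k is fixed per node (stable maps) as the mesh neighbor with the largest
first-beat peak-to-peak amplitude, ties to the lowest index.  The first
α samples subtract a zero-padded neighbor; amplitude windows in the
shipped studies start after sample α, so the padded region never enters
a measurement.  On synthetic data, where neighboring waveforms are
similar but not time-shifted by propagation, the operator behaves like a
smoothed differencer; it preserves the scar < healthy amplitude ordering
but the absolute bipolar voltages do not sit inside the clinical
0.5/1.5 mV bands — those thresholds presuppose real far-field
cancellation.

## Clustering

K-means alternates nearest-centroid assignment (ties to the lowest
cluster index) with the metric-matched centroid update listed in the
README; that pairing is what makes the objective — the summed
point-to-centroid distance under the chosen metric — non-increasing, a
property asserted on every fit.  L2 uses the *squared* Euclidean norm.
Degenerate vectors (zero norm under cosine, constant under correlation)
get a defined fallback distance of 1 with a warning.  Initialization is
distance-weighted (k-means++-style) seeding from the data under the
fit's own metric; 10 restarts by default, best final objective kept;
convergence on unchanged labels or objective improvement ≤ `tol` (0 by
default), capped at 300 iterations.  Empty clusters are re-seeded with
the observation farthest from its centroid.  `cluster_map` reindexes
labels by descending cluster size and reports edge-connected components
per cluster — the spatial-compactness diagnostic that separates the
cosine/correlation regionalizations from the L1/L2 ones.

## TWA estimation

The beat matrix stacks aligned repolarization segments (converted to µV)
in beat order, dropping the last beat of an odd count.

* **Spectral**: per-column periodogram |FFT|²/M of the mean-removed beat
  series, averaged over the N columns; the alternans bin is 0.5
  cycles/beat (exactly the Nyquist bin of the beat series).  Noise mean
  and SD come from the aggregate spectrum on [0.33, 0.49) cycles/beat —
  a standard choice; the band is configurable.  V_alt = P(0.5) −
  μ_noise is clipped at 0 and, following the source convention, is a
  *power* excess (no square root), so it is comparable across nodes but
  not in amplitude units.  σ_noise = 0 (e.g. M = 8 leaves a single band
  bin) yields an infinity sentinel with a warning; M < 8 warns.  The
  shipped alternans studies use 32 beats, which gives 5 band bins and a
  calibrated K (null fraction of K > 3 ≈ 0.2% at 502 nodes); short
  8-beat demos exercise the plumbing, not spectral detection.
* **MMA**: x̂₀ = x₀, x̂₁ = x₁, then x̂ₘ = x̂ₘ₋₂ + h with h from the
  innovation Δ = xₘ − x̂ₘ₋₂.  The limited update is
  h = sign(Δ)·min(|Δ|/8, h_max), h_max = 32 µV — a parametric stand-in
  for the classical 1/8-limited schedule, exposed in config — plus an
  unlimited mode h = Δ/2 used for analytic tests.  Because the
  recursion starts from raw beats, early alternant waves are noise; the
  per-node *map* marker is max V_l over the second half of the pairs
  (`mma_burnin_frac = 0.5`), while `mma_method` itself returns every
  V_l.
* **Temporal**: even/odd sample means, V_alt = ½ max |difference| — on
  noiseless alternation this recovers the injected δ to machine
  precision through the entire chain, the package's strongest
  end-to-end invariant (tested at 1% through baseline removal and
  filtering, whose passband ripple is the only loss).

`twa_map` applies extract → align → matrix → estimator per node with one
shared configuration; nodes failing a precondition get NaN and one
aggregated log line.

## Problem sizes and determinism

The shipped studies use 502-node spheres (8 beats for waveform analyses,
32 for spectral/TWA detection) and a 1002-node × 8-beat demo pipeline —
the full demo completes in well under a minute of CPU.  Ten-seed medians
back every stochastic claim.  All randomness flows through explicit
integer seeds (one `numpy` generator per call); the pipeline manifest
echoes its configuration and SHA-256 checksums, and a rerun with the
same seed reproduces every checksum bit for bit.

## Known limitations

Valve and scar tissue are indistinguishable by amplitude alone (both
< 3 mV unipolar); the voltage classifier labels both "scar" and the
docstring says so.  The spectral V_alt is a power, not a µV amplitude.
The MMA limiting schedule is a documented stand-in.  Region growing by
hop count makes geodesically irregular patches on coarse meshes.  None
of the clinical thresholds have been validated against ECGI-estimated
potentials with real regularization distortion.
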