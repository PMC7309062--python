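"""T-wave alternans estimation from beat-by-sample repolarization matrices.

Given M aligned repolarization segments of N samples each, stacked as a
matrix with rows ``x_m`` (beats) and columns ``s_n`` (beat series), three
estimators quantify the every-other-beat alternation:

* Spectral Method (SM): per-column periodograms averaged into an
  aggregate spectrum P(f) over cycles/beat; the K-score
  ``(P(0.5) - mu_noise) / sigma_noise`` compares the alternans bin with a
  noise band near it, and K > 3 is the conventional significance level.
  The alternans estimate is ``Valt = P(0.5) - mu_noise`` (clipped at 0).
* Modified Moving Average (MMA): recursive even/odd estimates
  ``xhat_m = xhat_{m-2} + h_{m-2}`` with a limited (nonlinear) update h;
  alternant waves ``v_l = xhat_{2l-1} - xhat_{2l-2}`` and magnitudes
  ``V_l = max_n |v_l|``.
* Temporal Method (TM): even/odd sample-mean templates;
  ``Valt = 0.5 * max_n |xbar_odd - xbar_even|``.

Beat indexing is 0-based throughout: beat 0 is "even".  With an injected
half-difference delta, TM recovers exactly delta and MMA's V_l equals
2*delta.  Matrix values are in microvolts, so all magnitudes are uV.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

from .data_model import BeatAnnotation, PotentialRecording, SurfaceMesh
from .preprocess import PreprocessConfig, align_segments, extract_repolarization

log = logging.getLogger(__name__)

MISSING = np.nan  # per-node sentinel when an estimator's preconditions fail


@dataclasses.dataclass
class RepolarizationMatrix:
    """M x N beat-by-sample matrix (uV): row m = beat m, column n = beat
    series of sample n."""

    M: np.ndarray
    fs: float
    node: int = -1

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2 or self.M.shape[0] < 2:
            raise ValueError("matrix needs >= 2 beat rows")

    @property
    def n_beats(self) -> int:
        return self.M.shape[0]

    @property
    def n_samples(self) -> int:
        return self.M.shape[1]


@dataclasses.dataclass
class SpectralResult:
    freqs: np.ndarray          # cycles/beat
    aggregate_psd: np.ndarray
    K_score: float
    Valt_uV: float
    noise_mean: float
    noise_sd: float


@dataclasses.dataclass
class MMAResult:
    even_estimates: np.ndarray   # xhat of even beats
    odd_estimates: np.ndarray
    alternant_waves: np.ndarray  # (M//2, N): v_l
    magnitudes: np.ndarray       # V_l per pair
    max_magnitude_uV: float


@dataclasses.dataclass
class TemporalResult:
    template_even: np.ndarray
    template_odd: np.ndarray
    Valt_uV: float


@dataclasses.dataclass
class TWAConfig:
    """Estimator tuning shared by every node of a map."""

    noise_band: tuple[float, float] = (0.33, 0.49)  # cycles/beat, half-open
    mma_limiting: str = "standard"                  # or "none"
    mma_h_max_uV: float = 32.0
    # fraction of beat pairs discarded before the per-node MMA map marker:
    # the recursion starts from two raw beats and its transient decays by
    # 7/8 per pair, so early alternant waves reflect noise, not alternans
    mma_burnin_frac: float = 0.5
    alignment_max_lag_ms: float = 20.0


def build_beat_matrix(segments: np.ndarray, fs: float,
                      node: int = -1) -> RepolarizationMatrix:
    """Stack aligned segments into the beat matrix; an odd count drops the
    last beat so even/odd pairing is complete."""
    segments = np.asarray(segments, dtype=float)
    if segments.ndim != 2:
        raise ValueError("segments must be a 2-D (beat, sample) array of "
                         "equal-length rows")
    m = segments.shape[0]
    if m % 2 == 1:
        segments = segments[: m - 1]
    return RepolarizationMatrix(segments, fs, node)


def spectral_method(mat: RepolarizationMatrix,
                    cfg: TWAConfig | None = None) -> SpectralResult:
    """Aggregate-periodogram spectral analysis of the beat series.

    Each column (beat series) is mean-removed and its periodogram
    ``|FFT|^2 / M`` computed; the aggregate spectrum averages the N
    columns.  Noise statistics come from the configured band (default
    [0.33, 0.49) cycles/beat).  Needs an even M; fewer than 8 beats only
    warns (the spectral resolution is then poor).
    """
    cfg = cfg or TWAConfig()
    X = mat.M
    m = X.shape[0]
    if m < 8:
        warnings.warn(f"spectral method with M={m} < 8 beats is unreliable")
    X = X - X.mean(axis=0, keepdims=True)
    spec = np.abs(np.fft.rfft(X, axis=0)) ** 2 / m
    freqs = np.fft.rfftfreq(m, d=1.0)
    aggregate = spec.mean(axis=1)
    lo, hi = cfg.noise_band
    band = (freqs >= lo) & (freqs < hi)
    if not band.any():
        raise ValueError(f"noise band {cfg.noise_band} contains no frequency bin "
                         f"for M={m} beats")
    mu = float(aggregate[band].mean())
    sd = float(aggregate[band].std())
    p_alt = float(aggregate[np.argmin(np.abs(freqs - 0.5))])
    if sd == 0:
        log.warning("spectral method: zero noise SD; K-score reported as inf")
        k_score = np.inf if p_alt > mu else 0.0
    else:
        k_score = (p_alt - mu) / sd
    return SpectralResult(freqs, aggregate, float(k_score),
                          max(p_alt - mu, 0.0), mu, sd)


def mma_method(mat: RepolarizationMatrix,
               cfg: TWAConfig | None = None) -> MMAResult:
    """Modified Moving Average estimation.

    Even and odd beat streams are tracked separately by the recursion
    ``xhat_m = xhat_{m-2} + h_{m-2}`` with ``xhat_0 = x_0``,
    ``xhat_1 = x_1``.  The update h is computed from the innovation
    ``delta = x_m - xhat_{m-2}``: with ``standard`` limiting
    ``h = sign(delta) * min(|delta| / 8, h_max)``; with ``none``
    ``h = delta / 2`` (half-step toward the incoming beat, exact on
    stationary alternation).  Alternant waves are the per-pair differences
    of the odd and even estimates.
    """
    cfg = cfg or TWAConfig()
    X = mat.M
    m = X.shape[0]
    if m < 4:
        raise ValueError(f"MMA needs >= 4 beats, got {m}")
    xhat = np.empty_like(X)
    xhat[0], xhat[1] = X[0], X[1]
    for i in range(2, m):
        delta = X[i] - xhat[i - 2]
        if cfg.mma_limiting == "none":
            h = delta / 2.0
        elif cfg.mma_limiting == "standard":
            h = np.sign(delta) * np.minimum(np.abs(delta) / 8.0, cfg.mma_h_max_uV)
        else:
            raise ValueError(f"unknown limiting mode {cfg.mma_limiting!r}")
        xhat[i] = xhat[i - 2] + h
    pairs = m // 2
    waves = np.stack([xhat[2 * l - 1] - xhat[2 * l - 2]
                      for l in range(1, pairs + 1)])
    mags = np.abs(waves).max(axis=1)
    return MMAResult(xhat[0::2], xhat[1::2], waves, mags, float(mags.max()))


def temporal_method(mat: RepolarizationMatrix) -> TemporalResult:
    """Temporal Method: half the maximum absolute difference between the
    even- and odd-beat sample-mean templates."""
    X = mat.M
    even = X[0::2].mean(axis=0)
    odd = X[1::2].mean(axis=0)
    return TemporalResult(even, odd, float(0.5 * np.abs(odd - even).max()))


@dataclasses.dataclass
class TWAMap:
    """Per-node alternans markers over a mesh."""

    method: str
    markers: np.ndarray                 # uV (TM/MMA) or uV-scale power (SM Valt)
    k_scores: np.ndarray | None = None  # SM only
    traces: np.ndarray | None = None    # per-node alternant wave / template diff


def twa_map(rec: PotentialRecording, annotation: BeatAnnotation,
            mesh: SurfaceMesh, method: str,
            pre_cfg: PreprocessConfig | None = None,
            twa_cfg: TWAConfig | None = None) -> TWAMap:
    """Per-node alternans map with identical tuning for every node.

    For each node: extract 300 ms repolarization segments, align them to
    the median template, build the beat matrix (mV -> uV) and run the
    requested estimator (``tm``, ``sm`` or ``mma``).  Nodes failing a
    precondition (too few complete beats) get a NaN marker and are logged.
    """
    if method not in ("tm", "sm", "mma"):
        raise ValueError(f"method must be 'tm', 'sm' or 'mma', got {method!r}")
    pre_cfg = pre_cfg or PreprocessConfig()
    twa_cfg = twa_cfg or TWAConfig()
    if mesh.node_count != rec.node_count:
        raise ValueError("recording does not match mesh node count")
    n = rec.node_count
    markers = np.full(n, MISSING)
    k_scores = np.full(n, MISSING) if method == "sm" else None
    traces = None
    max_lag = max(1, int(twa_cfg.alignment_max_lag_ms / 1000.0 * rec.fs))
    skipped: list[int] = []
    prior_level = log.level
    log.setLevel(logging.ERROR)  # per-node notices aggregated below
    for i in range(n):
        try:
            segments = extract_repolarization(rec.signals[i],
                                              annotation.fiducials[i],
                                              rec.fs, pre_cfg)
            aligned, _ = align_segments(segments, max_lag)
            mat = build_beat_matrix(aligned * 1000.0, rec.fs, node=i)  # mV->uV
            if method == "tm":
                res = temporal_method(mat)
                markers[i] = res.Valt_uV
                trace = res.template_odd - res.template_even
            elif method == "sm":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sres = spectral_method(mat, twa_cfg)
                markers[i] = sres.Valt_uV
                k_scores[i] = sres.K_score
                trace = sres.aggregate_psd
            else:
                mres = mma_method(mat, twa_cfg)
                burnin = min(int(len(mres.magnitudes) * twa_cfg.mma_burnin_frac),
                             len(mres.magnitudes) - 1)
                markers[i] = float(mres.magnitudes[burnin:].max())
                trace = mres.alternant_waves[burnin + int(
                    np.argmax(mres.magnitudes[burnin:]))]
            if traces is None:
                traces = np.zeros((n, trace.size))
            traces[i] = trace
        except ValueError as exc:
            skipped.append(i)
            last_error = str(exc)
    log.setLevel(prior_level)
    if skipped:
        log.warning("twa_map(%s): %d node(s) skipped (e.g. node %d: %s)",
                    method, len(skipped), skipped[0], last_error)
    if method == "sm" and k_scores is not None and np.isinf(k_scores).any():
        log.warning("twa_map(sm): %d node(s) with zero noise SD (K = inf); "
                    "the noise band holds few bins at this beat count",
                    int(np.isinf(k_scores).sum()))
    return TWAMap(method, markers, k_scores, traces)
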