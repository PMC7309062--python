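"""Signal conditioning for per-node electrograms.

Chain: cubic-spline baseline removal, zero-phase low-pass filtering in the
alternans band (cutoff 15 Hz by default), adaptive-threshold beat
detection, fixed-length beat windowing for clustering, 300 ms
repolarization windowing, and cross-correlation alignment against a median
template.

All time-to-index conversions truncate (floor): a window of ``w`` seconds
at rate ``fs`` spans ``int(w * fs)`` samples.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, detrend, find_peaks, sosfiltfilt

from .data_model import BeatAnnotation, PotentialRecording

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PreprocessConfig:
    """Conditioning parameters.

    ``lowpass_cutoff_hz`` bounds the alternans band; ``repol_window_ms`` is
    the repolarization segment length and ``repol_offset_ms`` its distance
    from the fiducial; ``beat_window_s`` / ``peak_position_s`` define the
    clustering segmentation (absolute peak placed at 0.33 s of a 1.25 s
    window); ``alignment_max_lag_ms`` caps the alignment search.
    """

    lowpass_cutoff_hz: float = 15.0
    filter_order: int = 4
    repol_window_ms: float = 300.0
    repol_offset_ms: float = 60.0
    beat_window_s: float = 1.25
    peak_position_s: float = 0.33
    alignment_max_lag_ms: float = 20.0
    refractory_s: float = 0.2
    threshold_frac: float = 0.4
    ewma_alpha: float = 0.2
    # knots sit in mid-diastole: far enough before the fiducial that the
    # 15 Hz-filtered depolarization smear (~1/cutoff wide) does not reach them
    knot_lead_ms: float = 150.0
    isoelectric_halfwidth_ms: float = 25.0

    def __post_init__(self) -> None:
        if self.repol_window_ms <= 0 or self.beat_window_s <= 0:
            raise ValueError("window lengths must be positive")
        if not 0 < self.peak_position_s < self.beat_window_s:
            raise ValueError("peak_position_s must lie inside the beat window")


def remove_baseline(signal: np.ndarray, fs: float,
                    knots: np.ndarray) -> np.ndarray:
    """Subtract the cubic spline through per-beat isoelectric levels.

    The level at each knot is the median of the signal in a +/-25 ms
    neighborhood (robust to residual noise).  Outside the knot span the
    spline is held at its edge values.  With fewer than 4 knots (cubic
    spline underdetermined) the function falls back to linear detrending
    and logs a warning.
    """
    signal = np.asarray(signal, dtype=float)
    knots = np.unique(np.asarray(knots, dtype=np.int64))
    if knots.size and (knots.min() < 0 or knots.max() >= signal.size):
        raise ValueError("knots must lie within the signal")
    if knots.size < 4:
        log.warning("baseline removal: %d knot(s) < 4, falling back to "
                    "linear detrend", knots.size)
        return detrend(signal, type="linear")
    half = int(cfg_ms_to_samples(25.0, fs))
    levels = np.array([
        np.median(signal[max(0, k - half): k + half + 1]) for k in knots
    ])
    spline = CubicSpline(knots, levels)
    x = np.arange(signal.size)
    baseline = spline(np.clip(x, knots[0], knots[-1]))
    return signal - baseline


def cfg_ms_to_samples(ms: float, fs: float) -> int:
    return int(ms / 1000.0 * fs)


def lowpass_filter(signal: np.ndarray, fs: float,
                   cutoff_hz: float = 15.0, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass.

    Works along the last axis, so a whole (node, sample) matrix can be
    filtered in one call.  Zero group delay by construction; the effective
    magnitude response is the square of a single Butterworth pass.
    """
    if cutoff_hz >= fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {fs / 2}")
    sos = butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=-1)


def detect_beats(signal: np.ndarray, fs: float,
                 cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Adaptive-threshold detection of depolarization peaks.

    Local maxima of ``|signal|`` separated by at least the refractory
    period are accepted when they exceed ``threshold_frac`` times an
    exponentially averaged recent peak amplitude.  Detection runs on a
    zero-phase 0.5-40 Hz band-limited copy (baseline wander and broadband
    noise destabilize the threshold otherwise); returned indices refer to
    the original sampling grid.  Invariant under positive amplitude
    scaling; a flat signal yields an empty array.
    """
    cfg = cfg or PreprocessConfig()
    signal = np.asarray(signal, dtype=float)
    refractory = max(1, int(cfg.refractory_s * fs))
    hp, lp = 0.5, min(40.0, 0.45 * fs)
    if lp > hp and signal.size > 32:
        try:
            sos = butter(2, [hp, lp], btype="band", fs=fs, output="sos")
            signal = sosfiltfilt(sos, signal)
        except ValueError:
            pass  # signal too short to pad; detect on the raw trace
    mag = np.abs(signal)
    candidates, _ = find_peaks(mag, distance=refractory)
    if candidates.size == 0:
        return np.array([], dtype=np.int64)
    amps = mag[candidates]
    # seed the running level from the strongest peak of the first 2 s
    early = amps[candidates < int(2.0 * fs)]
    ewma = float(early.max() if early.size else amps[0])
    accepted = []
    for idx, a in zip(candidates, amps):
        if a >= cfg.threshold_frac * ewma:
            accepted.append(int(idx))
            ewma = (1.0 - cfg.ewma_alpha) * ewma + cfg.ewma_alpha * float(a)
    return np.array(accepted, dtype=np.int64)


def extract_beat_window(signal: np.ndarray, fiducial: int, fs: float,
                        cfg: PreprocessConfig | None = None
                        ) -> tuple[np.ndarray, bool]:
    """Fixed-length beat window with the fiducial at ``peak_position_s``.

    Returns ``(window, padded)``; edge beats are zero-padded and flagged.
    Length is ``int(beat_window_s * fs)`` and the fiducial lands at index
    ``int(peak_position_s * fs)`` (675 for the defaults at 2048 Hz).
    """
    cfg = cfg or PreprocessConfig()
    signal = np.asarray(signal, dtype=float)
    length = int(cfg.beat_window_s * fs)
    peak_idx = int(cfg.peak_position_s * fs)
    start = int(fiducial) - peak_idx
    end = start + length
    window = np.zeros(length)
    src_lo, src_hi = max(0, start), min(signal.size, end)
    window[src_lo - start: src_hi - start] = signal[src_lo:src_hi]
    padded = start < 0 or end > signal.size
    return window, padded


def extract_repolarization(signal: np.ndarray, fiducials: np.ndarray,
                           fs: float, cfg: PreprocessConfig | None = None
                           ) -> np.ndarray:
    """Per-beat repolarization segments: ``repol_window_ms`` windows
    starting ``repol_offset_ms`` after each fiducial.

    Beats whose window exceeds the record are dropped (the alternans math
    needs complete segments).  Fewer than 2 usable beats is an error.
    Returns an (M, N) array with N = ``int(0.3 * fs)`` at the defaults.
    """
    cfg = cfg or PreprocessConfig()
    signal = np.asarray(signal, dtype=float)
    n = int(cfg.repol_window_ms / 1000.0 * fs)
    offset = int(cfg.repol_offset_ms / 1000.0 * fs)
    segments = []
    for fid in np.asarray(fiducials, dtype=np.int64):
        start = int(fid) + offset
        if start < 0 or start + n > signal.size:
            continue
        segments.append(signal[start: start + n])
    if len(segments) < 2:
        raise ValueError(
            f"only {len(segments)} usable repolarization segment(s); "
            "alternans is undefined with fewer than 2"
        )
    return np.stack(segments)


def align_segments(segments: np.ndarray,
                   max_lag: int = 40) -> tuple[np.ndarray, np.ndarray]:
    """Circularly align segments to their pointwise-median template.

    Each segment is rolled by the integer lag in ``[-max_lag, max_lag]``
    maximizing its dot product with the template; exact ties break toward
    the smaller ``|lag|`` (then the positive one).  Returns the aligned
    stack and the applied lags, so a segment built as ``roll(base, +s)``
    recovers lag ``-s``.
    """
    segments = np.asarray(segments, dtype=float)
    if segments.ndim != 2 or segments.shape[0] < 2:
        raise ValueError("need >= 2 equal-length segments")
    template = np.median(segments, axis=0)
    lags = np.array(sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), -l)))
    # roll(seg, l) . template == seg . roll(template, -l)
    rolled = np.stack([np.roll(template, -l) for l in lags])
    scores = segments @ rolled.T          # (M, n_lags), tie-priority order
    best = np.argmax(scores, axis=1)      # first max = smallest |lag|
    chosen = lags[best]
    aligned = np.stack([np.roll(seg, l) for seg, l in zip(segments, chosen)])
    return aligned, chosen


def preprocess_recording(rec: PotentialRecording,
                         cfg: PreprocessConfig | None = None,
                         annotation: BeatAnnotation | None = None,
                         apply_lowpass: bool = True
                         ) -> tuple[PotentialRecording, BeatAnnotation]:
    """Full conditioning chain over all nodes.

    Beats are detected on the raw signal (the detector is amplitude
    adaptive), spline knots are placed ``knot_lead_ms`` before each
    fiducial, then baseline removal and zero-phase low-pass filtering are
    applied.  Pass ``annotation`` to reuse known fiducials instead of
    detecting.  Returns the conditioned recording and the annotation.

    ``apply_lowpass=False`` stops after baseline removal: the 15 Hz
    alternans-band filter suppresses the sharp depolarization deflection,
    so peak-to-peak amplitude maps and clinical voltage classification
    must run on the unfiltered (baseline-removed) signals.
    """
    cfg = cfg or PreprocessConfig()
    fs = rec.fs
    lead = cfg_ms_to_samples(cfg.knot_lead_ms, fs)
    out = np.empty_like(rec.signals)
    fiducials: list[np.ndarray] = []
    windows: list[list[tuple[int, int]]] = []
    pre = int(0.30 * fs)
    post = int(0.55 * fs)
    for i in range(rec.node_count):
        sig = rec.signals[i]
        fids = (annotation.fiducials[i] if annotation is not None
                else detect_beats(sig, fs, cfg))
        knots = np.clip(np.asarray(fids, dtype=np.int64) - lead, 0, sig.size - 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[i] = remove_baseline(sig, fs, knots) if knots.size else sig
        fiducials.append(np.asarray(fids, dtype=np.int64))
        windows.append([
            (int(max(0, f - pre)), int(min(sig.size, f + post))) for f in fids
        ])
    if apply_lowpass:
        out = lowpass_filter(out, fs, cfg.lowpass_cutoff_hz, cfg.filter_order)
    clean = dataclasses.replace(rec, signals=out)
    return clean, BeatAnnotation(fiducials, windows)
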