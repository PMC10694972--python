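"""Multi-beat body-surface recordings: lead QC, beat detection, signal averaging.

The vest records ~5 min of 256-channel torso potentials at 2400 Hz with no
band-pass or notch filtering; all enhancement happens here by averaging
aligned beats, which suppresses incoherent noise by ~1/sqrt(N).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .errors import InsufficientBeatsError, InvalidParameterError, SignalError

__all__ = [
    "BeatRecording",
    "FiducialWindows",
    "AveragedBeat",
    "qc_leads",
    "detect_beats",
    "signal_average",
]

CLIP_MV = 10.0  # amplifier sensitivity range is +-10 mV


@dataclass
class BeatRecording:
    """Raw multi-beat torso potentials, channels x samples in mV."""

    signals: np.ndarray
    fs: float
    channel_table: pd.DataFrame  # columns: panel, row, col
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise SignalError("signals must be channels x samples")
        if self.fs <= 0:
            raise SignalError("fs must be positive")
        if len(self.channel_table) != self.signals.shape[0]:
            raise SignalError("channel_table rows must match channel count")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class FiducialWindows:
    """QRS and T-wave windows in ms from the averaged-beat start."""

    qrs_on: float
    qrs_off: float
    t_on: float
    t_off: float

    def __post_init__(self) -> None:
        if not (0 <= self.qrs_on < self.qrs_off < self.t_on < self.t_off):
            raise SignalError(
                "fiducial windows must satisfy 0 <= QRSon < QRSoff < Ton < Toff"
            )

    @property
    def qrs(self) -> tuple[float, float]:
        return (self.qrs_on, self.qrs_off)

    @property
    def t(self) -> tuple[float, float]:
        return (self.t_on, self.t_off)


@dataclass
class AveragedBeat:
    """Signal-averaged single beat per channel with fiducial windows."""

    waveforms: np.ndarray  # channels x samples, mV
    fs: float
    rr_mean: float  # ms
    n_beats_used: int
    windows: FiducialWindows
    lead_status: pd.DataFrame  # columns: included (bool), reason (str)

    def __post_init__(self) -> None:
        self.waveforms = np.asarray(self.waveforms, dtype=float)
        beat_ms = 1000.0 * self.waveforms.shape[1] / self.fs
        if self.windows.t_off > beat_ms + 1e-9:
            raise SignalError("fiducial windows exceed beat length")
        if self.n_beats_used < 1:
            raise SignalError("n_beats_used must be >= 1")

    @property
    def included(self) -> np.ndarray:
        return self.lead_status["included"].to_numpy()

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.waveforms.shape[1]) * 1000.0 / self.fs


# -- lead quality control ------------------------------------------------------


def qc_leads(
    rec: BeatRecording,
    flat_sd_mv: float = 1e-3,
    artifact_sd_mv: float = 3.0,
    clip_fraction: float = 0.01,
    clip_level_mv: float = CLIP_MV,
    max_excluded_fraction: float = 0.5,
) -> pd.DataFrame:
    """Exclude flat, artefact-laden or clipped channels.

    A channel is excluded when its SD is below ``flat_sd_mv`` (1 uV default:
    lost contact), above ``artifact_sd_mv``, or when more than
    ``clip_fraction`` of its samples sit at the +-10 mV rails. Idempotent:
    re-running on the surviving channels excludes nothing new.
    """
    sd = rec.signals.std(axis=1)
    clipped = (np.abs(rec.signals) >= clip_level_mv - 1e-9).mean(axis=1)
    included = np.ones(rec.n_channels, dtype=bool)
    reason = np.array([""] * rec.n_channels, dtype=object)
    for i in range(rec.n_channels):
        if sd[i] < flat_sd_mv:
            included[i], reason[i] = False, "flat"
        elif clipped[i] > clip_fraction:
            included[i], reason[i] = False, "clipping"
        elif sd[i] > artifact_sd_mv:
            included[i], reason[i] = False, "artifact"
    status = pd.DataFrame({"included": included, "reason": reason})
    if (~included).mean() > max_excluded_fraction:
        raise SignalError(
            f"{(~included).sum()} of {rec.n_channels} channels excluded "
            f"({status[~status.included].reason.value_counts().to_dict()}); "
            "recording unusable"
        )
    return status


# -- beat detection ------------------------------------------------------------


def _rms_trace(rec: BeatRecording, included: np.ndarray | None) -> np.ndarray:
    sig = rec.signals if included is None else rec.signals[included]
    sig = sig - np.median(sig, axis=1, keepdims=True)
    return np.sqrt((sig**2).mean(axis=0))


def detect_beats(
    rec: BeatRecording,
    lead_status: pd.DataFrame | None = None,
    refractory_ms: float = 250.0,
    smooth_ms: float = 60.0,
    min_beats: int = 5,
    min_duration_s: float = 10.0,
) -> np.ndarray:
    """Detect R-peak times (ms) from the cross-channel RMS energy envelope.

    Energy = moving average of the squared RMS trace; peaks must be separated
    by the refractory period and exceed 30% of the robust (98th percentile)
    envelope maximum.
    """
    if rec.duration_s < min_duration_s:
        raise SignalError(
            f"recording too short ({rec.duration_s:.1f} s < {min_duration_s} s)"
        )
    included = lead_status["included"].to_numpy() if lead_status is not None else None
    rms = _rms_trace(rec, included)
    if rms.max() < 1e-9:
        raise SignalError("flat recording: no signal energy")
    energy = rms**2
    w = max(1, int(round(smooth_ms * rec.fs / 1000.0)))
    kernel = np.ones(w) / w
    energy = np.convolve(energy, kernel, mode="same")
    height = 0.3 * np.percentile(energy, 98)
    distance = max(1, int(round(refractory_ms * rec.fs / 1000.0)))
    peaks, _ = find_peaks(energy, height=height, distance=distance)
    if len(peaks) < min_beats:
        raise InsufficientBeatsError(
            f"only {len(peaks)} beats detected (need >= {min_beats})"
        )
    return peaks * 1000.0 / rec.fs


# -- signal averaging ----------------------------------------------------------


def signal_average(
    rec: BeatRecording,
    beat_onsets_ms: Sequence[float],
    reject_fraction: float = 0.1,
    lead_status: pd.DataFrame | None = None,
    window_ms: tuple[float, float] = (-150.0, 600.0),
    align_search_ms: float = 50.0,
    qrs_threshold: float = 0.15,
    qrs_pad_ms: float = 8.0,
    t_gap_ms: float = 30.0,
    t_span_ms: float = 450.0,
) -> AveragedBeat:
    """Average beats aligned to the median-beat template.

    Beats are windowed about each detected R time, aligned by cross-correlating
    their RMS traces with the template (median beat) within
    ``+-align_search_ms``, the worst-correlated ``reject_fraction`` discarded,
    and the remainder averaged per channel. Fiducial QRS/T windows are then
    placed from the averaged beat (QRS from the high-frequency derivative
    energy, T as a configurable span after QRS offset).
    """
    onsets = np.asarray(beat_onsets_ms, dtype=float)
    if len(onsets) < 5:
        raise InsufficientBeatsError("need >= 5 beat onsets for averaging")
    if not 0 <= reject_fraction < 1:
        raise InvalidParameterError("reject_fraction must be in [0, 1)")
    if lead_status is None:
        lead_status = pd.DataFrame(
            {"included": np.ones(rec.n_channels, bool),
             "reason": [""] * rec.n_channels}
        )
    included = lead_status["included"].to_numpy()

    fs = rec.fs
    pre = int(round(-window_ms[0] * fs / 1000.0))
    post = int(round(window_ms[1] * fs / 1000.0))
    w = pre + post
    search = int(round(align_search_ms * fs / 1000.0))

    rms = _rms_trace(rec, included)
    centres = np.round(onsets * fs / 1000.0).astype(int)
    usable = [
        (c, t) for c, t in zip(centres, onsets)
        if c - pre - search >= 0 and c + post + search <= rec.n_samples
    ]
    if len(usable) < 5:
        raise InsufficientBeatsError("fewer than 5 beats fit inside the recording")
    centres = np.array([c for c, _ in usable])
    kept_onsets = np.array([t for _, t in usable])

    beat_rms = np.stack([rms[c - pre : c + post] for c in centres])
    template = np.median(beat_rms, axis=0)
    tz = template - template.mean()
    tnorm = np.linalg.norm(tz)

    shifts = np.zeros(len(centres), dtype=int)
    corr = np.zeros(len(centres))
    for i, c in enumerate(centres):
        best_r, best_s = -np.inf, 0
        for s in range(-search, search + 1):
            seg = rms[c - pre + s : c + post + s]
            sz = seg - seg.mean()
            denom = np.linalg.norm(sz) * tnorm
            r = float(sz @ tz) / denom if denom > 0 else 0.0
            if r > best_r:
                best_r, best_s = r, s
        shifts[i], corr[i] = best_s, best_r

    n_reject = int(np.ceil(reject_fraction * len(centres))) if reject_fraction else 0
    if n_reject >= len(centres):
        raise SignalError("all beats rejected")
    order = np.argsort(corr)  # ascending: worst first
    accepted = np.sort(order[n_reject:])

    acc = np.zeros((rec.n_channels, w))
    for i in accepted:
        c = centres[i] + shifts[i]
        acc += rec.signals[:, c - pre : c + post]
    waveforms = acc / len(accepted)

    # RR from all detected onsets (median is robust to missed/rejected beats,
    # which would otherwise inflate a mean of accepted-only gaps)
    rr = np.diff(np.sort(onsets))
    rr_mean = float(np.median(rr[rr > 0])) if np.any(rr > 0) else float("nan")

    windows = _fiducial_windows(
        waveforms[included], fs, qrs_threshold, qrs_pad_ms, t_gap_ms, t_span_ms
    )
    return AveragedBeat(
        waveforms=waveforms,
        fs=fs,
        rr_mean=rr_mean,
        n_beats_used=len(accepted),
        windows=windows,
        lead_status=lead_status.copy(),
    )


def _fiducial_windows(
    waveforms: np.ndarray,
    fs: float,
    qrs_threshold: float,
    qrs_pad_ms: float,
    t_gap_ms: float,
    t_span_ms: float,
) -> FiducialWindows:
    """Place QRS/T windows from the averaged beat.

    QRS is the contiguous region around the peak of the cross-channel RMS of
    the Savitzky-Golay derivative (high-frequency energy localises the QRS even
    when the slow T wave dominates raw amplitude), padded by ``qrs_pad_ms``.
    The T window is located the same way inside the search region opening
    ``t_gap_ms`` after QRS offset and spanning ``t_span_ms``: the contiguous
    region around the peak of a wide-frame derivative RMS, padded by 40 ms.
    Tying the T window to the measured T-wave energy (rather than a fixed span)
    keeps late-window baseline drift out of the repolarization search.
    """
    n = waveforms.shape[1]
    frame = max(5, int(round(5.0 * fs / 1000.0)) | 1)
    deriv = savgol_filter(waveforms, frame, polyorder=2, deriv=1, axis=1)
    hf = np.sqrt((deriv**2).mean(axis=0))
    peak = int(np.argmax(hf))
    thresh = qrs_threshold * hf[peak]
    lo = peak
    while lo > 0 and hf[lo - 1] > thresh:
        lo -= 1
    hi = peak
    while hi < n - 1 and hf[hi + 1] > thresh:
        hi += 1
    pad = qrs_pad_ms
    ms = 1000.0 / fs
    qrs_on = max(0.0, lo * ms - pad)
    qrs_off = hi * ms + pad
    search_lo = int(round((qrs_off + t_gap_ms) / ms))
    search_hi = min(n, int(round((qrs_off + t_gap_ms + t_span_ms) / ms)))
    if search_hi - search_lo < 5:
        raise SignalError("beat window too short for a T-wave window")
    t_frame = max(5, int(round(25.0 * fs / 1000.0)) | 1)
    t_deriv = savgol_filter(waveforms, t_frame, polyorder=2, deriv=1, axis=1)
    thf = np.sqrt((t_deriv**2).mean(axis=0))
    tpk = search_lo + int(np.argmax(thf[search_lo:search_hi]))
    t_thresh = qrs_threshold * thf[tpk]
    tlo = tpk
    while tlo > search_lo and thf[tlo - 1] > t_thresh:
        tlo -= 1
    thi = tpk
    while thi < search_hi - 1 and thf[thi + 1] > t_thresh:
        thi += 1
    t_pad = 40.0
    t_on = max(qrs_off + t_gap_ms, tlo * ms - t_pad)
    t_off = min((n - 1) * ms, thi * ms + t_pad)
    if t_off <= t_on:
        raise SignalError("beat window too short for a T-wave window")
    return FiducialWindows(qrs_on=qrs_on, qrs_off=qrs_off, t_on=t_on, t_off=t_off)
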