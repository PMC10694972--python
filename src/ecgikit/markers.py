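"""Per-node electrophysiological markers from unipolar electrograms.

Activation time (AT) is the instant of steepest QRS downslope (dV/dt min),
repolarization time (RT) the steepest T-wave upslope (dV/dt max), and the
activation-recovery interval ARI = RT - AT, a surrogate of local action
potential duration. Repolarization intervals are additionally reported with
Bazett rate correction (interval / sqrt(RR in s)); AT is never corrected.
Derivatives use a Savitzky-Golay filter (order 2) since raw finite differences
at 2400 Hz amplify reconstruction noise; the QRS uses a 5 ms frame (sharp
intrinsic deflection) and the T wave a 25 ms frame (the repolarization upslope
is an order of magnitude slower, and a short frame lets residual noise steal
the argmax).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .errors import InvalidParameterError, MarkerError
from .inverse import EpicardialSignalSet
from .sigproc import FiducialWindows

__all__ = [
    "NodeMarkers",
    "compute_at",
    "compute_rt",
    "compute_ari",
    "bazett_correct",
    "compute_amplitude",
    "compute_fractionation",
    "compute_markers",
    "qc_markers",
]

SG_FRAME_MS = 5.0
SG_FRAME_T_MS = 25.0
SG_ORDER = 2


@dataclass
class NodeMarkers:
    """Marker map: one row per heart node.

    ARI = RT - AT holds exactly at every included node; nodes failing QC or
    sitting on the valve plane carry ``excluded=True`` with a reason code.
    """

    at: np.ndarray  # ms
    rt: np.ndarray  # ms
    rt_c: np.ndarray  # ms, Bazett-corrected
    ari: np.ndarray  # ms
    ari_c: np.ndarray  # ms, Bazett-corrected
    amplitude: np.ndarray  # mV
    fractionation: np.ndarray  # count
    rr: float  # ms, beat RR used for correction
    excluded: np.ndarray  # bool
    reason: np.ndarray  # str

    def __post_init__(self) -> None:
        n = len(self.at)
        for name in ("rt", "rt_c", "ari", "ari_c", "amplitude",
                     "fractionation", "excluded", "reason"):
            if len(getattr(self, name)) != n:
                raise MarkerError(f"{name} length mismatch")
        inc = ~self.excluded
        if not np.allclose(self.ari[inc], self.rt[inc] - self.at[inc]):
            raise MarkerError("ARI identity violated on included nodes")
        if np.any(self.rt[inc] <= self.at[inc]):
            raise MarkerError("RT must exceed AT on included nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.at)

    @property
    def included(self) -> np.ndarray:
        return ~self.excluded

    def copy(self) -> "NodeMarkers":
        return NodeMarkers(
            self.at.copy(), self.rt.copy(), self.rt_c.copy(), self.ari.copy(),
            self.ari_c.copy(), self.amplitude.copy(), self.fractionation.copy(),
            self.rr, self.excluded.copy(), self.reason.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": np.arange(self.n_nodes),
                "at_ms": self.at,
                "rt_ms": self.rt,
                "rtc_ms": self.rt_c,
                "ari_ms": self.ari,
                "aric_ms": self.ari_c,
                "amp_mv": self.amplitude,
                "frac": self.fractionation,
                "excluded": self.excluded,
                "reason": self.reason,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rr: float) -> "NodeMarkers":
        return cls(
            at=df["at_ms"].to_numpy(float),
            rt=df["rt_ms"].to_numpy(float),
            rt_c=df["rtc_ms"].to_numpy(float),
            ari=df["ari_ms"].to_numpy(float),
            ari_c=df["aric_ms"].to_numpy(float),
            amplitude=df["amp_mv"].to_numpy(float),
            fractionation=df["frac"].to_numpy(int),
            rr=rr,
            excluded=df["excluded"].to_numpy(bool),
            reason=df["reason"].fillna("").to_numpy(object),
        )


# -- single-waveform primitives --------------------------------------------------


def _sg_derivative(wave: np.ndarray, fs: float,
                   frame_ms: float = SG_FRAME_MS) -> np.ndarray:
    frame = max(5, int(round(frame_ms * fs / 1000.0)) | 1)
    frame = min(frame, len(wave) - (1 - len(wave) % 2))
    return savgol_filter(wave, frame, SG_ORDER, deriv=1, axis=-1) * fs / 1000.0


def _window_slice(window_ms: tuple[float, float], fs: float, n: int) -> slice:
    lo = int(np.ceil(window_ms[0] * fs / 1000.0 - 1e-9))
    hi = int(np.floor(window_ms[1] * fs / 1000.0 + 1e-9)) + 1
    lo, hi = max(0, lo), min(n, hi)
    if hi - lo < 5:
        raise MarkerError("marker window shorter than 5 samples")
    return slice(lo, hi)


def compute_at(ueg: np.ndarray, qrs_window: tuple[float, float], fs: float) -> float:
    """Time (ms) of the steepest QRS downslope; ties break to the earliest."""
    ueg = np.asarray(ueg, float)
    sl = _window_slice(qrs_window, fs, len(ueg))
    d = _sg_derivative(ueg, fs)[sl]
    return (sl.start + int(np.argmin(d))) * 1000.0 / fs


def compute_rt(ueg: np.ndarray, t_window: tuple[float, float], fs: float) -> float:
    """Time (ms) of the steepest T-wave upslope; errors on a flat window."""
    ueg = np.asarray(ueg, float)
    sl = _window_slice(t_window, fs, len(ueg))
    seg = ueg[sl]
    if np.ptp(seg) < 1e-12:
        raise MarkerError("no deflection in the T-wave window")
    d = _sg_derivative(ueg, fs, frame_ms=SG_FRAME_T_MS)[sl]
    return (sl.start + int(np.argmax(d))) * 1000.0 / fs


def compute_ari(at: float, rt: float) -> float:
    """ARI = RT - AT (ms); RT must exceed AT."""
    if rt <= at:
        raise MarkerError(f"invalid interval: RT ({rt}) <= AT ({at})")
    return rt - at


def bazett_correct(interval_ms: float, rr_ms: float):
    """Bazett heart-rate correction: interval / sqrt(RR in seconds).

    Applied to repolarization intervals (RT, ARI) only, never to AT.
    """
    if np.any(np.asarray(rr_ms) <= 0):
        raise InvalidParameterError("RR must be positive")
    return interval_ms / np.sqrt(rr_ms / 1000.0)


def compute_amplitude(ueg: np.ndarray, qrs_window: tuple[float, float],
                      fs: float) -> float:
    """QRS peak-to-trough amplitude (mV) within the window."""
    sl = _window_slice(qrs_window, fs, len(ueg))
    return float(np.ptp(ueg[sl]))


def compute_fractionation(
    ueg: np.ndarray,
    qrs_window: tuple[float, float],
    fs: float,
    prominence: float | None = None,
    baseline_window: tuple[float, float] | None = None,
) -> int:
    """Count of negative QRS deflections (abnormal-conduction indicator).

    Local minima below the isoelectric baseline (median of the pre-QRS
    segment) with at least the given prominence (default 5% of the QRS
    peak-to-trough amplitude) are counted. The segment is smoothed with the
    marker Savitzky-Golay frame first and deflections narrower than 2 ms are
    ignored, so broadband reconstruction noise does not register as
    fractionation. A monophasic positive QRS yields 0.
    """
    ueg = np.asarray(ueg, float)
    sl = _window_slice(qrs_window, fs, len(ueg))
    frame = max(5, int(round(SG_FRAME_MS * fs / 1000.0)) | 1)
    seg = savgol_filter(ueg[sl], min(frame, len(ueg[sl]) - (1 - len(ueg[sl]) % 2)),
                        SG_ORDER)
    if prominence is None:
        prominence = 0.05 * np.ptp(seg)
    if prominence <= 0:
        raise InvalidParameterError("prominence must be > 0")
    if baseline_window is not None:
        bsl = _window_slice(baseline_window, fs, len(ueg))
        baseline = float(np.median(ueg[bsl]))
    else:
        baseline = float(np.median(ueg[: max(1, sl.start)])) if sl.start else float(
            np.median(seg[:3])
        )
    min_width = max(1, int(round(2.0 * fs / 1000.0)))
    troughs, _ = find_peaks(-seg, prominence=prominence, width=min_width)
    return int(np.sum(seg[troughs] < baseline))


# -- map-level extraction ---------------------------------------------------------


def compute_markers(
    phi_e: EpicardialSignalSet,
    windows: FiducialWindows,
    rr_ms: float,
    prominence: float | None = None,
) -> NodeMarkers:
    """Extract the full marker map from a reconstructed epicardial signal set."""
    n, fs = phi_e.n_nodes, phi_e.fs
    ueg = phi_e.ueg
    qsl = _window_slice(windows.qrs, fs, ueg.shape[1])
    tsl = _window_slice(windows.t, fs, ueg.shape[1])
    d_qrs = savgol_filter(
        ueg, max(5, int(round(SG_FRAME_MS * fs / 1000.0)) | 1),
        SG_ORDER, deriv=1, axis=1,
    )
    d_t = savgol_filter(
        ueg, max(5, int(round(SG_FRAME_T_MS * fs / 1000.0)) | 1),
        SG_ORDER, deriv=1, axis=1,
    )
    at = (qsl.start + np.argmin(d_qrs[:, qsl], axis=1)) * 1000.0 / fs
    rt = (tsl.start + np.argmax(d_t[:, tsl], axis=1)) * 1000.0 / fs
    amplitude = np.ptp(ueg[:, qsl], axis=1)
    frac = np.empty(n, dtype=int)
    for i in range(n):
        frac[i] = compute_fractionation(
            ueg[i], windows.qrs, fs, prominence=prominence
        )
    excluded = np.zeros(n, dtype=bool)
    reason = np.array([""] * n, dtype=object)
    bad = rt <= at
    excluded[bad] = True
    reason[bad] = "ari_nonpositive"
    ari = np.where(bad, np.nan, rt - at)
    rt_c = bazett_correct(rt, rr_ms)
    ari_c = np.where(bad, np.nan, bazett_correct(np.where(bad, 1.0, ari), rr_ms))
    return NodeMarkers(
        at=at, rt=rt, rt_c=rt_c, ari=ari, ari_c=ari_c,
        amplitude=amplitude, fractionation=frac, rr=rr_ms,
        excluded=excluded, reason=reason,
    )


def qc_markers(
    markers: NodeMarkers,
    windows: FiducialWindows,
    amplitude_floor_mv: float = 0.05,
    warn_fraction: float = 0.3,
) -> NodeMarkers:
    """Rule-based marker quality control.

    Nodes are excluded when AT falls outside the QRS window, RT outside the
    T window, ARI is non-positive, or the QRS amplitude is below the floor.
    A warning is raised if more than ``warn_fraction`` of nodes get excluded.
    """
    import warnings

    out = markers.copy()
    checks = [
        ((out.at < windows.qrs_on) | (out.at > windows.qrs_off), "at_outside_qrs"),
        ((out.rt < windows.t_on) | (out.rt > windows.t_off), "rt_outside_t"),
        (~(out.rt - out.at > 0), "ari_nonpositive"),
        (out.amplitude < amplitude_floor_mv, "low_amplitude"),
    ]
    for mask, code in checks:
        newly = mask & ~out.excluded
        out.excluded[newly] = True
        out.reason[newly] = code
    if out.excluded.mean() > warn_fraction:
        warnings.warn(
            f"{out.excluded.sum()} of {out.n_nodes} nodes excluded by marker QC",
            stacklevel=2,
        )
    return out
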