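"""Intra-/inter-observer and scan-re-scan reliability analyses.

Paired marker maps (matched closest cardiac sites) are compared with Pearson
waveform correlations, Spearman sequence correlations, a two-way random
effects ICC without interaction (absolute agreement, single measure), per-site
absolute differences in ms and %, and non-parametric Bland-Altman limits of
agreement (median bias, 5th/95th percentile limits, IQR-based confidence
intervals) — the non-parametric form is used because between-observer
differences are typically non-normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from scipy.signal import resample

from .errors import StatsError
from .geometry import PairedSites
from .inverse import EpicardialSignalSet
from .markers import NodeMarkers

__all__ = [
    "BlandAltmanSummary",
    "ReliabilityReport",
    "ueg_similarity",
    "sequence_correlation",
    "icc_two_way_random",
    "nonparametric_bland_altman",
    "absolute_differences",
    "scan_rescan_report",
    "reliability_report",
]

log = logging.getLogger(__name__)


def _quantile(x: np.ndarray, q) -> np.ndarray:
    # inclusive linear-interpolation quantile, fixed since dialects differ
    return np.percentile(np.asarray(x, float), q, method="linear")


@dataclass
class BlandAltmanSummary:
    """Non-parametric limits of agreement over per-case difference vectors."""

    per_case_bias: np.ndarray  # median difference per case
    per_case_lower: np.ndarray  # 5th percentile per case
    per_case_upper: np.ndarray  # 95th percentile per case
    bias: float  # median of per-case biases
    lower: float
    upper: float
    bias_ci: tuple[float, float]  # IQR of the per-case bias distribution
    lower_ci: tuple[float, float]
    upper_ci: tuple[float, float]

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("per_case_bias", "per_case_lower", "per_case_upper"):
            d[k] = list(map(float, d[k]))
        return d


@dataclass
class ReliabilityReport:
    """All reliability quantities for one paired-analysis experiment."""

    r_ueg: np.ndarray = field(default_factory=lambda: np.array([]))
    r_ueg_median: float = float("nan")
    r_ueg_iqr: tuple[float, float] = (float("nan"), float("nan"))
    rs_at: float = float("nan")
    rs_rt: float = float("nan")
    rs_ari: float = float("nan")
    icc_ueg: float = float("nan")
    icc_at: float = float("nan")
    icc_rt: float = float("nan")
    icc_ari: float = float("nan")
    delta_at_ms: dict = field(default_factory=dict)
    delta_rt_ms: dict = field(default_factory=dict)
    delta_ari_ms: dict = field(default_factory=dict)
    n_pairs: int = 0
    ba: BlandAltmanSummary | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["r_ueg"] = list(map(float, self.r_ueg))
        if self.ba is not None:
            d["ba"] = self.ba.to_dict()
        return d


# -- waveform similarity ----------------------------------------------------------


def ueg_similarity(
    set_a: EpicardialSignalSet,
    set_b: EpicardialSignalSet,
    pairs: PairedSites,
) -> np.ndarray:
    """Pearson correlation between the full paired waveforms, per site pair.

    Sets with different sample counts are resampled to the shorter; sites with
    a zero-variance waveform are skipped (NaN) and logged.
    """
    a, b = set_a.ueg, set_b.ueg
    if a.shape[1] != b.shape[1]:
        n = min(a.shape[1], b.shape[1])
        if a.shape[1] != n:
            a = resample(a, n, axis=1)
        if b.shape[1] != n:
            b = resample(b, n, axis=1)
    out = np.full(pairs.n_pairs, np.nan)
    for k, (i, j) in enumerate(pairs.pairs):
        wa, wb = a[i], b[j]
        if np.ptp(wa) < 1e-15 or np.ptp(wb) < 1e-15:
            log.info("ueg_similarity: zero-variance waveform at pair %d, skipped", k)
            continue
        out[k] = np.corrcoef(wa, wb)[0, 1]
    return out


def _paired_values(
    markers_a: NodeMarkers, markers_b: NodeMarkers, pairs: PairedSites, variable: str
) -> tuple[np.ndarray, np.ndarray]:
    attr = {"at": "at", "rt": "rt", "ari": "ari"}[variable]
    ia, ib = pairs.pairs[:, 0], pairs.pairs[:, 1]
    ok = markers_a.included[ia] & markers_b.included[ib]
    return getattr(markers_a, attr)[ia[ok]], getattr(markers_b, attr)[ib[ok]]


def sequence_correlation(
    markers_a: NodeMarkers,
    markers_b: NodeMarkers,
    pairs: PairedSites,
    variable: str,
) -> float:
    """Spearman correlation of a marker sequence over included paired sites."""
    a, b = _paired_values(markers_a, markers_b, pairs, variable)
    if len(a) < 10:
        raise StatsError(f"only {len(a)} included pairs (need >= 10)")
    if np.array_equal(a, b):
        return 1.0  # exact by definition; avoids rounding in the rank formula
    return float(stats.spearmanr(a, b).statistic)


# -- intraclass correlation --------------------------------------------------------


def icc_two_way_random(pairs_matrix: np.ndarray) -> float:
    """ICC, two-way random effects without interaction, absolute agreement,
    single measure (ICC(2,1)):

        (MS_rows - MS_err) / (MS_rows + (k-1) MS_err + (k/n)(MS_cols - MS_err))

    from the two-way ANOVA of an n-sites x k-raters table.
    """
    m = np.asarray(pairs_matrix, float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise StatsError("need an n x k matrix with k >= 2")
    n, k = m.shape
    if n < 5:
        raise StatsError("need >= 5 rows")
    grand = m.mean()
    row_m = m.mean(axis=1)
    col_m = m.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_err = np.sum((m - row_m[:, None] - col_m[None, :] + grand) ** 2)
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
    if abs(denom) < 1e-300:
        raise StatsError("zero total variance: ICC undefined")
    return float((ms_rows - ms_err) / denom)


# -- Bland-Altman -----------------------------------------------------------------


def nonparametric_bland_altman(
    diffs_per_case: list[np.ndarray], min_sites: int = 20
) -> BlandAltmanSummary:
    """Non-parametric limits of agreement.

    Per case: bias = median difference, limits = 5th/95th percentiles.
    Global: medians of the per-case distributions, with confidence intervals
    given by the interquartile range of each distribution. Cases with fewer
    than ``min_sites`` sites are skipped with a log entry.
    """
    biases, lowers, uppers = [], [], []
    for i, d in enumerate(diffs_per_case):
        d = np.asarray(d, float)
        d = d[np.isfinite(d)]
        if d.size < min_sites:
            log.info("bland-altman: case %d has %d sites (<%d), skipped",
                     i, d.size, min_sites)
            continue
        biases.append(float(np.median(d)))
        lo, hi = _quantile(d, [5, 95])
        lowers.append(float(lo))
        uppers.append(float(hi))
    if not biases:
        raise StatsError("no usable cases for Bland-Altman")
    biases = np.asarray(biases)
    lowers = np.asarray(lowers)
    uppers = np.asarray(uppers)

    def iqr(x):
        lo, hi = _quantile(x, [25, 75])
        return (float(lo), float(hi))

    return BlandAltmanSummary(
        per_case_bias=biases,
        per_case_lower=lowers,
        per_case_upper=uppers,
        bias=float(np.median(biases)),
        lower=float(np.median(lowers)),
        upper=float(np.median(uppers)),
        bias_ci=iqr(biases),
        lower_ci=iqr(lowers),
        upper_ci=iqr(uppers),
    )


def absolute_differences(
    markers_a: NodeMarkers,
    markers_b: NodeMarkers,
    pairs: PairedSites,
    variable: str,
) -> dict:
    """Per-site |a - b| in ms and in % of the pairwise mean, with pooled
    median (IQR). Sites whose pairwise mean is zero are skipped for % only."""
    a, b = _paired_values(markers_a, markers_b, pairs, variable)
    if len(a) < 1:
        raise StatsError("no included pairs")
    d_ms = np.abs(a - b)
    mean_ab = 0.5 * (a + b)
    ok = mean_ab != 0
    d_pc = 100.0 * d_ms[ok] / np.abs(mean_ab[ok])
    q = lambda x: (float(np.median(x)),
                   tuple(map(float, _quantile(x, [25, 75])))) if x.size else (
        float("nan"), (float("nan"), float("nan")))
    med_ms, iqr_ms = q(d_ms)
    med_pc, iqr_pc = q(d_pc)
    return {
        "delta_ms": d_ms,
        "delta_pc": d_pc,
        "median_ms": med_ms,
        "iqr_ms": iqr_ms,
        "median_pc": med_pc,
        "iqr_pc": iqr_pc,
    }


# -- composite reports ------------------------------------------------------------


def reliability_report(
    ueg_a: EpicardialSignalSet,
    ueg_b: EpicardialSignalSet,
    markers_a: NodeMarkers,
    markers_b: NodeMarkers,
    pairs: PairedSites,
) -> ReliabilityReport:
    """Full paired-run reliability report (intra-/inter-observer design)."""
    r = ueg_similarity(ueg_a, ueg_b, pairs)
    r_ok = r[np.isfinite(r)]
    rep = ReliabilityReport(n_pairs=pairs.n_pairs)
    rep.r_ueg = r
    if r_ok.size:
        rep.r_ueg_median = float(np.median(r_ok))
        rep.r_ueg_iqr = tuple(map(float, _quantile(r_ok, [25, 75])))
    for var, rs_name, icc_name, delta_name in (
        ("at", "rs_at", "icc_at", "delta_at_ms"),
        ("rt", "rs_rt", "icc_rt", "delta_rt_ms"),
        ("ari", "rs_ari", "icc_ari", "delta_ari_ms"),
    ):
        a, b = _paired_values(markers_a, markers_b, pairs, var)
        setattr(rep, rs_name, sequence_correlation(markers_a, markers_b, pairs, var))
        setattr(rep, icc_name, icc_two_way_random(np.c_[a, b]))
        d = absolute_differences(markers_a, markers_b, pairs, var)
        setattr(rep, delta_name, {
            "median_ms": d["median_ms"], "iqr_ms": d["iqr_ms"],
            "median_pc": d["median_pc"], "iqr_pc": d["iqr_pc"],
        })
    # waveform-agreement ICC across sites: per-site mean amplitude agreement
    ia, ib = pairs.pairs[:, 0], pairs.pairs[:, 1]
    wa = ueg_a.ueg[ia]
    wb = ueg_b.ueg[ib]
    amp = np.c_[np.ptp(wa, axis=1), np.ptp(wb, axis=1)]
    try:
        rep.icc_ueg = icc_two_way_random(amp)
    except StatsError:
        rep.icc_ueg = float("nan")
    at_a, at_b = _paired_values(markers_a, markers_b, pairs, "at")
    rep.ba = nonparametric_bland_altman([at_a - at_b])
    return rep


def scan_rescan_report(summaries_1: list, summaries_2: list) -> dict:
    """Scan-re-scan reliability on per-participant global means only.

    Per-site comparison is deliberately not performed for this design: the two
    visits' cardiac meshes are in different scanner coordinates and are not
    registered. Requires >= 3 paired participants.
    """
    if len(summaries_1) != len(summaries_2):
        raise StatsError("visit lists must be paired (same length and order)")
    if len(summaries_1) < 3:
        raise StatsError("need >= 3 paired participants")
    out = {}
    for var in ("mean_at", "mean_rtc", "mean_aric"):
        x = np.array([getattr(s, var) for s in summaries_1], float)
        y = np.array([getattr(s, var) for s in summaries_2], float)
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            rs = 1.0 if np.allclose(x, y) else float("nan")
        else:
            rs = float(stats.spearmanr(x, y).statistic)
        try:
            icc = icc_two_way_random(np.c_[x, y])
        except StatsError:
            icc = float("nan") if not np.allclose(x, y) else 1.0
        out[var] = {"rs": rs, "icc": icc, "n": len(x)}
    return out
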