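"""Per-participant spatial summaries and group/ECG statistics.

Global dispersion of a marker (AT_d, RT_d, ARI_d) is its max minus min over
included nodes; the local gradient (G_AT, G_RT, G_ARI) is, per node, the mean
absolute marker difference to its mesh neighbours divided by the inter-node
distance, averaged over included nodes (ms/mm). Group comparisons follow a
Shapiro-Wilk gate: Welch's t-test for normal data, Mann-Whitney U otherwise,
chi-square for categorical variables; ECG-to-map correlations are Spearman.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StatsError
from .geometry import SurfaceMesh, node_neighbours
from .markers import NodeMarkers

__all__ = [
    "ParticipantSummary",
    "TwelveLeadParams",
    "local_gradient",
    "global_dispersion",
    "summarize_participant",
    "compare_groups",
    "correlate_ecg",
]


@dataclass
class ParticipantSummary:
    """Global means, dispersions and gradients for one participant."""

    mean_at: float
    mean_rtc: float
    mean_aric: float
    at_d: float  # ms
    rt_d: float  # ms
    ari_d: float  # ms
    g_at: float  # ms/mm
    g_rt: float  # ms/mm
    g_ari: float  # ms/mm
    mean_amp: float  # mV
    mean_frac: float
    rr: float  # ms
    n_nodes_included: int
    group_label: str = ""

    def __post_init__(self) -> None:
        if self.n_nodes_included <= 0:
            raise StatsError("n_nodes_included must be > 0")
        for name in ("at_d", "rt_d", "ari_d", "g_at", "g_rt", "g_ari"):
            if getattr(self, name) < 0:
                raise StatsError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TwelveLeadParams:
    """Conventional 12-lead ECG intervals for one participant (ms)."""

    rr: float
    pr: float
    qrs: float
    qtc: float

    def __post_init__(self) -> None:
        for name in ("rr", "pr", "qrs", "qtc"):
            if getattr(self, name) <= 0:
                raise StatsError(f"{name} must be positive")
        if self.qrs >= self.qtc:
            raise StatsError("QRS duration must be below QTc")


def local_gradient(
    values: np.ndarray,
    mesh: SurfaceMesh,
    excluded: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Mean neighbour gradient per node (ms/mm) and the participant mean.

    Per included node i: mean over included 1-ring neighbours j of
    |v_i - v_j| / ||x_i - x_j||. Excluded nodes contribute neither as centres
    nor as neighbours; nodes with no included neighbour are dropped from the
    participant mean (returned as NaN).
    """
    values = np.asarray(values, float)
    n = mesh.n_vertices
    if len(values) != n:
        raise StatsError("values length must match mesh vertex count")
    if excluded is None:
        excluded = np.zeros(n, dtype=bool)
    adj = node_neighbours(mesh).tocoo()
    grad = np.full(n, np.nan)
    num = np.zeros(n)
    cnt = np.zeros(n, dtype=int)
    ok = ~excluded[adj.row] & ~excluded[adj.col]
    rows, cols, d = adj.row[ok], adj.col[ok], adj.data[ok]
    np.add.at(num, rows, np.abs(values[rows] - values[cols]) / d)
    np.add.at(cnt, rows, 1)
    has = cnt > 0
    grad[has] = num[has] / cnt[has]
    grad[excluded] = np.nan
    usable = grad[~np.isnan(grad)]
    if usable.size == 0:
        raise StatsError("no node has an included neighbour")
    return grad, float(usable.mean())


def global_dispersion(values: np.ndarray, excluded: np.ndarray | None = None) -> float:
    """Max minus min of a marker over included nodes (ms)."""
    values = np.asarray(values, float)
    if excluded is not None:
        values = values[~np.asarray(excluded, bool)]
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise StatsError("dispersion needs >= 2 included nodes")
    return float(values.max() - values.min())


def summarize_participant(
    markers: NodeMarkers, mesh: SurfaceMesh, group_label: str = ""
) -> ParticipantSummary:
    """Aggregate a QC'd, valve-excluded marker map into one summary row.

    Repolarization summaries use the Bazett-corrected RT/ARI; AT stays raw.
    """
    inc = markers.included
    if inc.sum() == 0:
        raise StatsError("no included nodes")
    exc = markers.excluded
    _, g_at = local_gradient(markers.at, mesh, exc)
    _, g_rt = local_gradient(markers.rt_c, mesh, exc)
    _, g_ari = local_gradient(markers.ari_c, mesh, exc)
    return ParticipantSummary(
        mean_at=float(markers.at[inc].mean()),
        mean_rtc=float(markers.rt_c[inc].mean()),
        mean_aric=float(markers.ari_c[inc].mean()),
        at_d=global_dispersion(markers.at, exc),
        rt_d=global_dispersion(markers.rt_c, exc),
        ari_d=global_dispersion(markers.ari_c, exc),
        g_at=g_at,
        g_rt=g_rt,
        g_ari=g_ari,
        mean_amp=float(markers.amplitude[inc].mean()),
        mean_frac=float(markers.fractionation[inc].mean()),
        rr=markers.rr,
        n_nodes_included=int(inc.sum()),
        group_label=group_label,
    )


def _to_frame(summaries: list) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(s.to_dict() if isinstance(s, ParticipantSummary) else dict(s))
    return pd.DataFrame(rows)


def compare_groups(
    summaries_a: list,
    summaries_b: list,
    variables: list[str],
    categorical: set[str] | frozenset[str] = frozenset(),
    alpha_normality: float = 0.05,
) -> pd.DataFrame:
    """Per-variable two-group comparison with a Shapiro-Wilk gate.

    Continuous variables: Shapiro-Wilk on the pooled within-group residuals at
    alpha selects Welch's t-test (normal) vs Mann-Whitney U; categorical
    variables (value counts) use the chi-square test without continuity
    correction. Zero-variance variables are reported untested.
    """
    fa, fb = _to_frame(summaries_a), _to_frame(summaries_b)
    rows = []
    for var in variables:
        a = fa[var].dropna().to_numpy(float)
        b = fb[var].dropna().to_numpy(float)
        if var in categorical:
            table = _contingency(a, b)
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            rows.append(
                dict(variable=var, test="chi-square", statistic=chi2, p=p,
                     direction="", summary_a=_cat_summary(a), summary_b=_cat_summary(b))
            )
            continue
        if len(a) < 3 or len(b) < 3:
            raise StatsError(f"{var}: need >= 3 per group")
        if np.ptp(np.concatenate([a, b])) == 0:
            rows.append(
                dict(variable=var, test="untested (zero variance)",
                     statistic=np.nan, p=np.nan, direction="",
                     summary_a=_loc_summary(a, True), summary_b=_loc_summary(b, True))
            )
            continue
        resid = np.concatenate([a - a.mean(), b - b.mean()])
        if np.ptp(resid) == 0:
            normal = True
        else:
            normal = stats.shapiro(resid).pvalue >= alpha_normality
        if normal:
            res = stats.ttest_ind(a, b, equal_var=False)
            test = "welch-t"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "mann-whitney"
        direction = "a>b" if np.median(a) > np.median(b) else (
            "a<b" if np.median(a) < np.median(b) else "a=b")
        rows.append(
            dict(variable=var, test=test, statistic=float(res.statistic),
                 p=float(res.pvalue), direction=direction,
                 summary_a=_loc_summary(a, normal), summary_b=_loc_summary(b, normal))
        )
    return pd.DataFrame(rows)


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    levels = np.unique(np.concatenate([a, b]))
    if len(levels) < 2:
        raise StatsError("categorical variable has a single level")
    return np.array(
        [[(a == v).sum() for v in levels], [(b == v).sum() for v in levels]]
    )


def _cat_summary(x: np.ndarray) -> str:
    vals, counts = np.unique(x, return_counts=True)
    return "; ".join(f"{v:g}: {c} [{100*c/len(x):.0f}%]" for v, c in zip(vals, counts))


def _loc_summary(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{x.mean():.3g} +- {x.std(ddof=1):.3g}"
    q1, q3 = np.percentile(x, [25, 75])
    return f"{np.median(x):.3g} ({q1:.3g}-{q3:.3g})"


def correlate_ecg(
    summaries: list,
    ecg: list[TwelveLeadParams],
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Spearman correlation between 12-lead ECG intervals and map summaries.

    ``pairs`` holds (ecg_variable, summary_variable) names. Missing data are
    excluded pairwise; a pair with all-tied values is reported as undefined.
    """
    fs = _to_frame(summaries)
    fe = pd.DataFrame([asdict(e) for e in ecg])
    if len(fs) != len(fe):
        raise StatsError("summaries and ecg lists must be participant-aligned")
    rows = []
    for ecg_var, map_var in pairs:
        x = fe[ecg_var].to_numpy(float)
        y = fs[map_var].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 5:
            raise StatsError(f"({ecg_var}, {map_var}): fewer than 5 complete cases")
        if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            rows.append(dict(ecg=ecg_var, map=map_var, rs=np.nan, p=np.nan,
                             n=int(ok.sum()), note="undefined: all tied"))
            continue
        r = stats.spearmanr(x[ok], y[ok])
        rows.append(dict(ecg=ecg_var, map=map_var, rs=float(r.statistic),
                         p=float(r.pvalue), n=int(ok.sum()), note=""))
    return pd.DataFrame(rows)
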