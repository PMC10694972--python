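"""Helpers for judging reconstructed marker maps against known ground truth.

Reconstructed AT/RT are reported relative to the averaged-beat window start,
whereas ground-truth times are relative to beat onset; the two axes differ by
one global constant per run. Comparisons therefore remove the median offset
before computing errors (ARI is offset-free by construction).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["compare_marker_sequence"]


def compare_marker_sequence(
    true_values: np.ndarray,
    estimated: np.ndarray,
    excluded: np.ndarray | None = None,
    remove_offset: bool = True,
) -> dict:
    """Spearman correlation and offset-corrected absolute errors.

    Returns a dict with ``spearman``, ``offset_ms`` (the removed global median
    offset), ``median_abs_error_ms`` and ``n``.
    """
    t = np.asarray(true_values, float)
    e = np.asarray(estimated, float)
    ok = np.isfinite(t) & np.isfinite(e)
    if excluded is not None:
        ok &= ~np.asarray(excluded, bool)
    t, e = t[ok], e[ok]
    if t.size < 3:
        raise ValueError("need >= 3 comparable nodes")
    offset = float(np.median(e - t)) if remove_offset else 0.0
    err = np.abs(e - t - offset)
    return {
        "spearman": float(stats.spearmanr(t, e).statistic),
        "offset_ms": offset,
        "median_abs_error_ms": float(np.median(err)),
        "n": int(t.size),
    }
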