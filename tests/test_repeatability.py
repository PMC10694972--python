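import numpy as np
import pandas as pd
import pytest

from ecgikit.errors import StatsError
from ecgikit.geometry import PairedSites
from ecgikit.inverse import EpicardialSignalSet
from ecgikit.repeatability import (
    _quantile,
    absolute_differences,
    icc_two_way_random,
    nonparametric_bland_altman,
    reliability_report,
    scan_rescan_report,
    sequence_correlation,
    ueg_similarity,
)


def _markers(at, rr=900.0, included=None):
    from ecgikit.markers import NodeMarkers

    at = np.asarray(at, float)
    n = len(at)
    rt = at + 250.0
    excluded = np.zeros(n, bool) if included is None else ~np.asarray(included)
    return NodeMarkers(
        at=at, rt=rt, rt_c=rt / np.sqrt(rr / 1000.0), ari=rt - at,
        ari_c=(rt - at) / np.sqrt(rr / 1000.0), amplitude=np.ones(n),
        fractionation=np.zeros(n, int), rr=rr, excluded=excluded,
        reason=np.array([""] * n, object),
    )


def _identity_pairs(n):
    return PairedSites(pairs=np.stack([np.arange(n)] * 2, axis=1),
                       pair_distance=np.zeros(n))


class TestIcc:
    def test_matches_pingouin_on_random_tables(self):
        import pingouin as pg

        rng = np.random.default_rng(0)
        for _ in range(25):
            n, k = int(rng.integers(6, 16)), int(rng.integers(2, 5))
            x = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            mine = icc_two_way_random(x)
            df = pd.DataFrame(
                {"targets": np.repeat(np.arange(n), k),
                 "raters": np.tile(np.arange(k), n),
                 "ratings": x.ravel()}
            )
            tbl = pg.intraclass_corr(df, targets="targets", raters="raters",
                                     ratings="ratings")
            ref = float(tbl.loc[tbl["Type"] == "ICC(A,1)", "ICC"].iloc[0])
            assert abs(mine - ref) < 1e-8

    def test_perfect_agreement_is_one(self):
        x = np.arange(10.0)
        assert np.isclose(icc_two_way_random(np.c_[x, x]), 1.0)

    def test_needs_five_rows_and_two_cols(self):
        with pytest.raises(StatsError):
            icc_two_way_random(np.zeros((3, 2)))
        with pytest.raises(StatsError):
            icc_two_way_random(np.zeros((8, 1)))

    def test_zero_variance_undefined(self):
        with pytest.raises(StatsError):
            icc_two_way_random(np.full((8, 2), 3.0))


class TestBlandAltman:
    def test_standard_normal_limits(self):
        rng = np.random.default_rng(4)
        d = rng.standard_normal(10_000)
        ba = nonparametric_bland_altman([d])
        assert abs(ba.bias) < 0.05
        assert abs(ba.lower - (-1.645)) < 0.05
        assert abs(ba.upper - 1.645) < 0.05

    def test_quantiles_match_numpy_linear(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=321)
        assert np.allclose(
            _quantile(x, [5, 25, 50, 75, 95]),
            np.percentile(x, [5, 25, 50, 75, 95], method="linear"),
        )

    def test_global_values_are_medians_of_cases(self):
        cases = [np.linspace(-1, 1, 50) + off for off in (-0.2, 0.0, 0.4)]
        ba = nonparametric_bland_altman(cases)
        assert np.isclose(ba.bias, np.median([np.median(c) for c in cases]))
        assert np.isclose(ba.lower,
                          np.median([np.percentile(c, 5) for c in cases]))

    def test_small_cases_skipped_and_empty_raises(self):
        with pytest.raises(StatsError):
            nonparametric_bland_altman([np.arange(5.0)])


class TestSequenceAndDifferences:
    def test_sequence_correlation_perfect_monotone(self):
        a = _markers(np.arange(30.0))
        b = _markers(np.arange(30.0) * 2 + 7)
        assert sequence_correlation(a, b, _identity_pairs(30), "at") == 1.0

    def test_only_included_pairs_used(self):
        at = np.arange(30.0)
        inc = np.ones(30, bool)
        inc[::3] = False
        a = _markers(at, included=inc)
        b = _markers(at[::-1])
        rs = sequence_correlation(a, b, _identity_pairs(30), "at")
        assert np.isclose(rs, -1.0)

    def test_too_few_pairs_rejected(self):
        a = _markers(np.arange(5.0))
        with pytest.raises(StatsError):
            sequence_correlation(a, a, _identity_pairs(5), "at")

    def test_absolute_differences_hand_values(self):
        a = _markers(np.array([100.0, 200.0, 300.0] * 10))
        b = _markers(np.array([90.0, 220.0, 300.0] * 10))
        d = absolute_differences(a, b, _identity_pairs(30), "at")
        assert np.allclose(np.unique(d["delta_ms"]), [0.0, 10.0, 20.0])
        assert np.isclose(d["median_ms"], 10.0)
        # percent of pairwise mean: 10/95, 20/210, 0
        assert np.isclose(np.max(d["delta_pc"]), 100 * 10 / 95)


class TestUegSimilarity:
    def test_identical_sets_give_unit_correlation(self):
        rng = np.random.default_rng(6)
        ueg = rng.normal(size=(12, 200))
        s = EpicardialSignalSet(ueg=ueg, fs=1000.0, lambda_used=0.1,
                                provenance="t")
        r = ueg_similarity(s, s, _identity_pairs(12))
        assert np.allclose(r, 1.0)

    def test_zero_variance_waveform_nan(self):
        ueg = np.random.default_rng(7).normal(size=(4, 100))
        ueg[2] = 5.0
        s = EpicardialSignalSet(ueg=ueg, fs=1000.0, lambda_used=0.1,
                                provenance="t")
        r = ueg_similarity(s, s, _identity_pairs(4))
        assert np.isnan(r[2]) and np.isfinite(r[[0, 1, 3]]).all()

    def test_resamples_different_lengths(self):
        rng = np.random.default_rng(8)
        base = np.sin(np.linspace(0, 8 * np.pi, 400))[None, :] * np.ones((3, 1))
        a = EpicardialSignalSet(ueg=base, fs=1000.0, lambda_used=0.1,
                                provenance="t")
        b = EpicardialSignalSet(ueg=base[:, ::2], fs=500.0, lambda_used=0.1,
                                provenance="t")
        r = ueg_similarity(a, b, _identity_pairs(3))
        assert np.all(r > 0.99)


class TestReports:
    def test_degenerate_intra_observer_case(self, processed):
        m = processed["markers"]
        phi = processed["phi"]
        n = m.n_nodes
        rep = reliability_report(phi, phi, m, m, _identity_pairs(n))
        assert rep.r_ueg_median == 1.0
        assert rep.rs_at == 1.0 and rep.rs_rt == 1.0 and rep.rs_ari == 1.0
        assert np.isclose(rep.icc_at, 1.0)
        assert rep.delta_at_ms["median_ms"] == 0.0
        assert rep.ba.bias == 0.0 and rep.ba.lower == 0.0 and rep.ba.upper == 0.0

    def test_scan_rescan_requires_three_pairs(self):
        from ecgikit.epstats import ParticipantSummary

        s = ParticipantSummary(
            mean_at=80.0, mean_rtc=300.0, mean_aric=220.0, at_d=60.0,
            rt_d=70.0, ari_d=80.0, g_at=0.6, g_rt=0.9, g_ari=1.0,
            mean_amp=1.2, mean_frac=1.0, rr=900.0, n_nodes_included=100,
        )
        with pytest.raises(StatsError):
            scan_rescan_report([s, s], [s, s])

    def test_scan_rescan_identical_visits(self):
        from ecgikit.epstats import ParticipantSummary

        rng = np.random.default_rng(9)
        subs = [
            ParticipantSummary(
                mean_at=float(80 + rng.normal()), mean_rtc=float(300 + rng.normal()),
                mean_aric=float(220 + rng.normal()), at_d=60.0, rt_d=70.0,
                ari_d=80.0, g_at=0.6, g_rt=0.9, g_ari=1.0, mean_amp=1.2,
                mean_frac=1.0, rr=900.0, n_nodes_included=100,
            )
            for _ in range(6)
        ]
        rep = scan_rescan_report(subs, subs)
        for var in ("mean_at", "mean_rtc", "mean_aric"):
            assert rep[var]["rs"] == 1.0
            assert np.isclose(rep[var]["icc"], 1.0)
            assert rep[var]["n"] == 6
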