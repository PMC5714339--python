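"""Protection ratios, footprint definition rules and the heterogeneity test."""

import numpy as np
import pytest
from scipy import stats

from footcall.io import Footprint, FootprintSet, PeakRecord
from footcall.peakmap import ResidueProfile
from footcall.pipeline import analyze_peaks
from footcall.protection import (
    BOTH_OBSERVED,
    FOXO_MISSING,
    CallerParams,
    call_protected_residues,
    cluster_footprints,
    heterogeneity_test,
    protection_ratio,
    reconcile_strands,
)


def _profile(values, condition, concentration=600, strand="forward"):
    arr = np.array(values, dtype=float)
    n = np.where(np.isnan(arr), 0, 5).astype(int)
    return ResidueProfile("sub1", strand, condition, concentration,
                          len(arr), arr, n)


def _ratio_track(ratios, concentration, strand="forward"):
    arr = np.array(ratios, dtype=float)
    bsa = _profile(arr, "BSA", concentration, strand)
    foxo = _profile(np.ones_like(arr), "FOXO", concentration, strand)
    return protection_ratio(bsa, foxo)


class TestRatio:
    def test_plain_ratio(self):
        track = protection_ratio(_profile([4.0], "BSA"), _profile([2.0], "FOXO"))
        assert track.value_at(1) == 2.0
        assert track.support[0] == BOTH_OBSERVED

    def test_ratio_one_means_no_protection(self):
        track = protection_ratio(_profile([1.5], "BSA"), _profile([1.5], "FOXO"))
        assert track.value_at(1) == 1.0

    def test_missing_foxo_uses_epsilon_floor(self):
        # FOXO median height 2.0, epsilon_fraction 5% -> epsilon 0.1
        bsa = _profile([3.0, 2.0, 2.0, 2.0], "BSA")
        foxo = _profile([np.nan, 2.0, 2.0, 2.0], "FOXO")
        track = protection_ratio(bsa, foxo, CallerParams(epsilon_fraction=0.05))
        assert track.value_at(1) == pytest.approx(30.0)
        assert track.support[0] == FOXO_MISSING

    def test_missing_foxo_ratio_capped(self):
        bsa = _profile([500.0, 2.0, 2.0], "BSA")
        foxo = _profile([np.nan, 2.0, 2.0], "FOXO")
        track = protection_ratio(bsa, foxo)
        assert track.value_at(1) == 50.0

    def test_mismatched_profiles_rejected(self):
        with pytest.raises(ValueError):
            protection_ratio(_profile([1.0], "BSA", 600),
                             _profile([1.0], "FOXO", 1200))


class TestProtectedCall:
    @pytest.mark.parametrize("r600, r1200, expected", [
        (2.0, 1.3, True),    # boundary: >= is inclusive
        (1.9, 1.9, False),
        (1.0, 2.4, True),    # either-concentration rule
    ])
    def test_either_concentration_threshold(self, r600, r1200, expected):
        track = call_protected_residues(_ratio_track([r600], 600),
                                        _ratio_track([r1200], 1200))
        assert bool(track.protected[0]) is expected

    def test_unobserved_never_protected(self):
        t600 = _ratio_track([np.nan], 600)
        t1200 = _ratio_track([np.nan], 1200)
        track = call_protected_residues(t600, t1200)
        assert not track.protected[0]


class TestClustering:
    def test_nine_bp_run_is_one_footprint(self):
        # nine consecutive protected residues = the minimum footprint length
        intervals = cluster_footprints(range(100, 109))
        assert [(iv.start, iv.end) for iv in intervals] == [(100, 108)]

    def test_isolated_positions_discarded(self):
        assert cluster_footprints([10, 20]) == []

    def test_gap_rule_enumerated_by_hand(self):
        positions = [50, 51, 52, 58, 59, 60]  # gap of 5 unprotected residues
        # default min length 9: both 3 bp clusters discarded
        assert cluster_footprints(positions, CallerParams()) == []
        short_ok = CallerParams(min_footprint_length=3)
        intervals = cluster_footprints(positions, short_ok)
        assert [(iv.start, iv.end) for iv in intervals] == [(50, 52), (58, 60)]
        # gap of 4 or less joins one cluster
        joined = cluster_footprints([50, 51, 52, 57, 58, 59], CallerParams())
        assert [(iv.start, iv.end) for iv in joined] == [(50, 59)]

    def test_min_protected_in_cluster(self):
        params = CallerParams(min_footprint_length=3, min_protected_in_cluster=3)
        assert cluster_footprints([50, 55], params) == []


def _iv(start, end, strand):
    from footcall.protection import _StrandInterval
    return _StrandInterval(start, end, strand, tuple(range(start, end + 1)))


class TestStrandReconciliation:
    def test_overlap_longest_strand_wins(self):
        fps = reconcile_strands([_iv(10, 30, "forward")], [_iv(15, 30, "reverse")], 1300)
        (f,) = fps
        assert (f.start, f.end) == (10, 30) and f.defining_strand == "both"

    def test_offset_five_prime_limits(self):
        fps = reconcile_strands([_iv(100, 110, "forward")], [_iv(113, 118, "reverse")], 1300)
        (f,) = fps
        assert (f.start, f.end) == (100, 118)

    def test_far_apart_stay_separate(self):
        fps = reconcile_strands([_iv(100, 110, "forward")], [_iv(130, 140, "reverse")], 1300)
        assert [(f.start, f.end) for f in fps] == [(100, 110), (130, 140)]

    def test_single_strand_passthrough(self):
        fps = reconcile_strands([_iv(10, 30, "forward")], [], 1300)
        (f,) = fps
        assert (f.start, f.end, f.defining_strand) == (10, 30, "forward")

    def test_equal_length_tie_takes_union(self):
        fps = reconcile_strands([_iv(10, 20, "forward")], [_iv(15, 25, "reverse")], 1300)
        (f,) = fps
        assert (f.start, f.end) == (10, 25)

    def test_naming_runs_proximal_to_distal(self):
        fps = reconcile_strands(
            [_iv(100, 120, "forward"), _iv(500, 520, "forward"),
             _iv(900, 920, "forward")], [], 1300)
        assert [f.name for f in fps] == ["M3", "M2", "M1"]

    def test_footprints_disjoint_and_cover_surviving_positions(self, analysis):
        fps = analysis.footprints
        for a, b in zip(fps.footprints, fps.footprints[1:]):
            assert a.end < b.start
        for f in fps:
            for pos in f.protected_positions["all"]:
                assert f.start <= pos <= f.end


class TestHeterogeneity:
    def test_homogeneous_is_null(self):
        fps = FootprintSet("region", 1000, (Footprint("M1", 1, 500),))
        # identical protected proportion (20%) inside and outside
        protected = list(range(1, 101)) + list(range(501, 601))
        res = heterogeneity_test(fps, protected)
        assert res["chi2"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_chi2_matches_textbook_oracle(self):
        fps = FootprintSet("region", 1300, (Footprint("M1", 1, 444),))
        protected = list(range(1, 301)) + list(range(445, 495))  # 300 in, 50 out
        res = heterogeneity_test(fps, protected)
        # brute-force oracle: sum (O - E)^2 / E from the margins
        obs = np.array([[300, 144], [50, 806]], dtype=float)
        row, col, n = obs.sum(1), obs.sum(0), obs.sum()
        exp = np.outer(row, col) / n
        chi2_oracle = ((obs - exp) ** 2 / exp).sum()
        assert res["chi2"] == pytest.approx(chi2_oracle)
        assert res["p"] == pytest.approx(stats.chi2.sf(chi2_oracle, 1))

    def test_fully_separated_is_extreme(self):
        fps = FootprintSet("region", 1300, (Footprint("M1", 1, 444),))
        res = heterogeneity_test(fps, range(1, 445))
        assert res["p"] < 1e-3
        assert res["chi2"] == pytest.approx(1300.0)  # maximal for these margins

    def test_exact_fallback_for_tiny_expectations(self):
        fps = FootprintSet("region", 1300, (Footprint("M1", 1, 9),))
        with pytest.warns(UserWarning, match="Fisher"):
            res = heterogeneity_test(fps, [1])
        assert res["method"] == "fisher"


class TestCallerInvariants:
    def test_threshold_monotonicity(self, study):
        cfg, _seq, _truth, records, fragments = study
        prev_protected, prev_bp, prev_n = None, None, None
        for thr in (1.5, 2.0, 3.0, 4.5):
            res = analyze_peaks(records, fragments, cfg.region_length,
                                CallerParams(ratio_threshold=thr))
            protected = res.protected_positions
            if prev_protected is not None:
                assert protected <= prev_protected
                assert res.footprints.total_bp <= prev_bp
                assert len(res.footprints) <= prev_n
            prev_protected, prev_bp, prev_n = (
                protected, res.footprints.total_bp, len(res.footprints))

    def test_sample_scale_invariance(self, study):
        cfg, _seq, _truth, records, fragments = study
        base = analyze_peaks(records, fragments, cfg.region_length)
        key = ("sub1", "FOXO", 600, "forward")
        scaled_records = [
            PeakRecord(r.called_size, r.height * 7.0, r.channel, r.replicate_id,
                       r.condition, r.concentration, r.labeled_strand, r.subfragment_id)
            if r.sample_key == key else r
            for r in records
        ]
        scaled = analyze_peaks(scaled_records, fragments, cfg.region_length)
        assert [(f.start, f.end) for f in scaled.footprints] == \
               [(f.start, f.end) for f in base.footprints]
        for strand in ("forward", "reverse"):
            np.testing.assert_allclose(scaled.tracks[strand].ratio_600,
                                       base.tracks[strand].ratio_600, rtol=1e-9)

    def test_determinism(self, study):
        cfg, _seq, _truth, records, fragments = study
        a = analyze_peaks(records, fragments, cfg.region_length)
        b = analyze_peaks(records, fragments, cfg.region_length)
        assert [(f.name, f.start, f.end, f.defining_strand) for f in a.footprints] == \
               [(f.name, f.start, f.end, f.defining_strand) for f in b.footprints]
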