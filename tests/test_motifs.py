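"""IUPAC scanning, footprint assignment, densities and consensus derivation."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from footcall.io import Footprint, FootprintSet, RegionPartition, ValidationError
from footcall.motifs import (
    IUPAC_SETS,
    MotifPattern,
    assign_hits_to_footprints,
    counts_from_densities,
    default_patterns,
    derive_consensus,
    motif_density,
    reverse_complement,
    scan_motifs,
)

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def brute_force_scan(sequence, pattern):
    """Independent oracle: position-by-position IUPAC comparison at every
    offset of both strands."""
    seq = sequence.upper()
    plen = len(pattern)
    hits = set()
    rc_seq = "".join(_COMP[c] for c in reversed(seq))
    for i in range(len(seq) - plen + 1):
        if all(seq[i + k] in IUPAC_SETS[pattern[k]] for k in range(plen)):
            hits.add((i + 1, i + plen, "forward"))
        if all(rc_seq[i + k] in IUPAC_SETS[pattern[k]] for k in range(plen)):
            # reflect reverse-complement coordinates back to forward strand
            start = len(seq) - (i + plen) + 1
            hits.add((start, start + plen - 1, "reverse"))
    return hits


class TestScan:
    def test_forward_hit(self):
        hits = scan_motifs("AATTGTTTCC", [MotifPattern("dbe", "TTGTTT", "DBE_core")])
        assert [(h.start, h.end, h.strand) for h in hits] == [(3, 8, "forward")]

    def test_reverse_hit(self):
        hits = scan_motifs("AAACAA", [MotifPattern("dbe", "TTGTTT", "DBE_core")])
        assert [(h.start, h.end, h.strand) for h in hits] == [(1, 6, "reverse")]

    @pytest.mark.parametrize("seq, matches", [("TGTTT", True), ("TCTTT", False)])
    def test_iupac_semantics(self, seq, matches):
        hits = scan_motifs(seq, [MotifPattern("fkh", "TRTTK", "FKH")],
                           strands=("forward",))
        assert bool(hits) is matches

    def test_derived_consensus_matches_dbe_instance(self):
        hits = scan_motifs("TTGTTTAC",
                           [MotifPattern("cons", "TTDTTKNB", "derived_consensus")],
                           strands=("forward",))
        assert [(h.start, h.end) for h in hits] == [(1, 8)]

    def test_self_overlapping_matches_all_reported(self):
        hits = scan_motifs("TTTTTTTT", [MotifPattern("t6", "TTTTTT", "near_DBE")],
                           strands=("forward",))
        assert [(h.start, h.end) for h in hits] == [(1, 6), (2, 7), (3, 8)]

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValidationError):
            MotifPattern("bad", "TTXTT", "FKH")

    def test_agrees_with_brute_force_oracle(self, rng):
        patterns = default_patterns()
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=1000))
            for pat in patterns:
                ours = {(h.start, h.end, h.strand)
                        for h in scan_motifs(seq, [pat])}
                assert ours == brute_force_scan(seq, pat.iupac)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.text(alphabet="ACGT", min_size=6, max_size=60),
           st.sampled_from([p.iupac for p in default_patterns()]))
    def test_reverse_complement_symmetry(self, seq, pattern_iupac):
        """Scanning the reverse complement swaps strands and reflects
        coordinates but preserves the hit multiset."""
        pat = [MotifPattern("p", pattern_iupac, "FKH")]
        L = len(seq)
        rc = "".join(_COMP[c] for c in reversed(seq))
        direct = {(h.start, h.end, h.strand) for h in scan_motifs(seq, pat)}
        flipped = {(L - h.end + 1, L - h.start + 1,
                    "forward" if h.strand == "reverse" else "reverse")
                   for h in scan_motifs(rc, pat)}
        assert direct == flipped


class TestAssignment:
    FPS = FootprintSet("region", 1300, (Footprint("M2", 90, 130), Footprint("M1", 190, 210)))

    def test_hit_inside_footprint(self):
        from footcall.motifs import MotifHit
        hits = [MotifHit("dbe", "DBE_core", 200, 205, "forward")]
        (h,) = assign_hits_to_footprints(hits, self.FPS)
        assert h.footprint == "M1"

    def test_hit_outside_footprints(self):
        from footcall.motifs import MotifHit
        hits = [MotifHit("dbe", "DBE_core", 500, 505, "forward")]
        (h,) = assign_hits_to_footprints(hits, self.FPS)
        assert h.footprint is None

    def test_fkh_subsumed_by_overlapping_dbe(self):
        from footcall.motifs import MotifHit
        hits = [
            MotifHit("dbe", "DBE_core", 99, 104, "forward"),
            MotifHit("fkh", "FKH", 100, 104, "forward"),
            MotifHit("fkh", "FKH", 120, 124, "forward"),
        ]
        out = assign_hits_to_footprints(hits, self.FPS)
        assert [h.subsumed for h in out] == [False, True, False]
        report = motif_density(out, RegionPartition())
        assert report["total"] == 2  # subsumed FKH excluded from counts


class TestDensity:
    def test_published_fragment_densities(self):
        """3 hits in the 392 bp fragment -> 7.7/kb; 21 in the 650 bp -> 32.3/kb."""
        from footcall.motifs import MotifHit
        part = RegionPartition()
        hits = [MotifHit("dbe", "DBE_core", 300 + 6 * i, 305 + 6 * i, "forward",
                         footprint="f") for i in range(3)]
        hits += [MotifHit("dbe", "DBE_core", 660 + 6 * i, 665 + 6 * i, "forward",
                          footprint="f") for i in range(21)]
        report = motif_density(hits, part)
        assert report["counts"] == [0, 3, 21]
        assert report["densities_per_kb"] == [0.0, 7.7, 32.3]

    def test_no_hits_reports_zeros(self):
        report = motif_density([], RegionPartition())
        assert report["densities_per_kb"] == [0.0, 0.0, 0.0]
        assert report["percentages"] == [0, 0, 0]

    def test_span_matched_on_both_strands_counts_once(self):
        from footcall.motifs import MotifHit
        hits = [MotifHit("p", "DBE_core", 10, 15, "forward", footprint="f"),
                MotifHit("p", "DBE_core", 10, 15, "reverse", footprint="f")]
        assert motif_density(hits, RegionPartition())["total"] == 1

    def test_counts_and_densities_round_trip(self, rng):
        """Sum of fragment counts equals the total and density x length
        rounds back to the count."""
        from footcall.motifs import MotifHit
        part = RegionPartition()
        starts = sorted(rng.choice(np.arange(1, 1290), size=40, replace=False))
        hits = [MotifHit("p", "DBE_core", int(s), int(s) + 5, "forward",
                         footprint="f") for s in starts]
        report = motif_density(hits, part)
        assert sum(report["counts"]) == report["total"] == 40
        assert counts_from_densities(report["densities_per_kb"],
                                     report["fragment_lengths"]) == report["counts"]


class TestConsensus:
    def test_identical_sites(self):
        cons, pfm = derive_consensus(["TTGTTTGC"] * 3)
        assert cons == "TTGTTTGC"
        assert pfm.sum() == 24

    def test_degenerate_columns_enumerated_by_hand(self):
        sites = ["TTGTTGGC", "TTATTTTG", "TTTTTTGT"]
        cons, _ = derive_consensus(sites, freq_threshold=0.2)
        assert cons == "TTDTTKKB"

    def test_matches_column_count_oracle(self, rng):
        sites = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(30)]
        cons, pfm = derive_consensus(sites, freq_threshold=0.10)
        set_to_code = {v: k for k, v in IUPAC_SETS.items()}
        for j in range(8):
            counts = Counter(s[j] for s in sites)
            keep = frozenset(b for b, c in counts.items() if c / 30 >= 0.10)
            assert cons[j] == set_to_code[keep]
            for i, base in enumerate("ACGT"):
                assert pfm[i, j] == counts.get(base, 0)

    def test_threshold_zero_is_fully_degenerate(self):
        cons, _ = derive_consensus(["AC", "CC", "GC", "TC"], freq_threshold=0.0)
        assert cons == "NC"
        cons, _ = derive_consensus(["AC", "GC", "TC"], freq_threshold=0.0)
        assert cons == "DC"  # only observed bases enter the code

    def test_unreachable_threshold_fails_loudly(self):
        with pytest.raises(ValidationError, match="threshold"):
            derive_consensus(["AC", "GC", "TC", "CC"], freq_threshold=0.9)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError, match="length"):
            derive_consensus(["ACGT", "ACG"])

    def test_dbe_site_collection_gives_ttdttknb(self):
        """A site collection with the composition the derived Drosophila
        consensus implies (D at 3, K at 6, N at 7, B at 8) round-trips
        through derivation."""
        sites = (
            ["TTGTTTGC"] * 40 + ["TTATTTAG"] * 25 + ["TTTTTTTT"] * 20
            + ["TTGTTGCT"] * 12 + ["TTATTTGG"] * 8
        )
        assert len(sites) == 105
        cons, _ = derive_consensus(sites, freq_threshold=0.10)
        assert cons == "TTDTTKNB"

    def test_reverse_complement_helper(self):
        assert reverse_complement("TTDTTKNB") == "VNMAAHAA"
        assert reverse_complement("TRTTK") == "MAAYA"
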