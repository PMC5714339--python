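"""Degenerate-motif scanning and binding-element statistics.

The FOXO-family elements handled here are short exact degenerate patterns,
not weight matrices: the DBE cores TTGTTT / TTATTT shared by the mouse DBE
and IRE elements, the single-mismatch near-DBE variants TTGTTG / TTTTTT,
the pan-FORKHEAD core TRTTK, and a derived degenerate consensus (default
TTDTTKNB).  Scanning covers both strands, reporting every (also
self-overlapping) match in forward-strand coordinates.

Density statistics follow the region partition into distal / central /
proximal fragments; the counting unit is the distinct matched span, so a
palindromic-like span matched on both strands counts once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import FootprintSet, RegionPartition, ValidationError

__all__ = [
    "IUPAC_SETS",
    "MotifPattern",
    "MotifHit",
    "default_patterns",
    "reverse_complement",
    "scan_motifs",
    "assign_hits_to_footprints",
    "motif_density",
    "counts_from_densities",
    "derive_consensus",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_SET_TO_IUPAC = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "S": "S", "W": "W", "N": "N",
}

PATTERN_CLASSES = ("DBE_core", "near_DBE", "FKH", "derived_consensus")


def reverse_complement(pattern: str) -> str:
    """Reverse complement of a (possibly degenerate) IUPAC string."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(pattern.upper()))
    except KeyError as exc:
        raise ValidationError(f"invalid IUPAC symbol {exc.args[0]!r} in {pattern!r}") from exc


@dataclass(frozen=True)
class MotifPattern:
    """One degenerate search pattern with its element class."""

    pattern_id: str
    iupac: str
    pattern_class: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValidationError("empty pattern")
        bad = [c for c in self.iupac.upper() if c not in IUPAC_SETS]
        if bad:
            raise ValidationError(f"invalid IUPAC symbol {bad[0]!r} in {self.iupac!r}")
        if self.pattern_class not in PATTERN_CLASSES:
            raise ValidationError(f"unknown pattern class {self.pattern_class!r}")
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)


def default_patterns(
    include: Iterable[str] = PATTERN_CLASSES,
) -> list[MotifPattern]:
    """The registered element set; each class individually switchable."""
    registry = [
        MotifPattern("DBE_TTGTTT", "TTGTTT", "DBE_core"),
        MotifPattern("DBE_TTATTT", "TTATTT", "DBE_core"),
        MotifPattern("nearDBE_TTGTTG", "TTGTTG", "near_DBE"),
        MotifPattern("nearDBE_TTTTTT", "TTTTTT", "near_DBE"),
        MotifPattern("FKH_TRTTK", "TRTTK", "FKH"),
        MotifPattern("consensus_TTDTTKNB", "TTDTTKNB", "derived_consensus"),
    ]
    wanted = set(include)
    unknown = wanted - set(PATTERN_CLASSES)
    if unknown:
        raise ValidationError(f"unknown pattern classes {sorted(unknown)}")
    return [p for p in registry if p.pattern_class in wanted]


@dataclass(frozen=True)
class MotifHit:
    """One motif match, in 1-based inclusive forward-strand coordinates of
    the occupied span regardless of the matching strand."""

    pattern_id: str
    pattern_class: str
    start: int
    end: int
    strand: str
    footprint: str | None = None
    subsumed: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _matches_at(seq: str, pattern: str, offset: int) -> bool:
    return all(seq[offset + k] in IUPAC_SETS[pattern[k]] for k in range(len(pattern)))


def scan_motifs(
    sequence: str,
    patterns: Sequence[MotifPattern] | None = None,
    strands: Sequence[str] = ("forward", "reverse"),
) -> list[MotifHit]:
    """Find every occurrence of each pattern on the requested strands.

    A reverse-strand hit is found by matching the reverse-complemented
    pattern against the forward sequence; its coordinates are the occupied
    forward-strand span.  Hits are ordered by (start, strand, pattern_id).
    """
    seq = sequence.upper()
    bad = [c for c in seq if c not in "ACGT"]
    if bad:
        raise ValidationError(f"non-ACGT symbol {bad[0]!r} in sequence")
    if patterns is None:
        patterns = default_patterns()
    hits: list[MotifHit] = []
    for pat in patterns:
        plen = len(pat)
        probes = []
        if "forward" in strands:
            probes.append((pat.iupac, "forward"))
        if "reverse" in strands:
            probes.append((reverse_complement(pat.iupac), "reverse"))
        for probe, strand in probes:
            for i in range(len(seq) - plen + 1):
                if _matches_at(seq, probe, i):
                    hits.append(MotifHit(
                        pattern_id=pat.pattern_id, pattern_class=pat.pattern_class,
                        start=i + 1, end=i + plen, strand=strand,
                    ))
    hits.sort(key=lambda h: (h.start, h.strand, h.pattern_id))
    return hits


def assign_hits_to_footprints(
    hits: Sequence[MotifHit],
    footprints: FootprintSet,
    dbe_precedence: bool = True,
) -> list[MotifHit]:
    """Annotate hits with the footprint they fall in (any overlap of at
    least 1 bp; the larger overlap wins when a hit straddles two footprints).

    With ``dbe_precedence`` on, an FKH hit whose span overlaps any DBE-core
    or near-DBE hit span is flagged ``subsumed``: FKH elements are counted
    only outside the DBE elements, though the hit itself is still reported.
    """
    dbe_spans = [
        (h.start, h.end) for h in hits if h.pattern_class in ("DBE_core", "near_DBE")
    ]
    annotated = []
    for h in hits:
        best, best_ov = None, 0
        for f in footprints:
            ov = min(h.end, f.end) - max(h.start, f.start) + 1
            if ov > best_ov:
                best, best_ov = f, ov
        subsumed = (
            dbe_precedence
            and h.pattern_class == "FKH"
            and any(h.start <= e and s <= h.end for s, e in dbe_spans)
        )
        annotated.append(replace(h, footprint=best.name if best else None,
                                 subsumed=subsumed))
    return annotated


def _distinct_spans(hits: Iterable[MotifHit]) -> list[tuple[int, int]]:
    return sorted({(h.start, h.end) for h in hits})


def motif_density(
    hits: Sequence[MotifHit],
    partition: RegionPartition,
    in_footprints_only: bool = True,
    exclude_subsumed: bool = True,
) -> dict:
    """Per-fragment motif counts, densities per kb, and percentages.

    The counting unit is the distinct hit span (a span matched on both
    strands counts once); a span belongs to the partition fragment containing
    its start coordinate.  Densities are rounded to one decimal, percentages
    to the nearest integer.  With no hits at all, densities and percentages
    are reported as zero.
    """
    kept = [
        h for h in hits
        if (not in_footprints_only or h.footprint is not None)
        and (not exclude_subsumed or not h.subsumed)
    ]
    spans = _distinct_spans(kept)
    lengths = partition.fragment_lengths
    counts = [0] * len(lengths)
    for s, _e in spans:
        counts[partition.fragment_index(s)] += 1
    total = sum(counts)
    densities = [round(c / (ln / 1000), 1) for c, ln in zip(counts, lengths)]
    if total:
        percentages = [round(100 * c / total) for c in counts]
    else:
        percentages = [0] * len(counts)
    return {
        "fragment_lengths": list(lengths),
        "counts": counts,
        "densities_per_kb": densities,
        "percentages": percentages,
        "total": total,
    }


def counts_from_densities(
    densities_per_kb: Sequence[float], fragment_lengths_bp: Sequence[int]
) -> list[int]:
    """Invert a published per-kb density back to the integer motif count of
    each fragment (density x length in kb, rounded)."""
    if len(densities_per_kb) != len(fragment_lengths_bp):
        raise ValidationError("densities and fragment lengths differ in number")
    return [round(d * ln / 1000) for d, ln in zip(densities_per_kb, fragment_lengths_bp)]


def derive_consensus(
    sites: Sequence[str],
    freq_threshold: float = 0.10,
) -> tuple[str, np.ndarray]:
    """Derive a degenerate IUPAC consensus from aligned fixed-length sites.

    Per column, base frequencies are computed and the consensus symbol is
    the (unique) IUPAC code whose base set is exactly the bases reaching
    ``freq_threshold``.  With threshold 0 every observed base enters the
    code; a threshold above the top frequency of some column is an error
    rather than an empty symbol.  Returns the consensus and the 4 x L
    position frequency matrix (rows A, C, G, T; counts).
    """
    if not sites:
        raise ValidationError("no sites given")
    L = len(sites[0])
    if L < 1:
        raise ValidationError("sites must be non-empty strings")
    cleaned = []
    for s in sites:
        s = s.upper()
        if len(s) != L:
            raise ValidationError(f"site {s!r} length {len(s)} != {L}")
        if any(c not in "ACGT" for c in s):
            raise ValidationError(f"non-ACGT symbol in site {s!r}")
        cleaned.append(s)

    order = "ACGT"
    pfm = np.zeros((4, L), dtype=int)
    for s in cleaned:
        for j, c in enumerate(s):
            pfm[order.index(c), j] += 1
    n = len(cleaned)
    symbols = []
    for j in range(L):
        freqs = pfm[:, j] / n
        bases = frozenset(order[i] for i in range(4) if freqs[i] >= freq_threshold
                          and pfm[i, j] > 0)
        if not bases:
            raise ValidationError(
                f"column {j + 1}: no base reaches frequency threshold {freq_threshold}"
            )
        symbols.append(_SET_TO_IUPAC[bases])
    return "".join(symbols), pfm
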