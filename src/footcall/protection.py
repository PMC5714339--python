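"""Protection ratios, protected-residue calls, footprint definition and the
within/outside-footprint heterogeneity test.

The calling rules mirror classic double-strand DNase I footprinting
practice: a residue is *protected* when its control/protein cleavage ratio
(BSA over transcription factor) is at least ``ratio_threshold`` at either
protein concentration; protected residues must cluster; overlapping
footprints on the two strands are resolved in favor of the strand with the
longer footprinted sequence; slightly offset strand footprints are bounded
by the 5' protected residue of each strand.

A ratio of one means no protection.  Ratios are computed on mean normalized
heights, so they are invariant to rescaling all heights of any one sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import Footprint, FootprintSet, ValidationError
from .peakmap import ResidueProfile

__all__ = [
    "CallerParams",
    "RatioTrack",
    "ProtectionTrack",
    "protection_ratio",
    "call_protected_residues",
    "cluster_footprints",
    "reconcile_strands",
    "heterogeneity_test",
    "merge_to_region",
    "call_footprints",
]

logger = logging.getLogger(__name__)

# support codes for one residue of a ratio track
BOTH_OBSERVED = "both_observed"
FOXO_MISSING = "foxo_missing"
BSA_MISSING = "bsa_missing"
UNOBSERVED = "unobserved"


@dataclass(frozen=True)
class CallerParams:
    """Tunable parameters of the footprint caller.

    ratio_threshold
        Minimum BSA/protein height ratio for a protected residue (inclusive).
    max_gap
        Longest run of unprotected residues bridged inside one cluster, and
        the maximum strand offset treated as the same footprint (bp).
    min_protected_in_cluster
        Minimum number of protected residues a cluster must contain.
    min_footprint_length
        Minimum footprint span in bp.
    epsilon_fraction
        When the protein-condition peak is absent but the control peak is
        present (complete protection), the ratio is computed against this
        fraction of the protein sample's median normalized height.
    ratio_cap
        Upper bound applied to such imputed ratios, avoiding infinities.
    """

    ratio_threshold: float = 2.0
    max_gap: int = 4
    min_protected_in_cluster: int = 3
    min_footprint_length: int = 9
    epsilon_fraction: float = 0.05
    ratio_cap: float = 50.0

    def __post_init__(self) -> None:
        if self.ratio_threshold <= 0 or self.epsilon_fraction <= 0 or self.ratio_cap <= 0:
            raise ValidationError("caller parameters must be positive")
        if self.min_footprint_length < 1 or self.min_protected_in_cluster < 1:
            raise ValidationError("caller parameters must be positive")
        if self.max_gap < 0:
            raise ValidationError("max_gap must be >= 0")


@dataclass
class RatioTrack:
    """Per-residue BSA/protein ratios for one strand at one concentration."""

    strand: str
    concentration: int
    length: int
    ratio: np.ndarray          # float; nan where unobserved or bsa-missing
    support: np.ndarray        # object array of support codes

    def value_at(self, position: int) -> float:
        return float(self.ratio[position - 1])


@dataclass
class ProtectionTrack:
    """Combined two-concentration protection state for one strand."""

    strand: str
    length: int
    ratio_600: np.ndarray
    ratio_1200: np.ndarray
    support_600: np.ndarray
    support_1200: np.ndarray
    protected: np.ndarray      # bool

    @property
    def protected_positions(self) -> tuple[int, ...]:
        return tuple(int(i) + 1 for i in np.flatnonzero(self.protected))


def protection_ratio(
    bsa: ResidueProfile,
    foxo: ResidueProfile,
    params: CallerParams = CallerParams(),
) -> RatioTrack:
    """Per-residue BSA/protein height ratio for one strand and concentration.

    Residues observed in both conditions get the plain ratio.  A residue with
    control signal but no protein signal in any replicate is completely
    protected: its ratio is imputed as ``bsa / (epsilon_fraction * median
    protein height)``, capped at ``ratio_cap`` and flagged ``foxo_missing``.
    Residues with no control signal are flagged and carry no ratio.
    """
    if bsa.strand != foxo.strand or bsa.concentration != foxo.concentration:
        raise ValidationError("profiles must share strand and concentration")
    if bsa.subfragment_id != foxo.subfragment_id or bsa.insert_length != foxo.insert_length:
        raise ValidationError("profiles must cover the same fragment")
    if bsa.condition != "BSA" or foxo.condition != "FOXO":
        raise ValidationError("expected (BSA, FOXO) profile pair")

    L = bsa.insert_length
    b = bsa.mean_norm_height
    f = foxo.mean_norm_height
    ratio = np.full(L, np.nan)
    support = np.empty(L, dtype=object)

    observed_f = f[~np.isnan(f)]
    epsilon = params.epsilon_fraction * (np.median(observed_f) if observed_f.size else 1.0)

    for i in range(L):
        b_ok = not np.isnan(b[i])
        f_ok = not np.isnan(f[i])
        if b_ok and f_ok:
            support[i] = BOTH_OBSERVED
            ratio[i] = b[i] / f[i] if f[i] > 0 else min(params.ratio_cap, np.inf)
        elif b_ok:
            support[i] = FOXO_MISSING
            ratio[i] = min(b[i] / epsilon, params.ratio_cap)
        elif f_ok:
            support[i] = BSA_MISSING
        else:
            support[i] = UNOBSERVED
    return RatioTrack(
        strand=bsa.strand, concentration=bsa.concentration, length=L,
        ratio=ratio, support=support,
    )


def call_protected_residues(
    track_600: RatioTrack,
    track_1200: RatioTrack,
    params: CallerParams = CallerParams(),
) -> ProtectionTrack:
    """A residue is protected iff its ratio reaches the threshold at either
    protein concentration (inclusive), and it was observed at all."""
    if track_600.strand != track_1200.strand:
        raise ValidationError("tracks must be on the same strand")
    if {track_600.concentration, track_1200.concentration} != {600, 1200}:
        raise ValidationError("need one 600 nM and one 1200 nM track")
    if track_600.concentration != 600:
        track_600, track_1200 = track_1200, track_600
    if track_600.length != track_1200.length:
        raise ValidationError("track length mismatch")

    with np.errstate(invalid="ignore"):
        best = np.fmax(track_600.ratio, track_1200.ratio)  # nan-ignoring max
    protected = ~np.isnan(best) & (best >= params.ratio_threshold)
    return ProtectionTrack(
        strand=track_600.strand, length=track_600.length,
        ratio_600=track_600.ratio, ratio_1200=track_1200.ratio,
        support_600=track_600.support, support_1200=track_1200.support,
        protected=protected,
    )


@dataclass(frozen=True)
class _StrandInterval:
    start: int
    end: int
    strand: str
    positions: tuple[int, ...]  # protected residues inside, per originating strand

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def cluster_footprints(
    protected_positions: Sequence[int],
    params: CallerParams = CallerParams(),
    strand: str = "forward",
) -> list[_StrandInterval]:
    """Greedy left-to-right clustering of protected residues on one strand.

    Consecutive protected residues join a cluster while the gap of
    unprotected residues between them is at most ``max_gap``; clusters with
    fewer than ``min_protected_in_cluster`` residues or spanning less than
    ``min_footprint_length`` bp are discarded.  The interval runs from the
    first to the last protected residue of the cluster.
    """
    positions = sorted(set(int(p) for p in protected_positions))
    clusters: list[list[int]] = []
    for pos in positions:
        if clusters and pos - clusters[-1][-1] - 1 <= params.max_gap:
            clusters[-1].append(pos)
        else:
            clusters.append([pos])
    out = []
    for cl in clusters:
        span = cl[-1] - cl[0] + 1
        if len(cl) < params.min_protected_in_cluster or span < params.min_footprint_length:
            continue
        out.append(_StrandInterval(start=cl[0], end=cl[-1], strand=strand,
                                   positions=tuple(cl)))
    return out


def _pair_merge(a: _StrandInterval, b: _StrandInterval,
                params: CallerParams) -> _StrandInterval | None:
    """Resolve one forward/reverse interval pair, or return None if unrelated."""
    fwd, rev = (a, b) if a.strand == "forward" else (b, a)
    overlap = min(a.end, b.end) - max(a.start, b.start) + 1
    if overlap >= 1:
        # overlapping strands: the longer footprinted strand defines the extent
        if a.length > b.length:
            keep = a
        elif b.length > a.length:
            keep = b
        else:  # equal lengths: union of both
            return _StrandInterval(min(a.start, b.start), max(a.end, b.end), "both",
                                   tuple(sorted(set(a.positions) | set(b.positions))))
        return _StrandInterval(keep.start, keep.end, "both",
                               tuple(sorted(set(a.positions) | set(b.positions))))
    gap = max(a.start, b.start) - min(a.end, b.end) - 1
    if 0 <= gap <= params.max_gap:
        # slightly offset strands: limits are the 5' protected residues of
        # each strand (forward 5' = lowest coordinate, reverse 5' = highest)
        start, end = fwd.start, rev.end
        if start > end:  # reverse footprint lies upstream; fall back to union
            start, end = min(a.start, b.start), max(a.end, b.end)
        return _StrandInterval(start, end, "both",
                               tuple(sorted(set(a.positions) | set(b.positions))))
    return None


def reconcile_strands(
    forward_intervals: Sequence[_StrandInterval],
    reverse_intervals: Sequence[_StrandInterval],
    region_length: int,
    params: CallerParams = CallerParams(),
    region_name: str = "region",
    name_prefix: str = "M",
) -> FootprintSet:
    """Combine per-strand footprint intervals into one named footprint set.

    Cross-strand pairs are resolved per the overlap/offset rules (applied
    transitively); residual overlaps from chained merges are unioned.
    Footprints are numbered from the proximal (3') end of the forward
    strand: the most proximal footprint is ``<prefix>1``, so reading the
    region 5' to 3' gives ``<prefix>N .. <prefix>1``.
    """
    items: list[_StrandInterval] = [replace(iv, strand="forward") for iv in forward_intervals]
    items += [replace(iv, strand="reverse") for iv in reverse_intervals]

    changed = True
    while changed:
        changed = False
        items.sort(key=lambda iv: (iv.start, iv.end, iv.strand))
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if "both" in (a.strand, b.strand) or a.strand == b.strand:
                    continue
                merged = _pair_merge(a, b, params)
                if merged is not None:
                    items = [iv for k, iv in enumerate(items) if k not in (i, j)]
                    items.append(merged)
                    changed = True
                    break
            if changed:
                break

    # chained merges can leave residual overlaps; union them
    items.sort(key=lambda iv: (iv.start, iv.end))
    merged_items: list[_StrandInterval] = []
    for iv in items:
        if merged_items and iv.start <= merged_items[-1].end:
            prev = merged_items[-1]
            strand = prev.strand if prev.strand == iv.strand else "both"
            merged_items[-1] = _StrandInterval(
                prev.start, max(prev.end, iv.end), strand,
                tuple(sorted(set(prev.positions) | set(iv.positions))),
            )
        else:
            merged_items.append(iv)

    n = len(merged_items)
    footprints = []
    for idx, iv in enumerate(merged_items):
        footprints.append(
            Footprint(
                name=f"{name_prefix}{n - idx}",
                start=iv.start, end=iv.end,
                defining_strand=iv.strand,
                protected_positions={"all": iv.positions},
            )
        )
    return FootprintSet(region_name=region_name, region_length=region_length,
                        footprints=tuple(footprints))


def heterogeneity_test(
    footprints: FootprintSet,
    protected_positions: Iterable[int],
    region_length: int | None = None,
) -> dict:
    """Chi-square test (1 df, no continuity correction) of protected-residue
    counts inside versus outside footprints.

    The 2x2 table is {protected, unprotected} x {inside, outside}, with the
    inside total equal to the summed footprint length.  When any expected
    cell count falls below 1 a Fisher exact test replaces the chi-square
    p-value (flagged in the result).
    """
    if region_length is None:
        region_length = footprints.region_length
    protected = {int(p) for p in protected_positions}
    if any(p < 1 or p > region_length for p in protected):
        raise ValidationError("protected position outside region")
    inside_total = footprints.total_bp
    outside_total = region_length - inside_total
    prot_in = sum(1 for p in protected if footprints.containing(p) is not None)
    prot_out = len(protected) - prot_in
    table = np.array([[prot_in, inside_total - prot_in],
                      [prot_out, outside_total - prot_out]], dtype=float)
    if (table < 0).any():
        raise ValidationError("more protected residues than residues in a class")

    expected = stats.contingency.expected_freq(table)
    result = {"table": table.astype(int), "method": "chi2"}
    if (expected == 0).any():
        result.update(chi2=0.0, p=1.0, method="degenerate")
        return result
    chi2 = float((np.square(table - expected) / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    if (expected < 1).any():
        warnings.warn("expected cell count < 1; falling back to Fisher exact test")
        _, p = stats.fisher_exact(table.astype(int))
        result["method"] = "fisher"
    result.update(chi2=chi2, p=float(p))
    return result


# --------------------------------------------------------------------------
# region-level orchestration
# --------------------------------------------------------------------------

def merge_to_region(
    profiles: Sequence[ResidueProfile],
    fragments: Mapping[str, "LabeledFragment"],
    region_length: int,
) -> ResidueProfile:
    """Combine same-sample profiles of overlapping subfragments into one
    region-coordinate profile.

    Positions covered by several subfragments take the replicate-weighted
    mean of the subfragment means; the recorded replicate count is the
    maximum over contributing subfragments.
    """
    keys = {(p.strand, p.condition, p.concentration) for p in profiles}
    if len(keys) != 1:
        raise ValidationError(f"profiles from mixed samples: {keys}")
    strand, condition, conc = keys.pop()
    weight = np.zeros(region_length)
    total = np.zeros(region_length)
    n_obs = np.zeros(region_length, dtype=int)
    for p in profiles:
        frag = fragments[p.subfragment_id]
        off = frag.region_offset - 1
        for i in range(p.insert_length):
            h, n = p.mean_norm_height[i], p.n_replicates_observed[i]
            if n > 0 and not np.isnan(h):
                total[off + i] += h * n
                weight[off + i] += n
                n_obs[off + i] = max(n_obs[off + i], n)
    mean = np.full(region_length, np.nan)
    covered = weight > 0
    mean[covered] = total[covered] / weight[covered]
    return ResidueProfile(
        subfragment_id="region", strand=strand, condition=condition,
        concentration=conc, insert_length=region_length,
        mean_norm_height=mean, n_replicates_observed=n_obs,
    )


def call_footprints(
    region_profiles: Mapping[tuple, ResidueProfile],
    region_length: int,
    params: CallerParams = CallerParams(),
    region_name: str = "region",
    name_prefix: str = "M",
) -> tuple[FootprintSet, dict[str, ProtectionTrack]]:
    """Run ratio computation, protected-residue calling, clustering and
    strand reconciliation on region-level profiles.

    ``region_profiles`` is keyed by ``(condition, concentration, strand)``.
    Returns the footprint set and the per-strand protection tracks.
    """
    tracks: dict[str, ProtectionTrack] = {}
    per_strand_intervals: dict[str, list[_StrandInterval]] = {}
    for strand in ("forward", "reverse"):
        ratio_tracks = []
        for conc in (600, 1200):
            bsa = region_profiles.get(("BSA", conc, strand))
            foxo = region_profiles.get(("FOXO", conc, strand))
            if bsa is None or foxo is None:
                raise ValidationError(f"missing profiles for {strand}/{conc}")
            ratio_tracks.append(protection_ratio(bsa, foxo, params))
        track = call_protected_residues(*ratio_tracks, params)
        tracks[strand] = track
        per_strand_intervals[strand] = cluster_footprints(
            track.protected_positions, params, strand=strand
        )
    footprints = reconcile_strands(
        per_strand_intervals["forward"], per_strand_intervals["reverse"],
        region_length=region_length, params=params,
        region_name=region_name, name_prefix=name_prefix,
    )
    return footprints, tracks
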