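"""End-to-end orchestration: peak tables -> profiles -> footprints.

This is the programmatic equivalent of ``footcall call``: it maps peaks to
residues, normalizes and averages replicates per sample, merges overlapping
subfragments onto region coordinates, computes protection ratios at both
protein concentrations, calls and reconciles footprints, and runs the
within/outside-footprint heterogeneity test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .io import FootprintSet, LabeledFragment, PeakRecord, ValidationError
from .peakmap import ResidueProfile, profiles_from_records
from .protection import (
    CallerParams,
    ProtectionTrack,
    call_footprints,
    heterogeneity_test,
    merge_to_region,
)

__all__ = ["RegionAnalysis", "analyze_peaks"]


@dataclass
class RegionAnalysis:
    """Everything the caller produced for one region."""

    footprints: FootprintSet
    tracks: Mapping[str, ProtectionTrack]
    region_profiles: Mapping[tuple, ResidueProfile]
    heterogeneity: dict

    @property
    def protected_positions(self) -> set[int]:
        """Union of protected residues over both strands (region coordinates)."""
        out: set[int] = set()
        for track in self.tracks.values():
            out.update(track.protected_positions)
        return out


def analyze_peaks(
    records: Iterable[PeakRecord],
    fragments: Mapping[str, LabeledFragment],
    region_length: int,
    params: CallerParams = CallerParams(),
    region_name: str = "region",
    name_prefix: str = "M",
) -> RegionAnalysis:
    """Run the full footprint-calling pipeline on annotated peak records."""
    profiles = profiles_from_records(records, fragments)
    by_sample: dict[tuple, list[ResidueProfile]] = {}
    for (sub_id, condition, conc, strand), prof in profiles.items():
        by_sample.setdefault((condition, conc, strand), []).append(prof)

    region_profiles = {
        key: merge_to_region(profs, fragments, region_length)
        for key, profs in by_sample.items()
    }
    expected = {(c, n, s) for c in ("BSA", "FOXO") for n in (600, 1200)
                for s in ("forward", "reverse")}
    missing = expected - set(region_profiles)
    if missing:
        raise ValidationError(f"missing sample profiles: {sorted(missing)}")

    footprints, tracks = call_footprints(
        region_profiles, region_length, params,
        region_name=region_name, name_prefix=name_prefix,
    )
    protected = set()
    for track in tracks.values():
        protected.update(track.protected_positions)
    het = heterogeneity_test(footprints, protected, region_length)
    return RegionAnalysis(
        footprints=footprints, tracks=tracks,
        region_profiles=region_profiles, heterogeneity=het,
    )
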