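"""From raw peak calls to per-residue mean normalized cleavage profiles.

Each electrophoresis peak is a cleavage product whose called size encodes
the cleaved residue: on a forward-labeled read, insert residue ``i``
produces a product of ``vector_prefix + i`` bp; on a reverse-labeled read,
the product of the residue ``j`` positions from the insert 3' end is
``vector_suffix + j`` bp.  Peaks snap to the nearest integer residue within
a tolerance (size calling is sub-bp precise at these lengths), heights are
normalized by the mean height of the sample's size-standard peaks, and
replicates are averaged per residue.

A residue with no peak in a replicate contributes nothing to that residue's
mean (absence can be either true protection or a dropout); downstream
protection calling handles the fully-missing case explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import LabeledFragment, PeakRecord, ValidationError

__all__ = [
    "ResidueProfile",
    "NormalizationFactor",
    "AssignmentResult",
    "assign_peaks_to_residues",
    "normalize_heights",
    "aggregate_replicates",
    "profiles_from_records",
]

logger = logging.getLogger(__name__)

DEFAULT_SIZE_TOLERANCE = 0.5
DEFAULT_MIN_REPLICATES = 3
DEFAULT_MIN_REPLICATES_PER_POSITION = 2


@dataclass(frozen=True)
class NormalizationFactor:
    """Mean height of all size-standard peaks in one sample run."""

    sample_key: tuple
    factor: float

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValidationError(f"normalization factor must be > 0, got {self.factor}")


@dataclass(frozen=True)
class AssignmentResult:
    """Peak-to-residue assignment for one replicate of one sample.

    ``heights`` maps 1-based insert positions (forward-strand coordinates)
    to raw peak heights; every input peak is either assigned, displaced by a
    taller peak at the same residue, or dropped as out of span:
    ``len(assigned) + displaced + dropped == n_input``.
    """

    heights: Mapping[int, float]
    n_input: int
    n_dropped: int
    n_displaced: int


@dataclass
class ResidueProfile:
    """Per-residue mean normalized height for one strand of one condition.

    Positions are 1-based insert coordinates on the forward strand and cover
    ``1..insert_length`` exactly once; residues never observed carry
    ``mean = nan`` and ``n = 0``.
    """

    subfragment_id: str
    strand: str
    condition: str
    concentration: int
    insert_length: int
    mean_norm_height: np.ndarray  # float, len == insert_length, nan = missing
    n_replicates_observed: np.ndarray  # int, len == insert_length
    low_support: np.ndarray = field(default=None)  # bool mask

    def __post_init__(self) -> None:
        if len(self.mean_norm_height) != self.insert_length:
            raise ValidationError("profile length mismatch")
        if self.low_support is None:
            self.low_support = np.zeros(self.insert_length, dtype=bool)

    def value_at(self, position: int) -> float:
        """Mean normalized height at a 1-based insert position (nan if unobserved)."""
        return float(self.mean_norm_height[position - 1])


def assign_peaks_to_residues(
    peaks: Sequence[PeakRecord],
    fragment: LabeledFragment,
    tolerance: float = DEFAULT_SIZE_TOLERANCE,
) -> AssignmentResult:
    """Snap signal peaks of one replicate to insert residues.

    Works for either labeling orientation; reverse-labeled peaks are mapped
    back to forward-strand insert coordinates.  At most one peak per residue:
    when two peaks fall within tolerance of the same residue the taller one
    wins and the loss is logged.
    """
    strands = {p.labeled_strand for p in peaks}
    if len(strands) > 1:
        raise ValidationError(f"peaks from mixed strands {strands}")
    if any(p.channel != "signal" for p in peaks):
        raise ValidationError("assign_peaks_to_residues expects signal-channel peaks")

    heights: dict[int, float] = {}
    n_dropped = 0
    n_displaced = 0
    L = fragment.length
    forward = not peaks or peaks[0].labeled_strand == "forward"
    for p in peaks:
        if forward:
            # size = prefix + i  for insert residue i
            residue = round(p.called_size - fragment.vector_prefix_len)
            expected = fragment.expected_size_forward(residue) if 1 <= residue <= L else None
        else:
            # size = suffix + j, residue counted from the insert 3' end
            j = round(p.called_size - fragment.vector_suffix_len)
            residue = L - j + 1
            expected = fragment.expected_size_reverse(residue) if 1 <= residue <= L else None
        if expected is None or abs(p.called_size - expected) > tolerance:
            n_dropped += 1
            continue
        if residue in heights:
            n_displaced += 1
            if p.height > heights[residue]:
                heights[residue] = p.height
            logger.warning(
                "two peaks within tolerance of residue %d in %s; kept the taller",
                residue, p.sample_key,
            )
        else:
            heights[residue] = p.height
    return AssignmentResult(
        heights=heights, n_input=len(peaks), n_dropped=n_dropped, n_displaced=n_displaced
    )


def normalize_heights(
    heights: Mapping[int, float],
    standard_peaks: Sequence[PeakRecord | float],
    sample_key: tuple = (),
    min_standards: int = 3,
) -> tuple[dict[int, float], NormalizationFactor]:
    """Divide every signal height by the mean height of the sample's
    size-standard peaks.

    This removes run-to-run injection/labeling scale so that replicates and
    the BSA vs protein conditions are comparable; normalized profiles are
    invariant to rescaling all heights of a sample by a constant.
    """
    std_heights = [p.height if isinstance(p, PeakRecord) else float(p) for p in standard_peaks]
    if len(std_heights) < min_standards:
        raise ValidationError(
            f"sample {sample_key}: {len(std_heights)} standard peaks "
            f"(need >= {min_standards}); pass --no-normalize or inject a factor"
        )
    factor = NormalizationFactor(sample_key=sample_key, factor=fmean(std_heights))
    return {pos: h / factor.factor for pos, h in heights.items()}, factor


def aggregate_replicates(
    replicate_maps: Sequence[Mapping[int, float]],
    fragment: LabeledFragment,
    strand: str,
    condition: str,
    concentration: int,
    min_replicates: int = DEFAULT_MIN_REPLICATES,
    min_replicates_per_position: int = DEFAULT_MIN_REPLICATES_PER_POSITION,
) -> ResidueProfile:
    """Average normalized heights per residue across replicates.

    The mean is over the replicates in which the residue's peak was observed
    — missing peaks are not zeros.  Positions observed in fewer than
    ``min_replicates_per_position`` replicates are flagged low-support.
    """
    if len(replicate_maps) < min_replicates:
        raise ValidationError(
            f"only {len(replicate_maps)} replicate maps; need >= {min_replicates}"
        )
    L = fragment.length
    mean = np.full(L, np.nan)
    n_obs = np.zeros(L, dtype=int)
    for pos in range(1, L + 1):
        vals = [m[pos] for m in replicate_maps if pos in m]
        if vals:
            mean[pos - 1] = fmean(vals)
            n_obs[pos - 1] = len(vals)
    low = (n_obs > 0) & (n_obs < min_replicates_per_position)
    return ResidueProfile(
        subfragment_id=fragment.fragment_id,
        strand=strand,
        condition=condition,
        concentration=concentration,
        insert_length=L,
        mean_norm_height=mean,
        n_replicates_observed=n_obs,
        low_support=low,
    )


def profiles_from_records(
    records: Iterable[PeakRecord],
    fragments: Mapping[str, LabeledFragment],
    tolerance: float = DEFAULT_SIZE_TOLERANCE,
    min_replicates: int = DEFAULT_MIN_REPLICATES,
) -> dict[tuple, ResidueProfile]:
    """Full peak-mapping stage: group records by sample, assign, normalize,
    aggregate.  Returns profiles keyed by
    ``(subfragment_id, condition, concentration, labeled_strand)``.
    """
    by_sample_rep: dict[tuple, dict[int, list[PeakRecord]]] = {}
    for rec in records:
        by_sample_rep.setdefault(rec.sample_key, {}).setdefault(rec.replicate_id, []).append(rec)

    profiles: dict[tuple, ResidueProfile] = {}
    for sample_key, reps in sorted(by_sample_rep.items()):
        sub_id, condition, conc, strand = sample_key
        if sub_id not in fragments:
            raise ValidationError(f"no fragment sequence for subfragment {sub_id!r}")
        fragment = fragments[sub_id]
        rep_maps = []
        for rep_id, recs in sorted(reps.items()):
            signal = [r for r in recs if r.channel == "signal"]
            standards = [r for r in recs if r.channel == "standard"]
            assigned = assign_peaks_to_residues(signal, fragment, tolerance=tolerance)
            normalized, _ = normalize_heights(
                assigned.heights, standards, sample_key=sample_key + (rep_id,)
            )
            rep_maps.append(normalized)
        profiles[sample_key] = aggregate_replicates(
            rep_maps, fragment, strand=strand, condition=condition,
            concentration=conc, min_replicates=min_replicates,
        )
    return profiles


def profile_to_tsv(profile: ResidueProfile) -> str:
    """Render a profile as TSV (position, strand, condition, concentration,
    mean_norm_height, n_replicates)."""
    lines = ["position\tstrand\tcondition\tconcentration\tmean_norm_height\tn_replicates"]
    for i in range(profile.insert_length):
        h = profile.mean_norm_height[i]
        lines.append(
            f"{i + 1}\t{profile.strand}\t{profile.condition}\t{profile.concentration}\t"
            f"{'' if np.isnan(h) else f'{h:.6g}'}\t{profile.n_replicates_observed[i]}"
        )
    return "\n".join(lines) + "\n"
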