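"""Input/output and the coordinate conventions used throughout the package.

All internal coordinates are 1-based inclusive on the forward strand of the
analyzed promoter region (position 1 = the most distal residue).  Reporting
relative to the transcription start site maps position ``p`` to
``p - (region_length + 1)``, so the most proximal residue is -1.  BED output
is the only 0-based half-open surface; the conversion happens exactly once,
in :func:`write_footprints_bed` / :func:`read_footprints_bed`.

Peak tables are delimited text (comma or tab) with a header; column names
for the called size and the peak height are resolved case-insensitively
through a small alias table because fragment-analysis software exports vary.
"""

from __future__ import annotations

import csv
import io as _stdio
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "FormatError",
    "ValidationError",
    "MetadataError",
    "PeakRecord",
    "LabeledFragment",
    "Footprint",
    "FootprintSet",
    "RegionPartition",
    "read_peak_table",
    "write_peak_table",
    "metadata_from_filename",
    "read_region_fasta",
    "write_footprints_bed",
    "read_footprints_bed",
    "tss_relative",
]

CONDITIONS = ("BSA", "FOXO")
CONCENTRATIONS = (600, 1200)
STRANDS = ("forward", "reverse")
CHANNELS = ("signal", "standard")

#: Vector residues shared by all forward-labeled fragments upstream of the
#: insert, and by all reverse-labeled fragments downstream of it.  A cleavage
#: product ending at insert residue 1 therefore runs 70 bp on the forward
#: read (69 vector + 1 insert).
DEFAULT_VECTOR_PREFIX = 69
DEFAULT_VECTOR_SUFFIX = 48

DEFAULT_REGION_LENGTH = 1300


class FormatError(ValueError):
    """A file does not follow the expected tabular/FASTA format."""


class ValidationError(ValueError):
    """Parsed values violate a domain invariant."""


class MetadataError(ValueError):
    """Sample metadata is missing, unknown or contradictory."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakRecord:
    """One called electrophoresis peak with its sample annotation.

    ``called_size`` is the fragment size in (fractional) base pairs assigned
    by the size-calling software; ``height`` is the fluorescence peak height
    in arbitrary units.
    """

    called_size: float
    height: float
    channel: str
    replicate_id: int
    condition: str
    concentration: int
    labeled_strand: str
    subfragment_id: str

    def __post_init__(self) -> None:
        if self.called_size <= 0:
            raise ValidationError(f"called_size must be > 0, got {self.called_size}")
        if self.height < 0:
            raise ValidationError(f"height must be >= 0, got {self.height}")
        if self.channel not in CHANNELS:
            raise ValidationError(f"unknown channel {self.channel!r}")
        if self.condition not in CONDITIONS:
            raise MetadataError(f"unknown condition {self.condition!r}")
        if self.concentration not in CONCENTRATIONS:
            raise ValidationError(
                f"concentration must be one of {CONCENTRATIONS}, got {self.concentration}"
            )
        if self.labeled_strand not in STRANDS:
            raise MetadataError(f"unknown labeled strand {self.labeled_strand!r}")

    @property
    def sample_key(self) -> tuple:
        """Key identifying one physical sample (all replicates pooled)."""
        return (self.subfragment_id, self.condition, self.concentration, self.labeled_strand)


@dataclass(frozen=True)
class LabeledFragment:
    """A subcloned insert with its vector context and region placement.

    ``region_offset`` is the 1-based coordinate of the insert's first residue
    within the full promoter region; ``tss_position`` anchors TSS-relative
    reporting and defaults to one past the proximal end of the region.
    """

    fragment_id: str
    insert_sequence: str
    vector_prefix_len: int = DEFAULT_VECTOR_PREFIX
    vector_suffix_len: int = DEFAULT_VECTOR_SUFFIX
    region_offset: int = 1
    tss_position: int | None = None

    def __post_init__(self) -> None:
        bad = [i for i, c in enumerate(self.insert_sequence) if c not in "ACGT"]
        if bad:
            raise ValidationError(
                f"{self.fragment_id}: non-ACGT symbol "
                f"{self.insert_sequence[bad[0]]!r} at position {bad[0] + 1}"
            )
        if self.region_offset < 1:
            raise ValidationError("region_offset must be >= 1")

    @property
    def length(self) -> int:
        return len(self.insert_sequence)

    @property
    def region_end(self) -> int:
        """1-based region coordinate of the insert's last residue."""
        return self.region_offset + self.length - 1

    def expected_size_forward(self, insert_pos: int) -> int:
        """Called size of the cleavage product ending at insert residue ``insert_pos``
        on a forward-labeled read."""
        return self.vector_prefix_len + insert_pos

    def expected_size_reverse(self, insert_pos: int) -> int:
        """Called size on a reverse-labeled read; the product runs from the
        insert's 3' end (forward-strand sense), so residue ``insert_pos`` is
        the ``length - insert_pos + 1``-th residue read."""
        return self.vector_suffix_len + (self.length - insert_pos + 1)


@dataclass(frozen=True)
class Footprint:
    """A protected interval on the region forward strand, 1-based inclusive."""

    name: str
    start: int
    end: int
    defining_strand: str = "both"
    protected_positions: Mapping[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValidationError(f"bad footprint interval [{self.start}, {self.end}]")
        if self.defining_strand not in ("forward", "reverse", "both"):
            raise ValidationError(f"bad defining_strand {self.defining_strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Footprint") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class FootprintSet:
    """Sorted, pairwise-disjoint footprints on one region."""

    region_name: str
    region_length: int
    footprints: tuple[Footprint, ...]

    def __post_init__(self) -> None:
        fps = tuple(sorted(self.footprints, key=lambda f: f.start))
        object.__setattr__(self, "footprints", fps)
        for a, b in zip(fps, fps[1:]):
            if a.end >= b.start:
                raise ValidationError(
                    f"footprints {a.name} [{a.start},{a.end}] and "
                    f"{b.name} [{b.start},{b.end}] overlap"
                )
        for f in fps:
            if f.end > self.region_length:
                raise ValidationError(
                    f"footprint {f.name} extends past region end {self.region_length}"
                )

    def __len__(self) -> int:
        return len(self.footprints)

    def __iter__(self):
        return iter(self.footprints)

    @property
    def total_bp(self) -> int:
        return sum(f.length for f in self.footprints)

    def containing(self, position: int) -> Footprint | None:
        for f in self.footprints:
            if f.start <= position <= f.end:
                return f
        return None


@dataclass(frozen=True)
class RegionPartition:
    """Cut coordinates splitting the region into consecutive fragments.

    ``boundaries`` are the last positions of every fragment except the final
    one; the default splits a 1300 bp region into 258, 392 and 650 bp
    segments (the distal / central / proximal density fragments, whose
    TSS-relative limits are -1042 and -650).
    """

    region_length: int = DEFAULT_REGION_LENGTH
    boundaries: tuple[int, ...] = (258, 650)

    def __post_init__(self) -> None:
        bounds = tuple(sorted(self.boundaries))
        object.__setattr__(self, "boundaries", bounds)
        if not bounds:
            raise ValidationError("partition needs at least one boundary")
        if bounds[0] < 1 or bounds[-1] >= self.region_length:
            raise ValidationError("boundaries must fall strictly inside the region")
        if len(set(bounds)) != len(bounds):
            raise ValidationError("duplicate partition boundary")

    @classmethod
    def from_lengths(cls, lengths: Sequence[int]) -> "RegionPartition":
        cuts, acc = [], 0
        for ln in lengths[:-1]:
            acc += ln
            cuts.append(acc)
        return cls(region_length=sum(lengths), boundaries=tuple(cuts))

    @property
    def fragment_lengths(self) -> tuple[int, ...]:
        edges = (0,) + self.boundaries + (self.region_length,)
        return tuple(b - a for a, b in zip(edges, edges[1:]))

    @property
    def intervals(self) -> tuple[tuple[int, int], ...]:
        """1-based inclusive (start, end) of every fragment."""
        edges = (0,) + self.boundaries + (self.region_length,)
        return tuple((a + 1, b) for a, b in zip(edges, edges[1:]))

    def fragment_index(self, position: int) -> int:
        """0-based index of the fragment containing ``position``."""
        if not 1 <= position <= self.region_length:
            raise ValidationError(f"position {position} outside region")
        for i, (a, b) in enumerate(self.intervals):
            if a <= position <= b:
                return i
        raise AssertionError("unreachable")


def tss_relative(position: int, region_length: int = DEFAULT_REGION_LENGTH) -> int:
    """Map a 1-based region coordinate to a TSS-relative coordinate.

    The TSS is taken to sit immediately downstream of the region's proximal
    end, so the proximal residue is -1 and the distal residue is
    ``-region_length``.
    """
    return position - (region_length + 1)


# --------------------------------------------------------------------------
# peak tables
# --------------------------------------------------------------------------

_SIZE_ALIASES = {"size", "called_size", "size_bp", "size (bp)"}
_HEIGHT_ALIASES = {"height", "peak_height", "height_rfu", "height (rfu)"}


def _resolve_columns(header: Sequence[str]) -> tuple[int, int]:
    lowered = [h.strip().lower() for h in header]
    size_idx = next((i for i, h in enumerate(lowered) if h in _SIZE_ALIASES), None)
    height_idx = next((i for i, h in enumerate(lowered) if h in _HEIGHT_ALIASES), None)
    if size_idx is None:
        raise FormatError(f"no size column found; header was {list(header)}")
    if height_idx is None:
        raise FormatError(f"no height column found; header was {list(header)}")
    return size_idx, height_idx


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def read_peak_table(
    path: str | Path | _stdio.StringIO,
    sample_metadata: Mapping[str, object],
) -> list[PeakRecord]:
    """Parse one delimited peak table into :class:`PeakRecord` objects.

    ``sample_metadata`` must supply ``condition``, ``concentration``,
    ``replicate_id``, ``labeled_strand``, ``channel`` and ``subfragment_id``
    (any subset may instead come from :func:`metadata_from_filename`).
    Malformed rows raise with their 1-based line number.
    """
    required = {"condition", "concentration", "replicate_id", "labeled_strand",
                "channel", "subfragment_id"}
    missing = required - set(sample_metadata)
    if missing:
        raise MetadataError(f"missing sample metadata keys: {sorted(missing)}")

    if isinstance(path, _stdio.StringIO):
        text = path.getvalue()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty peak table")
    delim = _sniff_delimiter(lines[0])
    rows = list(csv.reader(lines, delimiter=delim))
    size_idx, height_idx = _resolve_columns(rows[0])

    records: list[PeakRecord] = []
    for lineno, row in enumerate(rows[1:], start=2):
        try:
            size = float(row[size_idx])
            height = float(row[height_idx])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"line {lineno}: unparseable row {row!r}") from exc
        try:
            records.append(
                PeakRecord(
                    called_size=size,
                    height=height,
                    channel=str(sample_metadata["channel"]),
                    replicate_id=int(sample_metadata["replicate_id"]),  # type: ignore[arg-type]
                    condition=str(sample_metadata["condition"]),
                    concentration=int(sample_metadata["concentration"]),  # type: ignore[arg-type]
                    labeled_strand=str(sample_metadata["labeled_strand"]),
                    subfragment_id=str(sample_metadata["subfragment_id"]),
                )
            )
        except ValueError as exc:
            raise type(exc)(f"line {lineno}: {exc}") from exc
    return records


def write_peak_table(records: Iterable[PeakRecord], path: str | Path) -> None:
    """Write records as TSV with full per-row annotation (round-trippable
    via :func:`read_annotated_peak_table`)."""
    cols = ["called_size", "height", "channel", "replicate_id", "condition",
            "concentration", "labeled_strand", "subfragment_id"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(cols)
        for r in records:
            w.writerow([getattr(r, c) for c in cols])


def read_annotated_peak_table(path: str | Path) -> list[PeakRecord]:
    """Read a table written by :func:`write_peak_table` (annotation in-file)."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    return [
        PeakRecord(
            called_size=float(r["called_size"]),
            height=float(r["height"]),
            channel=r["channel"],
            replicate_id=int(r["replicate_id"]),
            condition=r["condition"],
            concentration=int(r["concentration"]),
            labeled_strand=r["labeled_strand"],
            subfragment_id=r["subfragment_id"],
        )
        for r in rows
    ]


_FILENAME_TOKENS = {
    "bsa": ("condition", "BSA"),
    "foxo": ("condition", "FOXO"),
    "dfoxo": ("condition", "FOXO"),
    "600": ("concentration", 600),
    "1200": ("concentration", 1200),
    "fwd": ("labeled_strand", "forward"),
    "forward": ("labeled_strand", "forward"),
    "rev": ("labeled_strand", "reverse"),
    "reverse": ("labeled_strand", "reverse"),
    "signal": ("channel", "signal"),
    "standard": ("channel", "standard"),
    "std": ("channel", "standard"),
}


def metadata_from_filename(name: str, overrides: Mapping[str, object] | None = None) -> dict:
    """Recover sample metadata from underscore/dash-separated filename tokens.

    Recognized tokens: condition (``BSA``/``FOXO``/``dFOXO``), concentration
    (``600``/``1200``), strand (``fwd``/``rev``...), channel
    (``signal``/``std``) and replicate (``rep<N>``); the first unrecognized
    token is taken as the subfragment id.  Explicit ``overrides`` (e.g. from a
    sidecar config) win on conflict.
    """
    meta: dict[str, object] = {}
    stem = Path(name).stem
    for token in re.split(r"[_\-.]", stem):
        low = token.lower()
        if low in _FILENAME_TOKENS:
            key, val = _FILENAME_TOKENS[low]
            meta.setdefault(key, val)
        elif m := re.fullmatch(r"rep(\d+)", low):
            meta.setdefault("replicate_id", int(m.group(1)))
        elif token and "subfragment_id" not in meta:
            meta["subfragment_id"] = token
    meta.setdefault("channel", "signal")
    if overrides:
        meta.update(overrides)
    return meta


# --------------------------------------------------------------------------
# sequences
# --------------------------------------------------------------------------

def read_region_fasta(
    path: str | Path,
    expected_length: int | None = None,
    **fragment_kwargs,
) -> dict[str, LabeledFragment]:
    """Read one or more region/subfragment sequences from FASTA.

    Sequences are upper-cased; any non-ACGT symbol (including ambiguity
    codes) is rejected with its position.  Returns fragments keyed by record
    id, preserving file order.
    """
    fragments: dict[str, LabeledFragment] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if expected_length is not None and len(seq) != expected_length:
            raise ValidationError(
                f"{rec.id}: length {len(seq)} != declared {expected_length}"
            )
        fragments[rec.id] = LabeledFragment(
            fragment_id=rec.id, insert_sequence=seq, **fragment_kwargs
        )
    if not fragments:
        raise FormatError(f"no FASTA records in {path}")
    return fragments


# --------------------------------------------------------------------------
# footprints as BED
# --------------------------------------------------------------------------

_STRAND_TO_BED = {"forward": "+", "reverse": "-", "both": "."}
_BED_TO_STRAND = {v: k for k, v in _STRAND_TO_BED.items()}


def write_footprints_bed(footprints: FootprintSet, path: str | Path | None = None) -> str:
    """Render a footprint set as BED6 text (0-based half-open), sorted by
    chromStart; optionally also write it to ``path``."""
    lines = []
    for f in footprints:
        lines.append(
            "\t".join([
                footprints.region_name,
                str(f.start - 1),
                str(f.end),
                f.name,
                "0",
                _STRAND_TO_BED[f.defining_strand],
            ])
        )
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text


def read_footprints_bed(
    source: str | Path, region_length: int = DEFAULT_REGION_LENGTH
) -> FootprintSet:
    """Read BED6 footprints back into 1-based inclusive coordinates.

    ``source`` may be a path or BED text itself.
    """
    text = source if isinstance(source, str) and "\t" in source else Path(source).read_text()
    footprints = []
    region_name = "region"
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        parts = ln.split("\t")
        if len(parts) < 6:
            raise FormatError(f"not a BED6 line: {ln!r}")
        region_name = parts[0]
        footprints.append(
            Footprint(
                name=parts[3],
                start=int(parts[1]) + 1,
                end=int(parts[2]),
                defining_strand=_BED_TO_STRAND[parts[5]],
            )
        )
    return FootprintSet(region_name=region_name, region_length=region_length,
                        footprints=tuple(footprints))
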