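"""Cross-species footprint projection through a supplied multiple alignment.

The alignment is consumed, never computed: gapped FASTA rows of the
orthologous promoter regions, optionally with a sidecar annotation marking
column intervals where one species' sequence is inverted relative to the
alignment orientation (a microinversion).  Footprint intervals are projected
position -> alignment column -> target coordinates, and two species'
footprints are called conserved homologs when their column spans overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO

from .io import Footprint, FootprintSet, ValidationError

__all__ = [
    "OrientationSegment",
    "AlignmentMap",
    "ProjectedInterval",
    "ConservationCall",
    "project_intervals",
    "classify_conservation",
    "conservation_matrix",
]

GAP_CHARS = "-."


@dataclass(frozen=True)
class OrientationSegment:
    """A 1-based inclusive alignment-column interval with its orientation
    for one species (``same`` or ``inverted`` relative to the alignment)."""

    col_start: int
    col_end: int
    orientation: str = "same"

    def __post_init__(self) -> None:
        if self.orientation not in ("same", "inverted"):
            raise ValidationError(f"bad orientation {self.orientation!r}")
        if not 1 <= self.col_start <= self.col_end:
            raise ValidationError("bad segment column interval")


class AlignmentMap:
    """Gapped rows plus per-species column <-> sequence coordinate maps.

    Sequence coordinates are assigned by walking columns left to right:
    within a ``same`` segment the non-gap columns of a species take
    ascending positions; within an ``inverted`` segment the block of
    positions they consume is assigned in descending order (the species'
    own coordinates run backwards through the inversion).  Rows are stored
    in alignment orientation.
    """

    def __init__(
        self,
        rows: Mapping[str, str],
        orientation_segments: Mapping[str, Sequence[OrientationSegment]] | None = None,
    ) -> None:
        if not rows:
            raise ValidationError("empty alignment")
        lengths = {len(r) for r in rows.values()}
        if len(lengths) != 1:
            raise ValidationError(f"alignment rows differ in length: {sorted(lengths)}")
        self.n_columns = lengths.pop()
        self.rows = {sp: row.upper() for sp, row in rows.items()}
        self.species = list(self.rows)

        segs = dict(orientation_segments or {})
        self.segments: dict[str, list[OrientationSegment]] = {}
        for sp in self.species:
            sp_segs = sorted(segs.get(sp, []), key=lambda s: s.col_start)
            for a, b in zip(sp_segs, sp_segs[1:]):
                if a.col_end >= b.col_start:
                    raise ValidationError(f"{sp}: overlapping orientation segments")
            # fill uncovered columns with 'same' segments
            full: list[OrientationSegment] = []
            cursor = 1
            for s in sp_segs:
                if s.col_end > self.n_columns:
                    raise ValidationError(f"{sp}: segment past alignment end")
                if s.col_start > cursor:
                    full.append(OrientationSegment(cursor, s.col_start - 1, "same"))
                full.append(s)
                cursor = s.col_end + 1
            if cursor <= self.n_columns:
                full.append(OrientationSegment(cursor, self.n_columns, "same"))
            self.segments[sp] = full

        self._pos_to_col: dict[str, dict[int, int]] = {}
        self._col_to_pos: dict[str, dict[int, int]] = {}
        for sp in self.species:
            p2c: dict[int, int] = {}
            c2p: dict[int, int] = {}
            consumed = 0
            row = self.rows[sp]
            for seg in self.segments[sp]:
                cols = [c for c in range(seg.col_start, seg.col_end + 1)
                        if row[c - 1] not in GAP_CHARS]
                k = len(cols)
                block = range(consumed + 1, consumed + k + 1)
                positions = list(block) if seg.orientation == "same" else list(block)[::-1]
                for col, pos in zip(cols, positions):
                    p2c[pos] = col
                    c2p[col] = pos
                consumed += k
            self._pos_to_col[sp] = p2c
            self._col_to_pos[sp] = c2p

    def sequence_length(self, species: str) -> int:
        return len(self._pos_to_col[self._check(species)])

    def _check(self, species: str) -> str:
        if species not in self.rows:
            raise ValidationError(f"species {species!r} not in alignment")
        return species

    def column_of(self, species: str, position: int) -> int:
        """Alignment column of a 1-based sequence position."""
        try:
            return self._pos_to_col[self._check(species)][position]
        except KeyError:
            raise ValidationError(f"{species}: position {position} outside sequence")

    def position_at(self, species: str, column: int) -> int | None:
        """1-based sequence position at a column, or None if gapped there."""
        return self._col_to_pos[self._check(species)].get(column)

    def orientation_at(self, species: str, column: int) -> str:
        for seg in self.segments[self._check(species)]:
            if seg.col_start <= column <= seg.col_end:
                return seg.orientation
        raise ValidationError(f"column {column} outside alignment")

    def column_span(self, species: str, start: int, end: int) -> set[int]:
        """Set of alignment columns occupied by a sequence interval."""
        return {self.column_of(species, p) for p in range(start, end + 1)}

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        orientation_segments: Mapping[str, Sequence[OrientationSegment]] | None = None,
    ) -> "AlignmentMap":
        rows = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(rows, orientation_segments)

    @classmethod
    def from_fasta_with_sidecar(cls, fasta_path: str | Path, yaml_path: str | Path) -> "AlignmentMap":
        """Sidecar YAML format: ``{species: [{columns: [c1, c2], orientation: inverted}]}``."""
        import yaml

        raw = yaml.safe_load(Path(yaml_path).read_text()) or {}
        segs = {
            sp: [OrientationSegment(int(d["columns"][0]), int(d["columns"][1]),
                                    d.get("orientation", "same"))
                 for d in entries]
            for sp, entries in raw.items()
        }
        return cls.from_fasta(fasta_path, segs)


@dataclass(frozen=True)
class ProjectedInterval:
    """One footprint projected onto a target species."""

    source_name: str
    source_start: int
    source_end: int
    target_start: int | None
    target_end: int | None
    orientation: str          # same | inverted
    fraction_mapped: float
    status: str               # projected | unalignable | split_part


@dataclass(frozen=True)
class ConservationCall:
    """Pairwise homology call between two species' footprints."""

    species_a: str
    footprint_a: str
    species_b: str
    footprint_b: str | None
    overlap_columns: int
    status: str               # conserved | species_specific

    def __post_init__(self) -> None:
        if self.status == "conserved" and self.footprint_b is None:
            raise ValidationError("conserved call needs a partner footprint")


def project_intervals(
    footprints: FootprintSet | Sequence[Footprint],
    alignment: AlignmentMap,
    species_a: str,
    species_b: str,
    min_mapped_fraction: float = 0.5,
) -> list[ProjectedInterval]:
    """Map each footprint of species A onto species B coordinates.

    Columns gapped in B are skipped; the projected interval is the [min, max]
    of the mapped positions.  A projection through a segment inverted in one
    species (but not both) is flagged ``inverted``.  A footprint whose
    columns cross an orientation breakpoint is split into per-orientation
    parts with a warning; one mapping fewer than ``min_mapped_fraction`` of
    its residues is reported ``unalignable``.
    """
    out: list[ProjectedInterval] = []
    for f in footprints:
        mapped: list[tuple[int, int, str]] = []  # (column, b_position, orientation key)
        total = f.length
        for pos in range(f.start, f.end + 1):
            col = alignment.column_of(species_a, pos)
            bpos = alignment.position_at(species_b, col)
            if bpos is None:
                continue
            ori_a = alignment.orientation_at(species_a, col)
            ori_b = alignment.orientation_at(species_b, col)
            rel = "inverted" if ori_a != ori_b else "same"
            mapped.append((col, bpos, rel))
        frac = len(mapped) / total
        if frac < min_mapped_fraction:
            out.append(ProjectedInterval(f.name, f.start, f.end, None, None,
                                         "same", frac, "unalignable"))
            continue
        orientations = {rel for _, _, rel in mapped}
        if len(orientations) == 1:
            bpositions = [b for _, b, _ in mapped]
            out.append(ProjectedInterval(
                f.name, f.start, f.end, min(bpositions), max(bpositions),
                orientations.pop(), frac, "projected",
            ))
        else:
            warnings.warn(
                f"footprint {f.name} spans an orientation breakpoint; split projection"
            )
            # split into maximal runs of constant relative orientation
            runs: list[list[tuple[int, int, str]]] = []
            for item in mapped:
                if runs and runs[-1][-1][2] == item[2]:
                    runs[-1].append(item)
                else:
                    runs.append([item])
            for run in runs:
                bpositions = [b for _, b, _ in run]
                out.append(ProjectedInterval(
                    f.name, f.start, f.end, min(bpositions), max(bpositions),
                    run[0][2], len(run) / total, "split_part",
                ))
    return out


def classify_conservation(
    footprint_sets: Mapping[str, FootprintSet],
    alignment: AlignmentMap,
    min_overlap: int = 1,
) -> list[ConservationCall]:
    """Pairwise homology calls for every footprint of every species pair.

    Two footprints are conserved homologs iff their alignment-column spans
    share at least ``min_overlap`` columns.  A footprint with no partner in
    the other species yields a ``species_specific`` call for that pair.
    Conservation is symmetric by construction.
    """
    spans: dict[tuple[str, str], set[int]] = {}
    for sp, fps in footprint_sets.items():
        for f in fps:
            spans[(sp, f.name)] = alignment.column_span(sp, f.start, f.end)

    calls: list[ConservationCall] = []
    species = sorted(footprint_sets)
    for a in species:
        for b in species:
            if a == b:
                continue
            for f in footprint_sets[a]:
                best_partner, best_ov = None, 0
                for g in footprint_sets[b]:
                    ov = len(spans[(a, f.name)] & spans[(b, g.name)])
                    if ov > best_ov:
                        best_partner, best_ov = g.name, ov
                if best_ov >= min_overlap:
                    calls.append(ConservationCall(a, f.name, b, best_partner,
                                                  best_ov, "conserved"))
                else:
                    calls.append(ConservationCall(a, f.name, b, None, 0,
                                                  "species_specific"))
    return calls


def conservation_matrix(
    calls: Sequence[ConservationCall],
    reference: str,
    clade: Sequence[str],
) -> dict[str, dict]:
    """Summarize, per reference-species footprint, which species of a clade
    conserve it, and whether it is clade-conserved (conserved pairwise with
    every other clade member)."""
    others = [sp for sp in clade if sp != reference]
    by_fp: dict[str, dict] = {}
    for c in calls:
        if c.species_a != reference or c.species_b not in others:
            continue
        entry = by_fp.setdefault(
            c.footprint_a, {"conserved_in": [], "partners": {}, "clade_conserved": False}
        )
        if c.status == "conserved":
            entry["conserved_in"].append(c.species_b)
            entry["partners"][c.species_b] = c.footprint_b
    for entry in by_fp.values():
        entry["clade_conserved"] = set(entry["conserved_in"]) == set(others)
    return by_fp
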