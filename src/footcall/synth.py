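"""Synthetic fragments and Peak Scanner-style peak tables with known truth.

The generator emulates the automated footprinting workflow end to end: a
random promoter-sized region carrying planted protein-binding sites (with
binding-element strings embedded), cut into overlapping 300-500 bp
subfragments inside vector context (69 bp leading / 48 bp trailing shared
vector residues), cleaved with per-position log-normal cut-rate
heterogeneity (DNase I cutting rates vary along a sequence), and read out
as per-replicate peak tables with multiplicative height noise, Bernoulli
peak dropout, Gaussian size-calling jitter and a separate size-standard
channel.  Protection at a planted site divides the protein-condition
cleavage rate by the site's protection factor on the strands it covers.

Defaults reproduce the study conditions the analysis assumes: a 1300 bp
region with 18 planted sites of 9-44 bp totalling 444 bp, four overlapping
subfragments, two protein concentrations against a BSA control, and five
replicates per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import (
    DEFAULT_VECTOR_PREFIX,
    DEFAULT_VECTOR_SUFFIX,
    FootprintSet,
    LabeledFragment,
    PeakRecord,
    ValidationError,
)

__all__ = [
    "PlantedSite",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_fragment",
    "simulate_peak_tables",
    "simulate_study",
    "match_footprints",
    "default_planted_sites",
]

#: Footprint lengths matching the observed study spread: 18 sites, each
#: 9-44 bp, totalling 444 bp.
_DEFAULT_SITE_LENGTHS = (9, 11, 13, 15, 17, 19, 21, 23, 24, 25, 26, 27, 29, 31, 33, 35, 42, 44)
_DEFAULT_EMBED = ("TTGTTT", "TTATTT")


@dataclass(frozen=True)
class PlantedSite:
    """One protein-bound site to plant: interval, protection strength, the
    strands on which cleavage is suppressed, and an optional element string
    written into the sequence at the site start."""

    start: int
    length: int
    protection_factor: float = 4.0
    strand_visibility: str = "both"
    motif: str | None = None

    def __post_init__(self) -> None:
        if self.length < 9:
            raise ValidationError("planted sites must be at least 9 bp")
        if self.protection_factor < 1:
            raise ValidationError("protection_factor must be >= 1")
        if self.strand_visibility not in ("forward", "reverse", "both"):
            raise ValidationError(f"bad strand_visibility {self.strand_visibility!r}")
        if self.motif is not None:
            if any(c not in "ACGT" for c in self.motif.upper()):
                raise ValidationError("embedded motif must be a concrete ACGT string")
            if len(self.motif) > self.length:
                raise ValidationError("embedded motif longer than its site")

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end

    def protects_strand(self, strand: str) -> bool:
        return self.strand_visibility in ("both", strand)


def default_planted_sites(
    region_length: int = 1300,
    protection_factor: float = 4.0,
    first_start: int = 40,
    spacing: int = 45,
) -> tuple[PlantedSite, ...]:
    """The default study-conditions site plan: 18 sites (9-44 bp, 444 bp
    total) evenly spread along the region, most carrying a DBE core string,
    three carrying no element (footprints without recognizable motifs occur
    in real data)."""
    sites = []
    cursor = first_start
    for idx, length in enumerate(_DEFAULT_SITE_LENGTHS):
        motif = None if idx in (10, 11, 12) else _DEFAULT_EMBED[idx % 2]
        sites.append(PlantedSite(start=cursor, length=length,
                                 protection_factor=protection_factor, motif=motif))
        cursor += length + spacing
    if sites[-1].end > region_length:
        raise ValidationError("default site plan does not fit the region")
    return tuple(sites)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    region_length: int = 1300
    subfragments: tuple[tuple[int, int], ...] = ((1, 400), (351, 400), (701, 350), (1001, 300))
    sites: tuple[PlantedSite, ...] = field(default_factory=default_planted_sites)
    cut_rate_sd: float = 0.5        # log-normal sigma of per-position cleavage propensity
    replicate_cv: float = 0.10      # multiplicative height noise CV per replicate
    size_jitter_sd: float = 0.08    # bp, Gaussian size-calling jitter
    dropout_p: float = 0.05         # per-peak Bernoulli dropout probability
    replicates: int = 5
    base_height: float = 500.0
    n_standard_peaks: int = 12
    standard_size_range: tuple[float, float] = (60.0, 600.0)
    standard_height: float = 1000.0
    vector_prefix_len: int = DEFAULT_VECTOR_PREFIX
    vector_suffix_len: int = DEFAULT_VECTOR_SUFFIX
    max_gap: int = 4                # caller gap parameter the spacing invariant refers to
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.dropout_p,):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must be in [0, 1]")
        if self.replicate_cv < 0 or self.size_jitter_sd < 0 or self.cut_rate_sd < 0:
            raise ValidationError("noise parameters must be >= 0")
        for start, length in self.subfragments:
            if not 300 <= length <= 500:
                raise ValidationError(f"subfragment length {length} outside 300-500 bp")
            if start < 1 or start + length - 1 > self.region_length:
                raise ValidationError("subfragment outside region")
        ordered = sorted(self.sites, key=lambda s: s.start)
        for a, b in zip(ordered, ordered[1:]):
            gap = b.start - a.end - 1
            if gap < 2 * self.max_gap:
                raise ValidationError(
                    f"planted sites [{a.start},{a.end}] and [{b.start},{b.end}] "
                    f"are spaced {gap} bp apart; need >= {2 * self.max_gap}"
                )
        for s in self.sites:
            if s.end > self.region_length:
                raise ValidationError("planted site outside region")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one simulated region."""

    footprints: tuple[tuple[int, int], ...]            # 1-based inclusive intervals
    motifs: tuple[tuple[int, int, str], ...]           # (start, end, embedded string)
    cut_rates: Mapping[str, np.ndarray]                # per-strand cleavage propensity
    protection: Mapping[str, np.ndarray]               # per-strand protection factor >= 1


def simulate_fragment(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[str, SyntheticTruth]:
    """Draw the region sequence and its ground truth.

    Background is uniform random ACGT; each planted site's element string
    (when present) overwrites the sequence at the site start.  Per-position,
    per-strand cleavage propensities are log-normal with sigma
    ``cut_rate_sd``; the protein condition divides them by the site's
    protection factor on the strands the site covers.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    L = config.region_length
    seq = list(rng.choice(list("ACGT"), size=L))
    motifs = []
    for site in config.sites:
        if site.motif:
            m = site.motif.upper()
            seq[site.start - 1: site.start - 1 + len(m)] = list(m)
            motifs.append((site.start, site.start + len(m) - 1, m))
    cut_rates = {
        s: np.exp(rng.normal(0.0, config.cut_rate_sd, size=L)) for s in ("forward", "reverse")
    }
    protection = {s: np.ones(L) for s in ("forward", "reverse")}
    for site in config.sites:
        for s in ("forward", "reverse"):
            if site.protects_strand(s):
                protection[s][site.start - 1: site.end] = site.protection_factor
    truth = SyntheticTruth(
        footprints=tuple((s.start, s.end) for s in sorted(config.sites, key=lambda x: x.start)),
        motifs=tuple(motifs),
        cut_rates=cut_rates,
        protection=protection,
    )
    return "".join(seq), truth


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=size)


def simulate_peak_tables(
    sequence: str,
    truth: SyntheticTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[PeakRecord], dict[str, LabeledFragment]]:
    """Generate per-sample peak tables for every subfragment.

    Samples are {BSA, FOXO} x {600, 1200 nM} x {forward, reverse labeling}
    per subfragment, ``replicates`` runs each.  Expected BSA height at a
    residue is ``base_height * cut_rate``; the protein-condition expectation
    divides by the local protection factor.  Per replicate each peak gets
    multiplicative log-normal noise, may drop out, and its called size
    jitters around the exact product length; the size-standard channel gets
    its own independently-noised peaks.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    fragments: dict[str, LabeledFragment] = {}
    records: list[PeakRecord] = []
    std_sizes = np.linspace(*config.standard_size_range, config.n_standard_peaks)

    for start, length in config.subfragments:
        frag_id = f"sub{start}"
        fragments[frag_id] = LabeledFragment(
            fragment_id=frag_id,
            insert_sequence=sequence[start - 1: start - 1 + length],
            vector_prefix_len=config.vector_prefix_len,
            vector_suffix_len=config.vector_suffix_len,
            region_offset=start,
        )
        frag = fragments[frag_id]
        for condition in ("BSA", "FOXO"):
            for conc in (600, 1200):
                for strand in ("forward", "reverse"):
                    rates = truth.cut_rates[strand][start - 1: start - 1 + length]
                    expected = config.base_height * rates
                    if condition == "FOXO":
                        expected = expected / truth.protection[strand][start - 1: start - 1 + length]
                    for rep in range(1, config.replicates + 1):
                        noise = _lognormal_noise(rng, config.replicate_cv, length)
                        drop = rng.random(length) < config.dropout_p
                        jitter = rng.normal(0.0, config.size_jitter_sd, size=length)
                        for i in range(length):
                            if drop[i]:
                                continue
                            insert_pos = i + 1
                            size = (
                                frag.expected_size_forward(insert_pos)
                                if strand == "forward"
                                else frag.expected_size_reverse(insert_pos)
                            ) + jitter[i]
                            records.append(PeakRecord(
                                called_size=float(size),
                                height=float(expected[i] * noise[i]),
                                channel="signal",
                                replicate_id=rep,
                                condition=condition,
                                concentration=conc,
                                labeled_strand=strand,
                                subfragment_id=frag_id,
                            ))
                        std_noise = _lognormal_noise(rng, config.replicate_cv,
                                                     config.n_standard_peaks)
                        for k in range(config.n_standard_peaks):
                            records.append(PeakRecord(
                                called_size=float(std_sizes[k]),
                                height=float(config.standard_height * std_noise[k]),
                                channel="standard",
                                replicate_id=rep,
                                condition=condition,
                                concentration=conc,
                                labeled_strand=strand,
                                subfragment_id=frag_id,
                            ))
    return records, fragments


def simulate_study(
    config: SimulationConfig,
) -> tuple[str, SyntheticTruth, list[PeakRecord], dict[str, LabeledFragment]]:
    """Convenience wrapper: sequence + truth + peak tables in one call,
    fully determined by ``config.seed``."""
    ss = np.random.SeedSequence(config.seed).spawn(2)
    sequence, truth = simulate_fragment(config, np.random.default_rng(ss[0]))
    records, fragments = simulate_peak_tables(sequence, truth, config,
                                              np.random.default_rng(ss[1]))
    return sequence, truth, records, fragments


def match_footprints(
    called: FootprintSet,
    truth_intervals: Sequence[tuple[int, int]],
    boundary_tol: int = 2,
) -> dict:
    """Score called footprints against planted intervals.

    A planted interval is *recovered* when some called footprint overlaps it
    and both boundaries agree within ``boundary_tol`` bp; called footprints
    overlapping no planted interval are false footprints.
    """
    recovered = 0
    boundary_errors = []
    for (ts, te) in truth_intervals:
        hit = None
        for f in called:
            if f.start <= te and ts <= f.end:
                hit = f
                break
        if hit is not None:
            err = max(abs(hit.start - ts), abs(hit.end - te))
            boundary_errors.append(err)
            if err <= boundary_tol:
                recovered += 1
    false_fp = sum(
        1 for f in called
        if not any(f.start <= te and ts <= f.end for ts, te in truth_intervals)
    )
    return {
        "n_true": len(truth_intervals),
        "n_called": len(called),
        "n_recovered": recovered,
        "recovery_rate": recovered / len(truth_intervals) if truth_intervals else float("nan"),
        "n_false": false_fp,
        "max_boundary_error": max(boundary_errors) if boundary_errors else None,
    }
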