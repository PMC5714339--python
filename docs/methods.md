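# Methods

## Assay model

`footcall` models automated DNase I footprinting read out on a capillary
DNA analyzer. A promoter region (default 1300 bp) is covered by
overlapping 300–500 bp subfragments cloned in a common vector; each
subfragment is amplified with one 5′-FAM-labeled primer so that cleavage
products share either the 69 leading (forward labeling) or the 48 trailing
(reverse labeling) vector residues. The called size of a product therefore
encodes the cleaved residue: `size = 69 + i` for insert residue `i` on a
forward read, `size = 48 + j` for the residue `j` positions from the
insert 3′ end on a reverse read. Cleavage intensity at a residue is the
height of its peak; DNase I cutting rates vary along any sequence for
structural reasons, so absolute heights are uninformative and all
inference is on BSA-control versus protein-condition *ratios* at the same
residue.

Assumptions: size calling is accurate to well under half a base at these
product lengths; the size-standard channel is a valid per-run scale
reference; protection is multiplicative (bound protein divides the local
cleavage rate); the two protein concentrations probe the same sites.

## Coordinates

All internal coordinates are 1-based inclusive on the region forward
strand, position 1 being the most distal residue. TSS-relative reporting
maps `p → p − (region_length + 1)`; the exact TSS coordinate is not part
of the data, so the region is treated as self-contained with the TSS
immediately downstream of its proximal end. BED is the only 0-based
half-open surface and the conversion lives in one function pair.
Footprints are named `<species-initial><k>` with `k` counting from the
proximal end, so reading the region 5′→3′ gives `M18 … M1` for an
18-footprint melanogaster-style set.

## Peak mapping and normalization

Peaks snap to the nearest integer residue within ±0.5 bp (configurable);
two peaks snapping to one residue keep the taller (shoulder artifacts),
logged. Heights are divided by the mean height of *all* size-standard
peaks of the same run — a size-restricted subset would also be defensible,
but the plain mean is the simplest scale estimate and normalized profiles
are exactly invariant to rescaling a run. Replicates (default 5, ≥ 3
required) are averaged per residue over the replicates in which the peak
was observed: a missing peak is *not* a zero, because absence may be
dropout or true protection; positions seen in fewer than 2 replicates are
flagged low-support. Overlapping subfragments are merged onto region
coordinates by a replicate-weighted mean.

## Protection calling

Per strand and concentration, the ratio track is BSA mean height over
protein mean height. A residue with control signal but no protein signal
in any replicate is completely protected; to avoid infinities its ratio is
imputed against `epsilon = 5 %` of the protein sample's median normalized
height and capped at 50. Residues with no control signal carry no ratio.

Caller parameters (all exposed in `CallerParams` and echoed in run
output):

| parameter | default | rationale |
|---|---|---|
| `ratio_threshold` | 2.0 (inclusive) | a twofold drop in cleavage at either concentration defines protection; ratio 1 means no protection |
| `max_gap` | 4 bp | "clustered" needs an operational gap; 4 bp bridges single noisy residues without fusing adjacent sites, and doubles as the strand-offset limit |
| `min_protected_in_cluster` | 3 | two isolated threshold crossings are noise |
| `min_footprint_length` | 9 bp | the shortest credible footprint; matches the smallest length the defaults are designed to represent |
| `epsilon_fraction` / `ratio_cap` | 0.05 / 50 | complete-protection imputation, above |

Clustering is greedy left-to-right. Strand reconciliation applies two
rules transitively: overlapping forward/reverse footprints take the extent
of the longer strand footprint (equal lengths → union, a case the rules
otherwise leave open); footprints offset by ≤ `max_gap` merge from the
forward strand's 5′ protected residue (lowest coordinate) to the reverse
strand's 5′ protected residue (highest coordinate). In the degenerate
geometry where the reverse footprint lies wholly upstream of the forward
one, those limits would invert, and the union is used instead. Residual
overlaps produced by chained merges are unioned.

The heterogeneity test is a 2×2 χ² (1 df) of
{protected, unprotected} × {inside, outside footprints}, without Yates
correction since counts are in the hundreds; when an expected cell drops
below 1 a Fisher exact p-value replaces the χ² p (flagged in the result).
Whether protection should be thresholded per concentration (as here) or on
pooled concentrations is a genuine design fork; the either-concentration
rule is the more faithful reading of the calling criterion and is what the
tests pin down.

## Motif statistics

Scanning is exact degenerate matching (no PWM scoring, no background
model): every offset on the forward strand and every offset of the
reverse-complemented pattern, all self-overlapping matches reported, in
forward-strand coordinates. The registered classes are DBE cores
(`TTGTTT`, `TTATTT`), near-DBE single-mismatch variants (`TTGTTG`,
`TTTTTT`), the pan-FKH core `TRTTK`, and the derived consensus
`TTDTTKNB`; each class can be switched off. Near-DBE occurrences count
with DBE in density statistics by default (switchable), since they are
strongly protected elements of the same family. FKH hits overlapping a
DBE-class span are reported but flagged subsumed and excluded from counts,
so FKH is counted only outside DBE elements.

Density statistics use the distal 258 bp / central 392 bp / proximal
650 bp partition (TSS-relative limits −1042 and −650). The counting unit
is the distinct matched span — a span matched on both strands counts once
— and a span belongs to the fragment containing its start (boundary
straddling must be deterministic; starts are unambiguous). Densities are
rounded to one decimal, percentages to integers, matching the reporting
convention the counts invert from.

Consensus derivation computes per-column base frequencies over the
detected fixed-length sites; the symbol is the unique IUPAC code of the
base set reaching `freq_threshold` (default 0.10 — low enough that a base
seen in ~1 of 10 sites still enters the code; no published cutoff exists).
The two 3′ positions of the derived FOXO consensus are its least
constrained — near the 0.10 threshold they flip between `N` and `B`-type
codes, and both spellings circulate — so the threshold is a parameter and
the position frequency matrix is always returned alongside the string.

## Cross-species projection

The multiple alignment is an input (gapped FASTA), never computed.
Orientation segments — column intervals where one species' sequence is
inverted relative to the alignment, as in a microinversion — come from a
sidecar annotation, not auto-detection. Within an inverted segment the
species' coordinate map runs strictly decreasing. Projection walks
footprint positions to columns to target coordinates, skipping columns
gapped in the target; a footprint mapping less than 50 % of its residues
is unalignable, and one spanning an orientation breakpoint is split per
orientation run with a warning. Two footprints are conserved homologs iff
their column spans share ≥ 1 column (`min_overlap`, configurable — no
published overlap rule exists); clade conservation requires a pairwise
partner in every clade member. Motif agreement inside conserved footprints
is not required for the position call and can be assessed separately from
the hit tables.

## Synthetic data

The generator emulates: uniform random ACGT background with concrete
element strings written at planted sites; per-position, per-strand
log-normal cleavage propensity (σ = 0.5) for sequence-dependent cutting
variability; multiplicative protection (factor 4 by default) on the
strands a site covers; five replicates with multiplicative log-normal
height noise (CV 10 %), height-independent Bernoulli dropout (5 %;
height-dependent dropout exists as a stress option), Gaussian size jitter
(σ = 0.08 bp); and a 12-peak size-standard channel per run. The default
site plan is the study-scale landscape the caller is meant to resolve:
18 sites of 9–44 bp totalling 444 bp on a 1300 bp region covered by four
overlapping subfragments, three sites deliberately carrying no recognizable
element. Everything derives from one integer seed.

Not emulated: sequence-specific DNase bias beyond random heterogeneity,
electrophoretic mobility artifacts, pull-up between dye channels,
concentration-dependent occupancy (both protein concentrations see the
same protection factor), and partial-occupancy intermediate ratios.
Passing recovery tests therefore demonstrates correctness of the calling
logic under the stated noise model, not performance on traces with
baseline drift or strongly height-dependent dropout.

## Problem sizes and numerics

The test suite and the acceptance script run the full pipeline on the
1300 bp region (≈ 57 000 peaks per simulation) and use 50 seeded
simulations for recovery statistics, 100 random 1 kb sequences for
scanner/oracle agreement and 20 random tables for the χ² oracle — sizes at
which the stochastic checks are stable from seed to seed. Ties in peak
snapping go to the taller peak; equal-length strand overlaps take the
union; replicate order never affects results; identical inputs give
bit-identical footprints.

## Limitations

In vitro protection does not imply in vivo occupancy, and ratio magnitude
is not an affinity estimate. Real peak tables may carry dialects beyond
the comma/tab + alias handling implemented. The caller's gap and
minimum-cluster defaults are operational choices where the underlying
criteria are qualitative; they are parameters precisely because other
reasonable settings shift footprint boundaries by a few bp.
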