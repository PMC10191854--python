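"""Validation, quantification and classification of somatic mobile-element insertions.

A somatic L1 retrotransposition (soL1R) call is supported by discordant /
clipped read pairs at the target breakpoint.  Two canonical hallmarks of
target-primed reverse transcription — a poly-A tail and a target site
duplication (TSD) — are required for validation, together with a minimum
fraction of supporting read pairs.  Validated events are classified by the
content of the inserted segment:

* ``solo``      — L1 (usually 3') sequence only;
* ``partnered`` — L1 sequence plus a unique downstream segment transduced
  from the source locus;
* ``orphan``    — the unique downstream segment only;
* ``unresolved``— none of the above patterns.

Transduced unique segments act as a barcode: a source element whose 3' end
lies within 15 kb upstream (in the source-strand sense) of the segment is
attributed as the origin.

This module also applies the SNV/indel panel filters used upstream of
phylogeny reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

INSERTION_CLASSES = ("solo", "partnered", "orphan", "unresolved")

#: maximum distance (bp) from a source 3' end to a transduced segment
TRANSDUCTION_WINDOW = 15_000

#: minimum fraction of supporting read pairs among breakpoint-informative pairs
MIN_SUPPORT_FRACTION = 0.10


@dataclass
class SegmentMapping:
    """Mapping of one end of an inserted segment back to a template."""

    contig: str
    start: int  # 0-based half-open internally
    end: int
    strand: str  # '+' or '-'
    #: True when the template is L1 (or another mobile-element) consensus/repeat
    is_repeat: bool = True


@dataclass
class SoL1REvent:
    """One somatic mobile-element insertion call."""

    sample_id: str
    chrom: str
    target_pos: int  # 1-based breakpoint in external tables
    strand: str = "+"
    insert_5p_map: Optional[SegmentMapping] = None
    insert_3p_map: Optional[SegmentMapping] = None
    polyA_len: int = 0
    tsd_len: int = 0
    supporting_pairs: int = 0
    reference_pairs: int = 0
    insertion_class: str = "unresolved"
    inverted: bool = False
    twin_priming: bool = False
    foldback: bool = False
    extra_synthesis_len: int = 0
    source_id: Optional[str] = None
    #: unique (non-repeat) transduced segment, when present
    unique_segment: Optional[SegmentMapping] = None

    def __post_init__(self):
        if self.supporting_pairs < 0 or self.reference_pairs < 0:
            raise ValueError("read-pair counts must be non-negative")
        if self.tsd_len < 0:
            raise ValueError("tsd_len must be non-negative")


@dataclass
class VariantCall:
    """A somatic SNV/indel with per-sample evidence across one individual's clones."""

    chrom: str
    pos: int
    ref: str
    alt: str
    #: sample -> (depth, variant reads); VAF derived as var/depth
    support: dict[str, tuple[int, int]] = field(default_factory=dict)
    panel_vaf: float = 0.0
    clip_indel_proportion: float = 0.0
    variant_read_mismatches: int = 0
    #: fraction of other clones showing low-level error reads (optional rule)
    error_read_fraction: float = 0.0

    def vaf(self, sample: str) -> float:
        depth, var = self.support[sample]
        if var > depth:
            raise ValueError("depth must be >= variant reads")
        return var / depth if depth > 0 else 0.0


# ---------------------------------------------------------------------------
# SNV/indel filtering
# ---------------------------------------------------------------------------

def filter_variants(
    calls: Sequence[VariantCall],
    *,
    panel_vaf_max: float = 0.01,
    clip_indel_max: float = 0.70,
    mismatch_max: int = 3,
    min_depth: int = 5,
    min_max_vaf: float = 0.25,
    error_read_fraction_max: Optional[float] = None,
) -> tuple[list[VariantCall], list[tuple[VariantCall, str]]]:
    """Apply the high-confidence variant filters.

    A call is retained iff its panel-of-normals VAF is below 1%, the
    proportion of indel/clipped reads at the locus is at most 70%, variant
    reads carry fewer than 3 mismatched bases, depth is at least 5 reads in
    every sample of the individual, and VAF reaches at least 0.25 in at
    least one sample.  The optional ``error_read_fraction_max`` activates a
    recurrent-error filter across clones (off by default).

    Returns ``(retained, rejected)`` where each rejected entry carries the
    first rule it violated.  Order-independent: rules are evaluated per call.
    """
    retained: list[VariantCall] = []
    rejected: list[tuple[VariantCall, str]] = []
    for call in calls:
        rule = _first_violated_rule(
            call,
            panel_vaf_max=panel_vaf_max,
            clip_indel_max=clip_indel_max,
            mismatch_max=mismatch_max,
            min_depth=min_depth,
            min_max_vaf=min_max_vaf,
            error_read_fraction_max=error_read_fraction_max,
        )
        if rule is None:
            retained.append(call)
        else:
            rejected.append((call, rule))
    return retained, rejected


def _first_violated_rule(
    call: VariantCall,
    *,
    panel_vaf_max: float,
    clip_indel_max: float,
    mismatch_max: int,
    min_depth: int,
    min_max_vaf: float,
    error_read_fraction_max: Optional[float],
) -> Optional[str]:
    if not call.support or any(d is None for d, _ in call.support.values()):
        return "insufficient_coverage_data"
    if call.panel_vaf >= panel_vaf_max:
        return "panel_of_normals"
    if call.clip_indel_proportion > clip_indel_max:
        return "clipping_or_indel_proportion"
    if call.variant_read_mismatches >= mismatch_max:
        return "variant_read_mismatches"
    if any(depth < min_depth for depth, _ in call.support.values()):
        return "min_depth_all_samples"
    if max(call.vaf(s) for s in call.support) < min_max_vaf:
        return "max_vaf_below_threshold"
    if (
        error_read_fraction_max is not None
        and call.error_read_fraction > error_read_fraction_max
    ):
        return "recurrent_error_reads"
    return None


# ---------------------------------------------------------------------------
# Insertion validation and quantification
# ---------------------------------------------------------------------------

def validate_insertion(
    event: SoL1REvent,
    *,
    min_support_fraction: float = MIN_SUPPORT_FRACTION,
    allow_tsd_absent: bool = False,
) -> tuple[bool, list[str]]:
    """Check the retrotransposition hallmarks on one insertion call.

    Passes iff a poly-A tail is present, a TSD is present (unless the
    blunt-insertion exception is enabled), and supporting pairs make up at
    least ``min_support_fraction`` of total read pairs.
    """
    reasons: list[str] = []
    if event.polyA_len <= 0:
        reasons.append("no_polyA")
    if event.tsd_len <= 0 and not allow_tsd_absent:
        reasons.append("no_TSD")
    total = event.supporting_pairs + event.reference_pairs
    if total == 0:
        reasons.append("no_informative_pairs")
    elif event.supporting_pairs < min_support_fraction * total:
        reasons.append("low_supporting_fraction")
    return (not reasons), reasons


def insertion_vaf(s: int, r: int) -> float:
    """Variant allele fraction of an insertion from read-pair counts.

    ``s`` supporting and ``r`` reference read pairs spanning the breakpoint
    (informative pairs).  Because an insertion presents two breakpoints —
    so reference pairs are sampled at both ends of the insert — reference
    pairs are counted twice in the denominator:  VAF = s / (s + 2 r).
    """
    if s < 0 or r < 0:
        raise ValueError("read-pair counts must be non-negative")
    if s + r == 0:
        raise ValueError("undefined VAF: no informative read pairs")
    return s / (s + 2 * r)


def cell_fraction(vaf: float, *, purity: float = 1.0, ploidy: int = 2) -> float:
    """Fraction of cells carrying a heterozygous autosomal insertion (capped at 1)."""
    if not 0 <= vaf <= 1:
        raise ValueError("VAF must lie in [0, 1]")
    if purity <= 0:
        raise ValueError("purity must be positive")
    return min(1.0, ploidy * vaf / purity)


def call_clonal_in_cancer(
    cancer_events: Iterable[SoL1REvent],
    reference_cutoff: Optional[float] = None,
    *,
    shared_normal_cell_fractions: Optional[Sequence[float]] = None,
    purity: float = 1.0,
) -> list[tuple[SoL1REvent, bool]]:
    """Flag clonal insertions in a cancer using a cutoff from shared normal events.

    The cutoff is the minimum cell fraction among validated soL1Rs shared by
    multiple normal clones (those are bona fide somatic events); an event is
    clonal iff its purity-adjusted cell fraction reaches the cutoff.
    """
    if reference_cutoff is None:
        if not shared_normal_cell_fractions:
            raise ValueError(
                "no shared normal events available: reference_cutoff must be supplied"
            )
        reference_cutoff = min(shared_normal_cell_fractions)
    flags = []
    for event in cancer_events:
        vaf = insertion_vaf(event.supporting_pairs, event.reference_pairs)
        cf = cell_fraction(vaf, purity=purity)
        flags.append((event, cf >= reference_cutoff))
    return flags


# ---------------------------------------------------------------------------
# Classification and source attribution
# ---------------------------------------------------------------------------

@dataclass
class SourceRecord:
    """Registry row used for 3' transduction attribution."""

    source_id: str
    chrom: str
    start: int  # 0-based half-open locus of the full-length element
    end: int
    strand: str

    @property
    def three_prime_end(self) -> int:
        return self.end if self.strand == "+" else self.start


def _downstream_distance(source: SourceRecord, segment: SegmentMapping) -> Optional[float]:
    """Distance from the source 3' end to the segment, in the source-strand sense.

    Transduced sequence lies 3' of (downstream from) the source; returns None
    when the segment is on the wrong contig or upstream of the 3' end.
    """
    if segment.contig != source.chrom:
        return None
    if source.strand == "+":
        dist = segment.start - source.three_prime_end
    else:
        dist = source.three_prime_end - segment.end
    return float(dist) if dist >= 0 else None


def attribute_source(
    segment: SegmentMapping,
    registry: Sequence[SourceRecord],
    *,
    window: int = TRANSDUCTION_WINDOW,
) -> tuple[Optional[str], list[str]]:
    """Attribute a unique transduced segment to the nearest in-window source.

    Returns ``(source_id or None, warnings)``; ties on distance are broken by
    the nearest 3' end and logged as ambiguous.
    """
    warnings: list[str] = []
    if segment.is_repeat:
        return None, ["segment_in_repeat: attribution refused"]
    candidates = []
    for source in registry:
        dist = _downstream_distance(source, segment)
        if dist is not None and dist <= window:
            candidates.append((dist, source.source_id))
    if not candidates:
        return None, ["no_source_within_window"]
    candidates.sort()
    if len(candidates) > 1:
        warnings.append(
            "ambiguous_attribution: " + ",".join(sid for _, sid in candidates)
        )
    return candidates[0][1], warnings


def classify_insertion(
    event: SoL1REvent,
    registry: Sequence[SourceRecord],
    *,
    window: int = TRANSDUCTION_WINDOW,
) -> SoL1REvent:
    """Assign the insertion class and, for transductions, the source element.

    Mutates and returns ``event``: sets ``insertion_class``, ``inverted`` and
    ``source_id``.  The class is a partition — every event receives exactly
    one label.
    """
    ends = [m for m in (event.insert_5p_map, event.insert_3p_map) if m is not None]
    repeat_ends = [m for m in ends if m.is_repeat]
    unique_ends = [m for m in ends if not m.is_repeat]

    # inversion: the two insert ends map on opposite strands of their template
    if event.insert_5p_map and event.insert_3p_map:
        a, b = event.insert_5p_map, event.insert_3p_map
        if a.contig == b.contig and a.strand != b.strand:
            event.inverted = True

    unique = event.unique_segment or (unique_ends[0] if unique_ends else None)

    if repeat_ends and unique is None:
        event.insertion_class = "solo"
        event.source_id = None
    elif repeat_ends and unique is not None:
        event.insertion_class = "partnered"
        event.source_id, _ = attribute_source(unique, registry, window=window)
    elif unique is not None:
        event.insertion_class = "orphan"
        event.source_id, _ = attribute_source(unique, registry, window=window)
    else:
        event.insertion_class = "unresolved"
        event.source_id = None
    return event


def annotate_mechanism(
    event: SoL1REvent,
    *,
    insert_length: Optional[int] = None,
    template_matched_length: Optional[int] = None,
) -> SoL1REvent:
    """Flag breakpoint mechanisms on a validated event.

    ``twin_priming`` — an inversion inside the retrotransposed body (the two
    insert ends map on opposite strands of the same template), the signature
    of two primed cDNA strands meeting head-to-head.

    ``foldback`` — a short inverted duplication of the 5' target flank: the
    5' insert end maps back to the *target* chromosome on the opposite strand
    immediately upstream of the breakpoint.

    ``extra_synthesis_len`` — inserted bases matching neither the L1 /
    transduced template nor the target flank, attributed to untemplated DNA
    synthesis during resolution; computed by exact length accounting when
    ``insert_length`` and ``template_matched_length`` are given.
    """
    a, b = event.insert_5p_map, event.insert_3p_map
    if a is not None and b is not None and a.contig == b.contig and a.strand != b.strand:
        if a.contig == event.chrom and not a.is_repeat:
            event.foldback = True
        else:
            event.twin_priming = True
            event.inverted = True
    if insert_length is not None and template_matched_length is not None:
        if template_matched_length > insert_length:
            raise ValueError("template-matched length exceeds insert length")
        event.extra_synthesis_len = insert_length - template_matched_length
    return event


def class_fractions(events: Iterable[SoL1REvent]) -> dict[str, float]:
    """Fraction of each insertion class among classified events."""
    counts = {c: 0 for c in INSERTION_CLASSES}
    total = 0
    for event in events:
        counts[event.insertion_class] += 1
        total += 1
    if total == 0:
        return {c: math.nan for c in INSERTION_CLASSES}
    return {c: counts[c] / total for c in INSERTION_CLASSES}
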