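"""Source-element fingerprinting, activity (TPAM), population frequency and truncation.

Every L1 3' transduction carries a unique downstream sequence that acts as a
barcode of its source locus, so transductions can be fingerprinted to the
retrotransposition-competent L1 (rc-L1) that produced them.  Per-source
activity is expressed as TPAM — transductions per L1 allele per one million
endogenous point mutations (EPMs) of molecular time — aggregated over the
individuals that carry the source.  Population allele frequency (PAF) is the
percentage of panel individuals carrying the element, and truncation status
records whether the element's open reading frames are disrupted.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .retro_calls import (
    SegmentMapping,
    SourceRecord,
    TRANSDUCTION_WINDOW,
    attribute_source,
)

REFERENCE_STATUSES = ("referenced", "non-referenced", "postzygotic")
TRUNCATION_STATUSES = ("intact", "truncated", "unknown")

#: minimum supporting-evidence fraction for presence of a source in a genome
PRESENCE_THRESHOLD = 0.15


@dataclass
class SourceElement:
    """One rc-L1 locus and its population/individual-level annotation."""

    source_id: str
    chrom: str
    start: int
    end: int
    strand: str
    reference_status: str = "referenced"
    subfamily: str = "L1HS"
    #: individual -> allele count (0, 1 or 2); postzygotic sources carry 1
    zygosity: dict[str, int] = field(default_factory=dict)
    paf: Optional[float] = None
    truncation: str = "unknown"

    def __post_init__(self):
        if self.reference_status not in REFERENCE_STATUSES:
            raise ValueError(f"unknown reference_status {self.reference_status!r}")
        if any(z not in (0, 1, 2) for z in self.zygosity.values()):
            raise ValueError("zygosity values must be 0, 1 or 2 alleles")
        if self.paf is not None and not 0 <= self.paf <= 100:
            raise ValueError("PAF must lie in [0, 100]")

    def to_record(self) -> SourceRecord:
        return SourceRecord(
            source_id=self.source_id,
            chrom=self.chrom,
            start=self.start,
            end=self.end,
            strand=self.strand,
        )


# ---------------------------------------------------------------------------
# Fingerprinting
# ---------------------------------------------------------------------------

def fingerprint(
    segment: SegmentMapping,
    registry: Sequence[SourceElement],
    *,
    window: int = TRANSDUCTION_WINDOW,
) -> tuple[Optional[str], list[str]]:
    """Attribute a transduced unique segment to its source element.

    The source whose 3' end lies within ``window`` bp upstream of the segment
    (in the source-strand sense) is attributed; the nearest wins on ties and
    the ambiguity is logged.  Segments mapping inside annotated repeats are
    refused, since they carry no unique barcode.
    """
    records = [s.to_record() for s in registry]
    return attribute_source(segment, records, window=window)


# ---------------------------------------------------------------------------
# TPAM
# ---------------------------------------------------------------------------

def compute_tpam(
    transductions_per_individual: Mapping[str, int],
    zygosity: Mapping[str, int],
    epm_per_individual: Mapping[str, float],
) -> float:
    """Transductions per L1 allele per 1 million EPMs of molecular time.

    Only carrier individuals (zygosity >= 1) contribute; exposures are pooled
    across carriers (ratio of sums), which is unbiased for Poisson counts:

        TPAM = sum(transductions) / sum(alleles * EPM / 1e6)
    """
    carriers = [ind for ind, z in zygosity.items() if z >= 1]
    if not carriers:
        raise ValueError("no carrier individuals: TPAM undefined")
    exposure = sum(zygosity[ind] * epm_per_individual.get(ind, 0.0) / 1e6 for ind in carriers)
    if exposure <= 0:
        raise ValueError("zero aggregate allele-EPM exposure: TPAM undefined")
    events = sum(transductions_per_individual.get(ind, 0) for ind in carriers)
    return events / exposure


# ---------------------------------------------------------------------------
# Population allele frequency
# ---------------------------------------------------------------------------

def call_presence(evidence_fraction: float, *, threshold: float = PRESENCE_THRESHOLD) -> bool:
    """A source exists in a genome iff its supporting-evidence fraction >= 15%.

    For non-reference sources the evidence is the fraction of L1-supporting
    reads; for reference sources, the fraction of short-insert read pairs
    opposing the L1 deletion.
    """
    if not 0 <= evidence_fraction <= 1:
        raise ValueError("evidence fraction must lie in [0, 1]")
    return evidence_fraction >= threshold


def compute_paf(
    panel: Mapping[str, float] | Sequence[float],
    *,
    threshold: float = PRESENCE_THRESHOLD,
) -> float:
    """PAF (%) of a source: percentage of panel individuals carrying it."""
    fractions = list(panel.values()) if isinstance(panel, Mapping) else list(panel)
    if not fractions:
        raise ValueError("empty panel: PAF undefined")
    present = sum(call_presence(f, threshold=threshold) for f in fractions)
    return 100.0 * present / len(fractions)


def paf_table(
    panel: pd.DataFrame, *, threshold: float = PRESENCE_THRESHOLD
) -> pd.Series:
    """PAF per source from a sources x individuals evidence-fraction table."""
    if panel.empty:
        raise ValueError("empty panel: PAF undefined")
    return 100.0 * (panel >= threshold).mean(axis=1)


# ---------------------------------------------------------------------------
# Truncation classification
# ---------------------------------------------------------------------------

@dataclass
class ConsensusVariant:
    """A sequence variant on the element's consensus coordinates, per allele."""

    allele: str
    pos: int  # 1-based consensus coordinate
    kind: str  # 'snv' | 'insertion' | 'deletion'
    ref: str = ""
    alt: str = ""
    introduces_stop: bool = False

    def length_change(self) -> int:
        if self.kind == "insertion":
            return len(self.alt) - len(self.ref)
        if self.kind == "deletion":
            return -(len(self.ref) - len(self.alt))
        return 0


def default_orf_intervals() -> dict[str, tuple[int, int]]:
    """L1HS consensus ORF intervals shipped with the package (1-based, inclusive)."""
    path = importlib.resources.files("l1mosaic.data").joinpath("l1hs_orfs.tsv")
    table = pd.read_csv(path, sep="\t")
    return {row.orf: (int(row.start), int(row.end)) for row in table.itertuples()}


def classify_truncation(
    variants: Iterable[ConsensusVariant],
    orf_intervals: Optional[Mapping[str, tuple[int, int]]] = None,
) -> tuple[str, list[str]]:
    """Classify a source element as intact or ORF-truncated.

    Truncated iff, on *every* informative allele, some variant introduces a
    premature stop or shifts the reading frame (indel of length not divisible
    by 3) inside a supplied ORF interval; intact when at least one informative
    allele has no such variant; unknown when no informative allele exists.
    """
    warnings: list[str] = []
    if orf_intervals is None:
        try:
            orf_intervals = default_orf_intervals()
        except FileNotFoundError:  # pragma: no cover
            warnings.append("ORF annotation unavailable: truncation unknown")
            return "unknown", warnings
    variants = list(variants)
    alleles = {v.allele for v in variants}
    if not alleles:
        return "unknown", ["no informative allele"]

    def in_orf(pos: int) -> bool:
        return any(lo <= pos <= hi for lo, hi in orf_intervals.values())

    def truncating(v: ConsensusVariant) -> bool:
        if not in_orf(v.pos):
            return False
        if v.introduces_stop:
            return True
        return v.length_change() % 3 != 0

    per_allele = {a: any(truncating(v) for v in variants if v.allele == a) for a in alleles}
    return ("truncated" if all(per_allele.values()) else "intact"), warnings


# ---------------------------------------------------------------------------
# Activity-vs-prevalence summary
# ---------------------------------------------------------------------------

def tpam_paf_correlation(tpam: Mapping[str, float], paf: Mapping[str, float]) -> float:
    """Spearman rank correlation between per-source TPAM and PAF."""
    from scipy import stats

    keys = sorted(set(tpam) & set(paf))
    if len(keys) < 3:
        return math.nan
    rho, _ = stats.spearmanr([tpam[k] for k in keys], [paf[k] for k in keys])
    return float(rho)
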