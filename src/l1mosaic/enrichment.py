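"""Genomic-feature binning and insertion-rate enrichment.

The genome is divided into four bins (0-3) per feature and the insertion
rate of each bin is compared against bin 0:

* fold-enrichment signals (DNase hypersensitivity, histone marks): signal < 1
  is bin 0; the remainder is split into three bins of equal genomic size by
  increasing signal;
* expression: FPKM = 0 is bin 0; the remainder into three equal-size bins;
* replication timing: four equal-size bins, latest-replicating = bin 0,
  earliest = bin 3;
* L1 endonuclease motif similarity: per-position minimum mismatch count to
  TTTT|R or Y|AAAA; >=4 mismatches = bin 0 (most dissimilar) down to <=1 =
  bin 3 (most similar).

"Equal-sized" means equal base pairs, since the rate denominators are bin
lengths.  Fold enrichment of bin k is (count_k/size_k)/(count_0/size_0) with
an exact conditional-binomial (Poisson rate-ratio) confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

BIN_SCHEMES = ("fold_enrichment", "expression", "replication_timing", "motif_mismatch")

#: L1 endonuclease target motifs (cleavage site marked by |): TTTT|R and Y|AAAA
MOTIFS = ("TTTTA", "TTTTG", "CAAAA", "TAAAA")


@dataclass
class FeatureBinning:
    """Per-interval bin assignment for one genomic feature."""

    feature: str
    scheme: str
    intervals: pd.DataFrame  # columns: chrom, start, end, bin (0-based half-open)

    def bin_sizes(self) -> pd.Series:
        sizes = (self.intervals["end"] - self.intervals["start"]).groupby(
            self.intervals["bin"]
        ).sum()
        return sizes.reindex(range(4), fill_value=0)

    def assign(self, chrom: str, pos: int) -> Optional[int]:
        """Bin of a 0-based position, or None when outside all intervals."""
        sub = self.intervals[self.intervals["chrom"] == chrom]
        hit = sub[(sub["start"] <= pos) & (pos < sub["end"])]
        if hit.empty:
            return None
        return int(hit["bin"].iloc[0])


def _equal_bp_tertiles(track: pd.DataFrame, positive_mask: np.ndarray) -> np.ndarray:
    """Split the positive-signal intervals into 3 bins of ~equal total bp by signal."""
    bins = np.zeros(len(track), dtype=int)
    pos_idx = np.flatnonzero(positive_mask)
    if len(pos_idx) == 0:
        return bins
    sub = track.iloc[pos_idx]
    order = np.argsort(sub["signal"].to_numpy(), kind="stable")
    lengths = (sub["end"] - sub["start"]).to_numpy()[order]
    cum = np.cumsum(lengths)
    total = cum[-1]
    # bin 1 = lowest third, bin 3 = highest third of positive signal, by bp
    tertile = np.minimum(3, 1 + (3 * (cum - lengths / 2) / total).astype(int))
    bins[pos_idx[order]] = tertile
    return bins


def bin_signal_track(track: pd.DataFrame, scheme: str, *, feature: str = "") -> FeatureBinning:
    """Bin a genome-wide interval signal track under a named scheme.

    ``track`` columns: chrom, start, end (0-based half-open), signal.
    """
    if scheme not in ("fold_enrichment", "expression", "replication_timing"):
        raise ValueError(f"unknown binning scheme {scheme!r}")
    required = {"chrom", "start", "end", "signal"}
    if not required <= set(track.columns):
        raise ValueError(f"track must have columns {sorted(required)}")
    track = track.reset_index(drop=True)
    signal = track["signal"].to_numpy(dtype=float)
    if np.allclose(signal, signal[0]):
        raise ValueError("degenerate binning: signal is constant across the genome")

    if scheme == "fold_enrichment":
        positive = signal >= 1.0
        if not positive.any():
            raise ValueError("degenerate binning: no interval with fold enrichment >= 1")
        bins = _equal_bp_tertiles(track, positive)
    elif scheme == "expression":
        positive = signal > 0.0
        if not positive.any():
            raise ValueError("degenerate binning: no expressed interval")
        bins = _equal_bp_tertiles(track, positive)
    else:  # replication_timing: quartiles by bp; latest (lowest timing value
        # = latest replication when the track encodes replication *timing
        # signal*, conventionally high = early) -> bin 0
        order = np.argsort(signal, kind="stable")
        lengths = (track["end"] - track["start"]).to_numpy()[order]
        cum = np.cumsum(lengths)
        total = cum[-1]
        quartile = np.minimum(3, (4 * (cum - lengths / 2) / total).astype(int))
        bins = np.zeros(len(track), dtype=int)
        bins[order] = quartile

    out = track[["chrom", "start", "end"]].copy()
    out["bin"] = bins
    return FeatureBinning(feature=feature or scheme, scheme=scheme, intervals=out)


# ---------------------------------------------------------------------------
# Endonuclease motif similarity
# ---------------------------------------------------------------------------

def motif_mismatches(site: str) -> int:
    """Minimum Hamming distance of a 5-mer to the L1 endonuclease motifs.

    Ambiguous bases (N or anything non-ACGT) count as mismatches.
    """
    site = site.upper()
    if len(site) != len(MOTIFS[0]):
        raise ValueError(f"site must be a {len(MOTIFS[0])}-mer")
    best = len(site)
    for motif in MOTIFS:
        mm = sum(1 for a, b in zip(site, motif) if a != b or a not in "ACGT")
        best = min(best, mm)
    return best


def mismatch_bin(mismatches: int) -> int:
    """Bin by motif similarity: >=4 -> 0, 3 -> 1, 2 -> 2, <=1 -> 3."""
    if mismatches >= 4:
        return 0
    if mismatches == 3:
        return 1
    if mismatches == 2:
        return 2
    return 3


def motif_mismatch_bins(
    sequence: str, chrom: str = "chr1", *, offset: int = 0
) -> FeatureBinning:
    """Per-position motif-similarity binning of a genome sequence.

    Each position is scored by the 5-mer starting there (positions within 4 bp
    of the end are skipped); contiguous runs of equal bin are merged into
    intervals.
    """
    k = len(MOTIFS[0])
    n = len(sequence) - k + 1
    if n <= 0:
        raise ValueError("sequence shorter than the motif")
    bins = np.fromiter(
        (mismatch_bin(motif_mismatches(sequence[i : i + k])) for i in range(n)),
        dtype=int,
        count=n,
    )
    rows = []
    run_start = 0
    for i in range(1, n + 1):
        if i == n or bins[i] != bins[run_start]:
            rows.append(
                {
                    "chrom": chrom,
                    "start": offset + run_start,
                    "end": offset + i,
                    "bin": int(bins[run_start]),
                }
            )
            run_start = i
    return FeatureBinning(
        feature="endonuclease_motif",
        scheme="motif_mismatch",
        intervals=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Enrichment scores
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    feature: str
    counts: dict[int, int]
    sizes: dict[int, float]
    #: bin -> (fold, ci_low, ci_high); bin 0 is the reference (fold 1, not reported)
    folds: dict[int, tuple[float, float, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in (1, 2, 3):
            fold, lo, hi = self.folds.get(b, (np.nan, np.nan, np.nan))
            rows.append(
                {
                    "feature": self.feature,
                    "bin": b,
                    "count": self.counts.get(b, 0),
                    "size_bp": self.sizes.get(b, 0.0),
                    "fold": fold,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        return pd.DataFrame(rows)


def rate_ratio_ci(
    count1: int, size1: float, count0: int, size0: float, *, confidence: float = 0.95
) -> tuple[float, float, float]:
    """Exact Poisson rate ratio (count1/size1)/(count0/size0) with CI.

    Conditional on the total count, count1 is binomial; the Clopper-Pearson
    interval for its proportion p maps to the rate ratio via
    ratio = p/(1-p) * size0/size1.
    """
    if size1 <= 0 or size0 <= 0:
        raise ValueError("bin sizes must be positive")
    n = count1 + count0
    if count0 == 0:
        # reference bin empty: ratio undefined; one-sided lower bound only
        if count1 == 0:
            return np.nan, 0.0, np.inf
        alpha = 1 - confidence
        p_low = stats.beta.ppf(alpha / 2, count1, 1) if count1 > 0 else 0.0
        lower = p_low / (1 - p_low) * size0 / size1 if p_low < 1 else np.inf
        return np.inf, lower, np.inf
    ratio = (count1 / size1) / (count0 / size0)
    alpha = 1 - confidence
    p_low = stats.beta.ppf(alpha / 2, count1, count0 + 1) if count1 > 0 else 0.0
    p_high = stats.beta.ppf(1 - alpha / 2, count1 + 1, count0)
    scale = size0 / size1
    lo = (p_low / (1 - p_low)) * scale if p_low < 1 else np.inf
    hi = (p_high / (1 - p_high)) * scale if p_high < 1 else np.inf
    return ratio, lo, hi


def enrichment_scores(
    insertions: pd.DataFrame, binning: FeatureBinning, *, confidence: float = 0.95
) -> EnrichmentResult:
    """Fold enrichment of insertion rate in bins 1-3 against bin 0.

    ``insertions`` columns: chrom, pos (0-based).  Insertions outside all
    binned intervals are not assignable and are excluded from the counts.
    """
    counts = {b: 0 for b in range(4)}
    intervals = binning.intervals
    for chrom, sub in insertions.groupby("chrom"):
        ivals = intervals[intervals["chrom"] == chrom].sort_values("start")
        if ivals.empty:
            continue
        starts = ivals["start"].to_numpy()
        ends = ivals["end"].to_numpy()
        bins = ivals["bin"].to_numpy()
        pos = sub["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        for b in bins[idx[ok]]:
            counts[int(b)] += 1
    sizes = binning.bin_sizes()
    result = EnrichmentResult(
        feature=binning.feature,
        counts=counts,
        sizes={b: float(sizes[b]) for b in range(4)},
    )
    for b in (1, 2, 3):
        result.folds[b] = rate_ratio_ci(
            counts[b], float(sizes[b]), counts[0], float(sizes[0]), confidence=confidence
        )
    return result


# ---------------------------------------------------------------------------
# Sliding-window insertion rate
# ---------------------------------------------------------------------------

def window_insertion_rate(
    insertions: pd.DataFrame,
    chrom_lengths: dict[str, int],
    *,
    window: int = 10_000_000,
    step: int = 5_000_000,
) -> pd.DataFrame:
    """Insertion counts per sliding window (default 10 Mb, 5 Mb increment).

    Windows are half-open [start, start+window) tiled per chromosome;
    insertions beyond the chromosome length are rejected rows, logged in
    ``DataFrame.attrs['rejected']``.
    """
    rows = []
    rejected = []
    by_chrom = {c: g["pos"].to_numpy() for c, g in insertions.groupby("chrom")}
    for chrom, length in chrom_lengths.items():
        pos = by_chrom.get(chrom, np.array([], dtype=int))
        bad = (pos < 0) | (pos >= length)
        if bad.any():
            rejected.extend((chrom, int(p)) for p in pos[bad])
            pos = pos[~bad]
        start = 0
        while start < length:
            end = min(start + window, length)
            count = int(((pos >= start) & (pos < end)).sum())
            rows.append({"chrom": chrom, "start": start, "end": end, "count": count})
            start += step
    for chrom in by_chrom:
        if chrom not in chrom_lengths:
            rejected.extend((chrom, int(p)) for p in by_chrom[chrom])
    out = pd.DataFrame(rows)
    out.attrs["rejected"] = rejected
    return out
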