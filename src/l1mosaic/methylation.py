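"""L1 promoter methylation scoring, epigenotype calls and concordance analyses.

A diploid clone's CpG methylation fraction at an L1 promoter is roughly
trimodal: ~0 when both alleles are demethylated, ~0.5 when one allele is, and
~1 when both are methylated.  Each covered CpG in the scoring window — the
first 250 bp downstream of the L1 transcription start site (+1 to +250) — is
classified by its methylated-read fraction and given a score (0 homozygous
demethylation, 5 heterozygous, 10 homozygous methylation); the promoter score
is the mean over scored CpGs, and the promoter epigenotype (open /
heterozygous / closed) is a deterministic function of that score.

The concordance analysis asks when the epigenotype is fixed in development:
clone pairs are stratified by the molecular time of their most recent common
ancestor and the per-source epigenotype agreement is compared across strata.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tree import LineageTree

CPG_CATEGORIES = ("homo_demethylated", "heterozygous", "homo_methylated")
EPIGENOTYPES = ("open", "heterozygous", "closed")

#: per-CpG classification thresholds on the methylated fraction
CPG_HETERO_MIN = 0.25
CPG_METH_MIN = 0.75

#: scoring window relative to the L1 transcription start site (1-based, inclusive)
SCORING_WINDOW = (1, 250)
DISPLAY_WINDOW = (-600, 600)

#: promoter-score cutoffs for the categorical epigenotype (midpoints of 0/5/10)
EPIGENOTYPE_OPEN_MAX = 2.5
EPIGENOTYPE_CLOSED_MIN = 7.5

CPG_SCORES = {"homo_demethylated": 0.0, "heterozygous": 5.0, "homo_methylated": 10.0}


@dataclass
class CpGRecord:
    """Methylation evidence at one CpG site."""

    rel_pos: int  # position relative to the L1 TSS (+1 = first downstream base)
    meth: int
    unmeth: int

    @property
    def coverage(self) -> int:
        return self.meth + self.unmeth

    @property
    def fraction(self) -> float:
        if self.coverage == 0:
            raise ValueError("methylated fraction undefined at zero coverage")
        return self.meth / self.coverage


@dataclass
class PromoterMethylome:
    """Per-CpG methylation around one L1 source's 5' end in one clone."""

    source_id: str
    clone_id: str
    cpgs: list[CpGRecord] = field(default_factory=list)


def classify_cpg(fraction: float) -> str:
    """Classify a CpG by methylated fraction: <0.25 / [0.25, 0.75) / >=0.75."""
    if not 0 <= fraction <= 1:
        raise ValueError("methylated fraction must lie in [0, 1]")
    if fraction < CPG_HETERO_MIN:
        return "homo_demethylated"
    if fraction < CPG_METH_MIN:
        return "heterozygous"
    return "homo_methylated"


@dataclass
class PromoterScore:
    score: float
    n_scored: int
    n_zero_coverage: int


def promoter_score(
    methylome: PromoterMethylome,
    *,
    window: tuple[int, int] = SCORING_WINDOW,
) -> PromoterScore:
    """Mean per-CpG score (0/5/10) over covered CpGs in the +1..+250 window.

    CpGs with zero coverage are excluded (not imputed) and counted in the
    coverage report; with no covered CpG in the window the score is undefined.
    """
    lo, hi = window
    in_window = [c for c in methylome.cpgs if lo <= c.rel_pos <= hi]
    covered = [c for c in in_window if c.coverage > 0]
    n_zero = len(in_window) - len(covered)
    if not covered:
        raise ValueError(
            f"no covered CpG in window {window} for {methylome.source_id}/{methylome.clone_id}"
        )
    score = float(np.mean([CPG_SCORES[classify_cpg(c.fraction)] for c in covered]))
    return PromoterScore(score=score, n_scored=len(covered), n_zero_coverage=n_zero)


def call_epigenotype(score: float) -> str:
    """Promoter epigenotype from the 0-10 score: open / heterozygous / closed."""
    if not 0 <= score <= 10:
        raise ValueError("promoter score must lie in [0, 10]")
    if score < EPIGENOTYPE_OPEN_MAX:
        return "open"
    if score < EPIGENOTYPE_CLOSED_MIN:
        return "heterozygous"
    return "closed"


def score_matrix(methylomes: Iterable[PromoterMethylome]) -> pd.DataFrame:
    """Clone x source matrix of promoter scores (NaN where undefined)."""
    cells: dict[tuple[str, str], float] = {}
    for m in methylomes:
        try:
            cells[(m.clone_id, m.source_id)] = promoter_score(m).score
        except ValueError:
            cells[(m.clone_id, m.source_id)] = math.nan
    if not cells:
        return pd.DataFrame()
    clones = sorted({k[0] for k in cells})
    sources = sorted({k[1] for k in cells})
    out = pd.DataFrame(index=clones, columns=sources, dtype=float)
    for (clone, source), v in cells.items():
        out.loc[clone, source] = v
    return out


# ---------------------------------------------------------------------------
# Concordance vs embryonic branching time
# ---------------------------------------------------------------------------

#: default molecular-time strata (mutations): before, inside, after the
#: gastrulation-to-organogenesis fixation window
DEFAULT_TIME_WINDOW = (17.0, 65.0)


def select_variable_sources(scores: pd.DataFrame, top_k: int = 30) -> list[str]:
    """The top-k sources by promoter-score variance across clones."""
    variances = scores.var(axis=0, skipna=True).sort_values(ascending=False)
    return list(variances.index[:top_k])


@dataclass
class ConcordanceResult:
    """Pairwise epigenotype agreement stratified by MRCA molecular time."""

    pair_table: pd.DataFrame  # clone_a, clone_b, source, mrca_time, stratum, agree, diff
    concordance_by_stratum: dict[str, float]
    ks_statistic: float
    ks_pvalue: float


def concordance_vs_branching(
    tree: LineageTree,
    scores: pd.DataFrame,
    *,
    top_k: int = 30,
    window: tuple[float, float] = DEFAULT_TIME_WINDOW,
) -> ConcordanceResult:
    """Relate clone-pair epigenotype concordance to embryonic branching time.

    For each pair of clones and each of the ``top_k`` most variable sources,
    records the absolute promoter-score difference and whether the categorical
    epigenotypes agree; pairs are stratified by MRCA molecular time into
    early (< window start), window, and late (> window end).  The KS statistic
    compares the score-difference distributions of the early and late strata.
    """
    clones = [c for c in scores.index]
    if len(clones) < 2:
        raise ValueError("need at least two clones with epigenotypes")
    sources = select_variable_sources(scores, top_k=top_k)
    lo, hi = window

    rows = []
    for a, b in itertools.combinations(clones, 2):
        t = tree.mrca_time(a, b)
        stratum = "early" if t < lo else ("window" if t <= hi else "late")
        for src in sources:
            sa, sb = scores.loc[a, src], scores.loc[b, src]
            if pd.isna(sa) or pd.isna(sb):
                continue
            rows.append(
                {
                    "clone_a": a,
                    "clone_b": b,
                    "source": src,
                    "mrca_time": t,
                    "stratum": stratum,
                    "agree": call_epigenotype(sa) == call_epigenotype(sb),
                    "score_diff": abs(sa - sb),
                }
            )
    table = pd.DataFrame(rows)
    concordance: dict[str, float] = {}
    for stratum in ("early", "window", "late"):
        sub = table[table["stratum"] == stratum] if not table.empty else table
        if len(sub) >= 1:
            concordance[stratum] = float(sub["agree"].mean())

    if table.empty:
        early, late = [], []
    else:
        early = table.loc[table["stratum"] == "early", "score_diff"]
        late = table.loc[table["stratum"].isin(["window", "late"]), "score_diff"]
    if len(early) >= 2 and len(late) >= 2:
        ks = stats.ks_2samp(early, late)
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_stat, ks_p = math.nan, math.nan
    return ConcordanceResult(
        pair_table=table,
        concordance_by_stratum=concordance,
        ks_statistic=ks_stat,
        ks_pvalue=ks_p,
    )


def concordance_rate(agree_count: int, total_pairs: int) -> float:
    """Concordance as a percentage of agreeing clone-L1 pairs."""
    if total_pairs <= 0:
        raise ValueError("total pair count must be positive")
    return 100.0 * agree_count / total_pairs


# ---------------------------------------------------------------------------
# Flanking-region methylation profile
# ---------------------------------------------------------------------------

def flank_profile_diff(
    group1: pd.DataFrame,
    group2: pd.DataFrame,
    *,
    promoter_window: tuple[int, int] = SCORING_WINDOW,
) -> pd.DataFrame:
    """Per-CpG mean-fraction difference between two clone groups around a source.

    Inputs are CpG-position x clone fraction tables (index = position relative
    to the L1 TSS, spanning up to +/-100 kb).  CpGs covered in only one group
    are excluded and counted.  The promoter scoring window is flagged.
    """
    common = group1.index.intersection(group2.index)
    excluded = len(group1.index.union(group2.index)) - len(common)
    mean1 = group1.loc[common].mean(axis=1, skipna=True)
    mean2 = group2.loc[common].mean(axis=1, skipna=True)
    defined = mean1.notna() & mean2.notna()
    excluded += int((~defined).sum())
    out = pd.DataFrame(
        {
            "mean_group1": mean1[defined],
            "mean_group2": mean2[defined],
            "difference": (mean1 - mean2)[defined],
        }
    )
    lo, hi = promoter_window
    out["in_promoter_window"] = (out.index >= lo) & (out.index <= hi)
    out.attrs["excluded_cpgs"] = excluded
    return out


# ---------------------------------------------------------------------------
# Readthrough transcription
# ---------------------------------------------------------------------------

def readthrough_fpkm(
    read_count: int,
    region_length: int,
    total_mapped: int,
    *,
    strand_matched: bool = True,
    sense_within_gene: bool = False,
) -> float:
    """FPKM of readthrough transcription 1 kb downstream of a source 3' end.

    Only reads on the source strand are informative (``strand_matched``);
    when the source lies sense within a gene the read origin is ambiguous and
    the FPKM is undefined.
    """
    if sense_within_gene:
        raise ValueError("FPKM undefined: source lies sense within a gene")
    if not strand_matched:
        raise ValueError("only source-strand-matching read counts are accepted")
    if region_length <= 0 or total_mapped <= 0:
        raise ValueError("region length and total mapped reads must be positive")
    return read_count / ((region_length / 1000.0) * (total_mapped / 1e6))
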