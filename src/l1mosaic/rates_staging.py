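"""Developmental staging, endogenous-mutation clocks and soL1R rate inference.

Somatic L1 retrotransposition (soL1R) rates are normalized per endogenous
point mutation (EPM) — SNVs attributable to the clock-like signatures SBS1
and SBS5/40 plus indels attributable to ID1/ID2 — so that lineages of very
different chronological span become comparable on a molecular-time axis.

Branches of the clone phylogeny are assigned to four stages:

* ``pregastrulation``  — shared branches whose mutations are detectable in
  bulk blood (mesodermal origin), hence predating germ-layer separation;
* ``postgastrulation`` — shared embryonic branches absent from blood;
* ``ageing``           — terminal branches of normal clones;
* ``tumourigenesis``   — the clonal branch of a matched cancer.

Rates are events per 1,000 EPMs with exact Poisson confidence intervals;
stage comparisons use the conditional (binomial) exact Poisson test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .tree import LineageTree, TreeNode

STAGES = ("pregastrulation", "postgastrulation", "ageing", "tumourigenesis")

#: signatures counted as endogenous molecular time
ENDOGENOUS_SIGNATURES = frozenset({"SBS1", "SBS5", "SBS40", "SBS5/40", "ID1", "ID2"})

#: per-cell-per-cell-division mutation rates: first two divisions, then later
EARLY_RATE_RANGE = (2.4, 3.8)
LATE_RATE_RANGE = (0.7, 1.2)


# ---------------------------------------------------------------------------
# Signature exposure refitting and EPM accounting
# ---------------------------------------------------------------------------

def fit_signature_exposures(
    spectrum: np.ndarray | Sequence[float],
    reference_signatures: pd.DataFrame,
) -> tuple[pd.Series, float]:
    """Refit known signatures to a mutation spectrum by non-negative least squares.

    ``reference_signatures`` columns are unit-sum signature profiles (for
    example 96 trinucleotide channels); the returned exposures minimize the
    squared reconstruction error subject to non-negativity.  Returns
    ``(exposures, residual_norm)``.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    ref = reference_signatures.to_numpy(dtype=float)
    if spectrum.shape[0] != ref.shape[0]:
        raise ValueError("spectrum length must match signature matrix rows")
    colsums = ref.sum(axis=0)
    if not np.allclose(colsums[colsums > 0], 1.0, atol=1e-6):
        raise ValueError("reference signature columns must sum to 1")
    if not spectrum.any():
        return pd.Series(0.0, index=reference_signatures.columns), 0.0
    coef, residual = optimize.nnls(ref, spectrum)
    return pd.Series(coef, index=reference_signatures.columns), float(residual)


def count_epm(exposures: Mapping[str, float]) -> int:
    """Endogenous point mutations: SBS1 + SBS5/40 SNV exposures + ID1/ID2 indels.

    Exposures are kept real-valued internally; the EPM count is rounded to the
    nearest integer for use in exact tests.
    """
    total = sum(v for k, v in exposures.items() if k in ENDOGENOUS_SIGNATURES)
    return int(round(total))


# ---------------------------------------------------------------------------
# Stage assignment
# ---------------------------------------------------------------------------

@dataclass
class StageAnnotation:
    """Branch (node id) -> stage, plus the blood evidence used."""

    stages: dict[str, str]
    blood_supported: dict[str, bool]
    warnings: list[str]

    def branches_in(self, stage: str) -> list[str]:
        return [b for b, s in self.stages.items() if s == stage]


def assign_stages(
    tree: LineageTree,
    blood_evidence: Optional[Mapping[str, bool]] = None,
    clone_tissue_labels: Optional[Mapping[str, str]] = None,
) -> StageAnnotation:
    """Assign each branch to a developmental stage.

    ``blood_evidence`` maps shared-branch node ids to whether their mutations
    were detected in bulk blood; shared branches with blood support are
    pregastrulational, other shared branches postgastrulational.  Terminal
    branches are ``ageing`` unless the clone is labelled ``cancer`` in
    ``clone_tissue_labels``, in which case the branch is ``tumourigenesis``.
    """
    blood_evidence = dict(blood_evidence or {})
    clone_tissue_labels = dict(clone_tissue_labels or {})
    warnings: list[str] = []
    if not blood_evidence:
        warnings.append(
            "no blood genotyping supplied: shared branches default to postgastrulation"
        )
    stages: dict[str, str] = {}
    supported: dict[str, bool] = {}
    for node in tree.branches():
        if node.is_leaf():
            tissue = clone_tissue_labels.get(node.sample or node.node_id, "normal")
            stages[node.node_id] = (
                "tumourigenesis" if tissue == "cancer" else "ageing"
            )
        else:
            has_blood = bool(blood_evidence.get(node.node_id, False))
            supported[node.node_id] = has_blood
            stages[node.node_id] = (
                "pregastrulation" if has_blood else "postgastrulation"
            )
        node.stage = stages[node.node_id]
    return StageAnnotation(stages=stages, blood_supported=supported, warnings=warnings)


# ---------------------------------------------------------------------------
# Rate estimation and comparison
# ---------------------------------------------------------------------------

@dataclass
class RateEstimate:
    """A soL1R rate normalized per 1,000 EPMs, with an exact Poisson 95% CI."""

    events: int
    epm: float
    rate_per_1000_epm: float
    ci_low: float
    ci_high: float

    def pcpcd_range(
        self,
        early: tuple[float, float] = EARLY_RATE_RANGE,
        late: tuple[float, float] = LATE_RATE_RANGE,
    ) -> tuple[float, float]:
        """Convert the per-EPM rate to events per cell per cell division.

        Multiplies the rate by the stated per-division endogenous mutation
        rates; the two bounds use the slow (late low) and fast (early high)
        clock.  Embryonic branches are dominated by the late-regime clock, so
        the late range is the default span.
        """
        per_epm = self.rate_per_1000_epm / 1000.0
        return (per_epm * late[0], per_epm * early[1])


def poisson_ci(events: int, *, confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson CI for a count, via chi-square quantiles."""
    if events < 0:
        raise ValueError("event count must be non-negative")
    alpha = 1.0 - confidence
    low = 0.0 if events == 0 else float(stats.chi2.ppf(alpha / 2, 2 * events)) / 2.0
    high = float(stats.chi2.ppf(1 - alpha / 2, 2 * events + 2)) / 2.0
    return low, high


def sol1r_rate(events: int, epm: float, *, confidence: float = 0.95) -> RateEstimate:
    """soL1R rate per 1,000 EPMs with an exact Poisson CI on the count."""
    if epm <= 0:
        raise ValueError("undefined rate: EPM exposure must be positive")
    if events < 0:
        raise ValueError("event count must be non-negative")
    low, high = poisson_ci(events, confidence=confidence)
    scale = 1000.0 / epm
    return RateEstimate(
        events=events,
        epm=epm,
        rate_per_1000_epm=events * scale,
        ci_low=low * scale,
        ci_high=high * scale,
    )


def compare_rates(events1: int, epm1: float, events2: int, epm2: float) -> float:
    """Two-sided exact Poisson test of rate equality between two exposures.

    Conditional on the total count, ``events1`` is Binomial(n, p) with
    p = epm1 / (epm1 + epm2) under the null; the two-sided p-value sums the
    probabilities of all outcomes no more likely than the observed one.
    """
    if epm1 <= 0 or epm2 <= 0:
        raise ValueError("exposures must be positive")
    n = events1 + events2
    if n == 0:
        return 1.0
    p = epm1 / (epm1 + epm2)
    return float(stats.binomtest(events1, n, p, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# Molecular time conversion and burden regression
# ---------------------------------------------------------------------------

def molecular_time_to_generations(
    m: float,
    *,
    fast: tuple[float, float] = (EARLY_RATE_RANGE[1], LATE_RATE_RANGE[1]),
    slow: tuple[float, float] = (EARLY_RATE_RANGE[0], LATE_RATE_RANGE[0]),
) -> tuple[int, int]:
    """Convert a mutation count to an (earliest, latest) cell-generation range.

    The first two divisions run at the early per-division rate r1 and later
    divisions at r2, so g = m / r1 when m <= 2 r1, else g = 2 + (m - 2 r1)/r2.
    The fast clock gives the earliest generation, the slow clock the latest.
    """
    if m < 0:
        raise ValueError("mutation count must be non-negative")

    def g(rates: tuple[float, float]) -> float:
        r1, r2 = rates
        if m <= 2 * r1:
            return m / r1
        return 2 + (m - 2 * r1) / r2

    return int(round(g(fast))), int(round(g(slow)))


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    pvalue: float
    n: int


def burden_age_regression(
    burdens: Sequence[float], ages: Sequence[float], *, confidence: float = 0.95
) -> RegressionResult:
    """OLS of per-individual mean soL1R burden on age (slope = events/clone/year)."""
    import statsmodels.api as sm

    burdens = np.asarray(burdens, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(burdens) != len(ages):
        raise ValueError("burden and age vectors must have equal length")
    if len(ages) < 3:
        raise ValueError("at least 3 individuals required")
    if np.allclose(ages, ages[0]):
        raise ValueError("undefined slope: all ages identical")
    X = sm.add_constant(ages)
    fit = sm.OLS(burdens, X).fit()
    ci = fit.conf_int(alpha=1 - confidence)
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        pvalue=float(fit.pvalues[1]),
        n=len(ages),
    )


# ---------------------------------------------------------------------------
# Tree-level rate report
# ---------------------------------------------------------------------------

def stage_rates(
    tree: LineageTree,
    annotation: StageAnnotation,
    *,
    confidence: float = 0.95,
) -> dict[str, RateEstimate]:
    """Aggregate events and EPM per stage across the tree and estimate rates."""
    events: dict[str, int] = {s: 0 for s in STAGES}
    epm: dict[str, float] = {s: 0.0 for s in STAGES}
    for node in tree.branches():
        stage = annotation.stages.get(node.node_id)
        if stage is None:
            continue
        events[stage] += len(node.sol1r_events)
        epm[stage] += node.epm
    out: dict[str, RateEstimate] = {}
    for stage in STAGES:
        if epm[stage] > 0:
            out[stage] = sol1r_rate(events[stage], epm[stage], confidence=confidence)
    return out


def rate_report(rates: Mapping[str, RateEstimate]) -> pd.DataFrame:
    rows = [
        {
            "stage": stage,
            "events": est.events,
            "epm": est.epm,
            "rate_per_1000_epm": est.rate_per_1000_epm,
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
        }
        for stage, est in rates.items()
    ]
    return pd.DataFrame(rows)
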