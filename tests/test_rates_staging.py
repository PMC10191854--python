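"""Signature refitting, EPM accounting, stage assignment and Poisson rate inference."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from l1mosaic.rates_staging import (
    assign_stages,
    burden_age_regression,
    compare_rates,
    count_epm,
    fit_signature_exposures,
    molecular_time_to_generations,
    sol1r_rate,
    stage_rates,
)
from l1mosaic.tree import LineageTree, TreeNode


def make_reference(n_channels=6):
    ref = pd.DataFrame(
        {
            "SBS1": [0.5, 0.5, 0, 0, 0, 0],
            "SBS5": [0, 0, 0.5, 0.5, 0, 0],
            "SBS18": [0, 0, 0, 0, 0.5, 0.5],
        }
    )
    return ref


# ---------------------------------------------------------------------------
# exposures / EPM
# ---------------------------------------------------------------------------

def test_pure_signature_spectrum_fits_exactly():
    ref = make_reference()
    spectrum = 100 * ref["SBS1"].to_numpy()
    exposures, residual = fit_signature_exposures(spectrum, ref)
    assert exposures["SBS1"] == pytest.approx(100)
    assert exposures["SBS5"] == pytest.approx(0, abs=1e-9)
    assert residual == pytest.approx(0, abs=1e-9)


def test_mixture_recovered_against_grid_search_oracle():
    ref = make_reference()
    spectrum = 60 * ref["SBS1"].to_numpy() + 40 * ref["SBS5"].to_numpy()
    exposures, _ = fit_signature_exposures(spectrum, ref)
    # independent oracle: exhaustive grid over integer exposure pairs
    best, best_err = None, math.inf
    for a in range(0, 101, 2):
        for b in range(0, 101, 2):
            err = np.sum(
                (a * ref["SBS1"].to_numpy() + b * ref["SBS5"].to_numpy() - spectrum) ** 2
            )
            if err < best_err:
                best, best_err = (a, b), err
    assert best == (60, 40)
    assert exposures["SBS1"] == pytest.approx(60, abs=1e-6)
    assert exposures["SBS5"] == pytest.approx(40, abs=1e-6)


def test_zero_spectrum_gives_zero_exposures():
    ref = make_reference()
    exposures, residual = fit_signature_exposures(np.zeros(6), ref)
    assert (exposures == 0).all() and residual == 0


def test_unnormalized_reference_rejected():
    bad = pd.DataFrame({"SBS1": [0.9, 0.9]})
    with pytest.raises(ValueError, match="sum to 1"):
        fit_signature_exposures([1.0, 1.0], bad)


def test_epm_sums_endogenous_signatures_only():
    assert count_epm({"SBS1": 100, "SBS5": 200, "SBS18": 50, "ID1": 30}) == 330
    assert count_epm({"SBS18": 500, "SBS88": 10, "ID5": 3}) == 0
    assert count_epm({"SBS5/40": 10.4, "ID2": 2.2}) == 13  # rounded for counting


# ---------------------------------------------------------------------------
# stage assignment
# ---------------------------------------------------------------------------

def staged_tree():
    root = TreeNode(node_id="zygote")
    shared1 = root.add_child(TreeNode(node_id="sh1", branch_length=5))
    shared2 = root.add_child(TreeNode(node_id="sh2", branch_length=20))
    shared1.add_child(TreeNode(node_id="c1", sample="c1", branch_length=900))
    shared1.add_child(TreeNode(node_id="c2", sample="c2", branch_length=800))
    shared2.add_child(TreeNode(node_id="c3", sample="c3", branch_length=850))
    shared2.add_child(TreeNode(node_id="tum", sample="tum", branch_length=1500))
    return LineageTree(root)


def test_blood_evidence_splits_pre_and_postgastrulation():
    tree = staged_tree()
    ann = assign_stages(tree, {"sh1": True, "sh2": False}, {"tum": "cancer"})
    assert ann.stages["sh1"] == "pregastrulation"
    assert ann.stages["sh2"] == "postgastrulation"
    assert ann.stages["c1"] == "ageing"
    assert ann.stages["tum"] == "tumourigenesis"
    # stages partition all branches
    assert set(ann.stages) == {n.node_id for n in tree.branches()}


def test_missing_blood_defaults_to_postgastrulation_with_warning():
    ann = assign_stages(staged_tree())
    assert ann.stages["sh1"] == "postgastrulation"
    assert any("blood" in w for w in ann.warnings)


def test_flipping_blood_evidence_only_flips_shared_labels():
    tree = staged_tree()
    a = assign_stages(tree, {"sh1": True, "sh2": False}).stages
    b = assign_stages(tree, {"sh1": False, "sh2": True}).stages
    changed = {k for k in a if a[k] != b[k]}
    assert changed == {"sh1", "sh2"}


# ---------------------------------------------------------------------------
# rate estimation
# ---------------------------------------------------------------------------

def test_rate_arithmetic_per_1000_epm():
    est = sol1r_rate(3, 2500)
    assert est.rate_per_1000_epm == pytest.approx(1.2)


def test_zero_count_ci_upper_bound_closed_form():
    est = sol1r_rate(0, 10_000)
    assert est.rate_per_1000_epm == 0
    # chi2.ppf(0.975, 2)/2 = -ln(0.025) = 3.68888...
    assert est.ci_high == pytest.approx(-math.log(0.025) / 10, rel=1e-6)
    assert est.ci_low == 0


def test_rate_undefined_at_zero_exposure():
    with pytest.raises(ValueError, match="EPM"):
        sol1r_rate(3, 0)


def test_ci_coverage_on_simulated_rates():
    """~95% of exact CIs cover the true rate over 500 Poisson replicates."""
    rng = np.random.default_rng(42)
    true_rate = 2.0 / 1000
    epm = 5000.0
    covered = 0
    n_rep = 500
    for _ in range(n_rep):
        events = rng.poisson(true_rate * epm)
        est = sol1r_rate(int(events), epm)
        covered += est.ci_low <= true_rate * 1000 <= est.ci_high
    assert 0.93 <= covered / n_rep <= 0.995


def test_rate_estimator_unbiased_over_replicates():
    rng = np.random.default_rng(1)
    true_rate, epm, n_rep = 2.0, 4000.0, 600
    estimates = [
        sol1r_rate(int(rng.poisson(true_rate / 1000 * epm)), epm).rate_per_1000_epm
        for _ in range(n_rep)
    ]
    se = np.std(estimates) / np.sqrt(n_rep)
    assert abs(np.mean(estimates) - true_rate) < 4 * se


# ---------------------------------------------------------------------------
# exact comparison
# ---------------------------------------------------------------------------

def enumerate_exact_p(e1, e2, epm1, epm2):
    """Minlike two-sided binomial p-value by direct enumeration."""
    n, p = e1 + e2, epm1 / (epm1 + epm2)
    probs = [stats.binom.pmf(k, n, p) for k in range(n + 1)]
    obs = probs[e1]
    return sum(q for q in probs if q <= obs * (1 + 1e-12))


@pytest.mark.parametrize(
    "e1, e2, epm1, epm2",
    [(3, 3, 1000, 1000), (10, 0, 1000, 1000), (1, 9, 1000, 9000), (7, 2, 500, 1500), (0, 5, 2000, 1000)],
)
def test_compare_rates_matches_enumeration_oracle(e1, e2, epm1, epm2):
    assert compare_rates(e1, epm1, e2, epm2) == pytest.approx(
        enumerate_exact_p(e1, e2, epm1, epm2), rel=1e-9
    )


def test_compare_rates_worked_examples():
    assert compare_rates(3, 1000, 3, 1000) == pytest.approx(1.0)
    assert compare_rates(10, 1000, 0, 1000) == pytest.approx(2 * 0.5**10)
    assert compare_rates(1, 1000, 9, 9000) == pytest.approx(1.0)


def test_compare_rates_symmetry_and_empty_null():
    assert compare_rates(4, 800, 9, 2400) == pytest.approx(compare_rates(9, 2400, 4, 800))
    assert compare_rates(0, 1000, 0, 2000) == 1.0


# ---------------------------------------------------------------------------
# molecular time -> generations
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "m, expected",
    [
        (0, (0, 0)),
        (7.6, (2, 6)),  # exactly 2 generations fast; 2 + 2.8/0.7 = 6 slow
        (16, (9, 18)),  # 2 + 8.4/1.2 = 9 fast; 2 + 11.2/0.7 = 18 slow
    ],
)
def test_generation_conversion(m, expected):
    assert molecular_time_to_generations(m) == expected


def test_negative_molecular_time_rejected():
    with pytest.raises(ValueError):
        molecular_time_to_generations(-1)


# ---------------------------------------------------------------------------
# burden regression
# ---------------------------------------------------------------------------

def test_exact_line_recovers_slope():
    ages = np.array([30, 40, 50, 60, 70.0])
    result = burden_age_regression(0.028 * ages, ages)
    assert result.slope == pytest.approx(0.028)
    assert result.intercept == pytest.approx(0, abs=1e-12)


def test_constant_burden_zero_slope_and_identical_ages_rejected():
    ages = [30, 50, 70.0]
    assert burden_age_regression([2, 2, 2.0], ages).slope == pytest.approx(0, abs=1e-12)
    with pytest.raises(ValueError, match="identical"):
        burden_age_regression([1, 2, 3.0], [50, 50, 50.0])


def test_regression_ci_coverage():
    rng = np.random.default_rng(3)
    ages = np.linspace(30, 75, 19)
    true_slope = 0.03
    covered = 0
    n_rep = 200
    for _ in range(n_rep):
        burdens = true_slope * ages + rng.normal(0, 0.4, size=ages.size)
        result = burden_age_regression(burdens, ages)
        covered += result.ci_low <= true_slope <= result.ci_high
    assert 0.90 <= covered / n_rep <= 0.99


# ---------------------------------------------------------------------------
# tree-level aggregation
# ---------------------------------------------------------------------------

def test_stage_rates_aggregate_events_and_epm():
    tree = staged_tree()
    for node in tree.branches():
        node.epm = node.branch_length
    tree.root.children[0].sol1r_events = ["e1"]  # sh1
    for leaf in tree.leaves():
        leaf.sol1r_events = ["x"] if leaf.sample == "c1" else []
    ann = assign_stages(tree, {"sh1": True, "sh2": False}, {"tum": "cancer"})
    rates = stage_rates(tree, ann)
    assert rates["pregastrulation"].events == 1
    assert rates["pregastrulation"].epm == 5
    assert rates["ageing"].events == 1
    assert rates["ageing"].epm == 900 + 800 + 850
    assert rates["tumourigenesis"].events == 0
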