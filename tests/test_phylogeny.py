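"""Genotype matrix, mutation grouping and perfect-phylogeny reconstruction.

The reconstruction oracle enumerates every rooted binary topology on small
leaf sets, derives the mutation groups a topology implies, reconstructs, and
checks the tree's cluster map (sample set -> summed branch length) equals the
generating one.  Larger cases use randomized truth-recovery from simulated
trees.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from l1mosaic.phylogeny import (
    GenotypeMatrix,
    MutationGroup,
    build_genotype_matrix,
    group_mutations,
    reconstruct_from_matrix,
    reconstruct_tree,
)
from l1mosaic.synthetic_data import SimulationConfig, simulate_dataset


def matrices(vafs: dict[str, list[float]], depth: int = 20):
    vaf = pd.DataFrame(vafs).T
    vaf.columns = [f"s{i}" for i in range(vaf.shape[1])]
    depth_m = pd.DataFrame(depth, index=vaf.index, columns=vaf.columns)
    return vaf, depth_m


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

def test_vaf_above_point_one_scores_presence():
    vaf, depth = matrices({"m1": [0.45, 0.05, 0.40]})
    g = build_genotype_matrix(vaf, depth)
    assert list(g.matrix.loc["m1"]) == [1, 0, 1]


def test_germline_rows_present_in_all_samples_dropped():
    vaf, depth = matrices({"m1": [0.5, 0.5, 0.5], "m2": [0.5, 0.0, 0.0]})
    g = build_genotype_matrix(vaf, depth)
    assert g.dropped_germline == ["m1"]
    assert list(g.matrix.index) == ["m2"]


def test_vaf_exactly_point_one_is_absence():
    vaf, depth = matrices({"m1": [0.1, 0.5]})
    g = build_genotype_matrix(vaf, depth)
    assert list(g.matrix.loc["m1"]) == [0, 1]


def test_low_depth_and_low_max_vaf_rows_dropped_with_reasons():
    vaf, depth = matrices({"m1": [0.5, 0.0], "m2": [0.2, 0.2], "m3": [0.5, 0.4]})
    depth.loc["m3", "s1"] = 4
    g = build_genotype_matrix(vaf, depth)
    assert dict(g.dropped_filters) == {
        "m2": "max_vaf_below_threshold",
        "m3": "min_depth_all_samples",
    }
    assert list(g.matrix.index) == ["m1"]


def test_empty_matrix_after_filtering_is_explicit_empty():
    vaf, depth = matrices({"m1": [0.2, 0.1]})
    g = build_genotype_matrix(vaf, depth)
    assert len(g) == 0 and g.matrix.empty


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def test_groups_keyed_by_exact_sample_sets_with_subordination():
    vaf, depth = matrices({"m1": [0.5, 0.5, 0.0], "m2": [0.5, 0.5, 0.0], "m3": [0.5, 0.0, 0.0]})
    groups = {g.samples: g for g in group_mutations(build_genotype_matrix(vaf, depth))}
    ab = groups[frozenset({"s0", "s1"})]
    a = groups[frozenset({"s0"})]
    assert ab.size == 2 and a.size == 1
    assert a.is_subordinate_to(ab) and not ab.is_subordinate_to(a)


def test_private_rows_make_m_groups_without_subordination():
    vaf, depth = matrices({"m1": [0.5, 0, 0], "m2": [0, 0.5, 0], "m3": [0, 0, 0.5]})
    groups = group_mutations(build_genotype_matrix(vaf, depth))
    assert len(groups) == 3
    for a, b in itertools.permutations(groups, 2):
        assert not a.is_subordinate_to(b)


def test_overlapping_groups_are_incomparable():
    a = MutationGroup(frozenset({"A", "B"}), ["m1"])
    b = MutationGroup(frozenset({"B", "C"}), ["m2"])
    # neither subset holds in either direction: a conflict candidate
    assert not a.is_subordinate_to(b) and not b.is_subordinate_to(a)
    assert not (a.samples <= b.samples or b.samples <= a.samples)


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def groups_from(spec: dict[frozenset, int]) -> list[MutationGroup]:
    return [
        MutationGroup(key, [f"{'+'.join(sorted(key))}:{i}" for i in range(size)])
        for key, size in spec.items()
    ]


def test_caterpillar_reconstruction_with_total_length():
    spec = {
        frozenset("ABC"): 5,
        frozenset("AB"): 3,
        frozenset("A"): 2,
        frozenset("B"): 1,
        frozenset("C"): 4,
    }
    tree, report = reconstruct_tree(groups_from(spec), samples=["A", "B", "C"])
    assert tree.total_branch_length() == 15
    assert not report.conflicting
    clusters = tree.clusters()
    for key, size in spec.items():
        assert clusters[key] == size


def test_single_sample_single_branch():
    tree, _ = reconstruct_tree(groups_from({frozenset("A"): 7}), samples=["A"])
    assert tree.total_branch_length() == 7
    assert [l.sample for l in tree.leaves()] == ["A"]


def test_conflicting_group_discarded_greedily_and_reported():
    spec = {frozenset("AB"): 5, frozenset("BC"): 2, frozenset("A"): 1}
    tree, report = reconstruct_tree(groups_from(spec), samples=["A", "B", "C"])
    assert len(report.conflicting) == 1
    assert report.conflicting[0].samples == frozenset("BC")
    assert report.discarded_mutations == 2
    # conservation: retained mutations minus discarded
    assert tree.total_branch_length() == 8 - 2


def test_equal_size_conflicts_break_lexicographically():
    spec = {frozenset("AB"): 3, frozenset("BC"): 3}
    _, report = reconstruct_tree(groups_from(spec), samples=["A", "B", "C"])
    assert report.conflicting[0].samples == frozenset("BC")  # 'A+B' sorts first


def enumerate_rooted_binary_topologies(leaves: tuple[str, ...]):
    """All rooted binary topologies as frozensets of clusters (leaf subsets)."""
    if len(leaves) == 1:
        yield frozenset([frozenset(leaves)])
        return
    first, rest = leaves[0], leaves[1:]
    # choose the subset joining `first` under the root's left child
    for k in range(0, len(rest)):
        for combo in itertools.combinations(rest, k):
            left = (first, *combo)
            right = tuple(l for l in rest if l not in combo)
            if not right:
                continue
            # avoid double counting: fix first leaf on the left side
            for lt in enumerate_rooted_binary_topologies(left):
                for rt in enumerate_rooted_binary_topologies(right):
                    yield lt | rt | {frozenset(leaves)}


def test_reconstruction_matches_every_topology_exhaustively():
    """Exhaustive oracle over all rooted binary topologies for 3-5 leaves."""
    for n in (3, 4, 5):
        leaves = tuple("ABCDE"[:n])
        seen = set()
        for clusters in enumerate_rooted_binary_topologies(leaves):
            clusters = frozenset(c for c in clusters if c != frozenset(leaves))
            if clusters in seen:
                continue
            seen.add(clusters)
            # deterministic sizes, all distinct, so recovery is unambiguous
            spec = {c: 2 * i + 1 for i, c in enumerate(sorted(clusters, key=sorted))}
            tree, report = reconstruct_tree(groups_from(spec), samples=list(leaves))
            assert not report.conflicting
            got = {k: v for k, v in tree.clusters().items() if v > 0}
            assert got == {k: float(v) for k, v in spec.items()}
        # sanity on the enumeration itself: (2n-3)!! topologies
        expected = {3: 3, 4: 15, 5: 105}[n]
        assert len(seen) == expected


def test_recovery_from_simulated_observations_at_high_depth():
    """Truth-recovery: reconstructed clusters equal the simulated tree's."""
    cfg = SimulationConfig(n_clones=8, age_years=4, mean_depth=80.0, seed=17)
    truth, obs = simulate_dataset(cfg)
    tree, report, genotypes = reconstruct_from_matrix(obs.vaf_matrix(), obs.depth_matrix())
    assert not report.conflicting
    # zero-length truth branches leave no mutations to recover, so compare
    # the mutation-bearing clusters only
    truth_clusters = {k: v for k, v in truth.tree.clusters().items() if v > 0}
    got = {k: v for k, v in tree.clusters().items() if v > 0}
    assert set(got) == set(truth_clusters)
    # lengths agree up to rare read-sampling dropout
    for key in truth_clusters:
        assert abs(got[key] - truth_clusters[key]) <= max(2, 0.02 * truth_clusters[key])


def test_private_mutation_only_extends_terminal_branch():
    spec = {frozenset("AB"): 3, frozenset("A"): 2, frozenset("B"): 1}
    base, _ = reconstruct_tree(groups_from(spec), samples=["A", "B"])
    spec2 = dict(spec)
    spec2[frozenset("A")] = 3
    extended, _ = reconstruct_tree(groups_from(spec2), samples=["A", "B"])
    b0, b1 = base.clusters(), extended.clusters()
    assert b1[frozenset("A")] == b0[frozenset("A")] + 1
    assert {k: v for k, v in b0.items() if k != frozenset("A")} == {
        k: v for k, v in b1.items() if k != frozenset("A")
    }
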