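"""Clone phylogeny reconstruction from a binary somatic-mutation genotype matrix.

Somatic mutations shared by subsets of single-cell clones record the clones'
developmental ancestry.  Mutations are binarized per sample (VAF > 0.1 after
coverage and quality filters), grouped by the exact set of carrying samples,
and the groups' subset hierarchy is converted into a rooted tree whose branch
lengths are mutation-group sizes (molecular time).

Groups whose sample sets overlap without nesting cannot coexist on a tree
(a "conflict").  Conflicts are resolved greedily: groups are accepted in
decreasing size (ties broken lexicographically by sample-set key) and a group
incompatible with the accepted laminar family has its mutations discarded
from the tree and logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .tree import LineageTree, TreeNode

VAF_PRESENCE_THRESHOLD = 0.1
MIN_DEPTH = 5
MIN_MAX_VAF = 0.25


@dataclass
class GenotypeMatrix:
    """n mutations x m samples presence matrix, with VAF provenance retained."""

    matrix: pd.DataFrame  # int {0,1}, index = mutation ids, columns = samples
    vaf: pd.DataFrame  # same shape, float
    dropped_germline: list[str] = field(default_factory=list)
    dropped_filters: list[tuple[str, str]] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    def __len__(self) -> int:
        return len(self.matrix)


@dataclass
class MutationGroup:
    """All mutations carried by exactly the same set of samples."""

    samples: frozenset
    mutations: list[str]

    @property
    def size(self) -> int:
        return len(self.mutations)

    def is_subordinate_to(self, other: "MutationGroup") -> bool:
        """True iff this group's samples are a strict subset of the other's."""
        return self.samples < other.samples


def build_genotype_matrix(
    vaf_matrix: pd.DataFrame,
    depth_matrix: pd.DataFrame,
    *,
    presence_vaf: float = VAF_PRESENCE_THRESHOLD,
    min_depth: int = MIN_DEPTH,
    min_max_vaf: float = MIN_MAX_VAF,
) -> GenotypeMatrix:
    """Binarize per-sample VAFs into a genotype matrix.

    Rows (mutations) are dropped when depth falls below ``min_depth`` in any
    sample (genotyping unreliable at low coverage) or when no sample reaches
    ``min_max_vaf`` (likely artefact).  An entry is 1 iff VAF is strictly
    greater than ``presence_vaf``.  Rows present in *all* samples are germline
    and removed.  An empty result is returned as an empty matrix, not an error.
    """
    if not vaf_matrix.columns.equals(depth_matrix.columns) or not vaf_matrix.index.equals(
        depth_matrix.index
    ):
        raise ValueError("VAF and depth matrices must share index and columns")

    dropped_filters: list[tuple[str, str]] = []
    keep_rows = []
    for mut in vaf_matrix.index:
        depths = depth_matrix.loc[mut]
        vafs = vaf_matrix.loc[mut]
        if (depths < min_depth).any():
            dropped_filters.append((mut, "min_depth_all_samples"))
        elif vafs.max() < min_max_vaf:
            dropped_filters.append((mut, "max_vaf_below_threshold"))
        else:
            keep_rows.append(mut)

    vaf_kept = vaf_matrix.loc[keep_rows]
    binary = (vaf_kept > presence_vaf).astype(int)

    germline_mask = binary.sum(axis=1) == binary.shape[1]
    dropped_germline = list(binary.index[germline_mask])
    binary = binary.loc[~germline_mask]
    vaf_kept = vaf_kept.loc[binary.index]

    # rows with no carrier convey no lineage information
    empty_mask = binary.sum(axis=1) == 0
    for mut in binary.index[empty_mask]:
        dropped_filters.append((mut, "no_carrier_sample"))
    binary = binary.loc[~empty_mask]
    vaf_kept = vaf_kept.loc[binary.index]

    return GenotypeMatrix(
        matrix=binary,
        vaf=vaf_kept,
        dropped_germline=dropped_germline,
        dropped_filters=dropped_filters,
    )


def group_mutations(genotypes: GenotypeMatrix) -> list[MutationGroup]:
    """Group mutations by the exact set of samples carrying them."""
    groups: dict[frozenset, list[str]] = {}
    samples = np.array(genotypes.samples)
    values = genotypes.matrix.to_numpy()
    for mut, row in zip(genotypes.matrix.index, values):
        key = frozenset(samples[row == 1])
        groups.setdefault(key, []).append(mut)
    return [MutationGroup(samples=k, mutations=v) for k, v in groups.items()]


def _compatible(a: frozenset, b: frozenset) -> bool:
    """Two sample sets can coexist on a tree iff nested or disjoint."""
    return a <= b or b <= a or not (a & b)


@dataclass
class ReconstructionReport:
    accepted: list[MutationGroup] = field(default_factory=list)
    conflicting: list[MutationGroup] = field(default_factory=list)

    @property
    def discarded_mutations(self) -> int:
        return sum(g.size for g in self.conflicting)


def reconstruct_tree(
    groups: list[MutationGroup],
    samples: Optional[list[str]] = None,
) -> tuple[LineageTree, ReconstructionReport]:
    """Build the rooted tree best explaining the mutation-group hierarchy.

    Accepted groups form a laminar family; each group becomes a branch whose
    length is the group's mutation count; each sample attaches at the terminal
    node of the smallest accepted group containing it (private groups become
    the terminal branch itself).
    """
    if samples is None:
        all_samples: set = set()
        for g in groups:
            all_samples |= g.samples
        samples = sorted(all_samples)
    if not samples:
        raise ValueError("cannot reconstruct a tree with no samples")

    report = ReconstructionReport()
    ordered = sorted(groups, key=lambda g: (-g.size, tuple(sorted(g.samples))))
    accepted: list[MutationGroup] = []
    for group in ordered:
        if all(_compatible(group.samples, a.samples) for a in accepted):
            accepted.append(group)
        else:
            report.conflicting.append(group)
    report.accepted = accepted

    # merge duplicates (cannot occur from group_mutations, but defensively)
    by_key: dict[frozenset, MutationGroup] = {}
    for g in accepted:
        if g.samples in by_key:
            by_key[g.samples].mutations.extend(g.mutations)
        else:
            by_key[g.samples] = MutationGroup(g.samples, list(g.mutations))

    root = TreeNode(node_id="root")
    tree_nodes: dict[frozenset, TreeNode] = {frozenset(samples): root}

    # nest sets from largest to smallest under their smallest strict superset
    keys = sorted(by_key, key=lambda k: (-len(k), tuple(sorted(k))))
    for key in keys:
        if key == frozenset(samples):
            # mutations shared by every sample form the trunk below the zygote
            # (normally removed as germline upstream, but honoured if supplied)
            trunk = TreeNode(
                node_id="trunk",
                branch_length=by_key[key].size,
                mutations=list(by_key[key].mutations),
            )
            root.add_child(trunk)
            tree_nodes[key] = trunk
            continue
        parent_key = min((k for k in tree_nodes if key < k), key=len)
        node = TreeNode(
            node_id="+".join(sorted(key)),
            branch_length=by_key[key].size,
            mutations=list(by_key[key].mutations),
        )
        tree_nodes[parent_key].add_child(node)
        tree_nodes[key] = node

    # attach each sample at the terminal node of its smallest containing set
    for sample in samples:
        containing = [k for k in tree_nodes if sample in k]
        host_key = min(containing, key=len)
        host = tree_nodes[host_key]
        if host_key == frozenset([sample]) and not host.children:
            host.sample = sample
        else:
            leaf = TreeNode(node_id=sample, sample=sample, branch_length=0.0)
            host.add_child(leaf)

    # a singleton group node that gained children needs a separate leaf —
    # handled above; ensure every singleton host with children got one
    tree = LineageTree(root)
    assert sorted(l.sample for l in tree.leaves()) == sorted(samples)
    return tree, report


def reconstruct_from_matrix(
    vaf_matrix: pd.DataFrame,
    depth_matrix: pd.DataFrame,
    **kwargs,
) -> tuple[LineageTree, ReconstructionReport, GenotypeMatrix]:
    """Convenience: genotype matrix -> groups -> tree in one call."""
    genotypes = build_genotype_matrix(vaf_matrix, depth_matrix, **kwargs)
    groups = group_mutations(genotypes)
    tree, report = reconstruct_tree(groups, samples=genotypes.samples)
    return tree, report, genotypes
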