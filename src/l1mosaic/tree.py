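"""Rooted clone phylogeny with mutation-count branch lengths.

A :class:`LineageTree` is a rooted tree whose branches carry sets of somatic
mutations; the branch length is the number of mutations in the corresponding
mutation group, so depth in the tree is "molecular time".  Leaves correspond
to sequenced single-cell clones; internal nodes to ancestral (typically
embryonic) cells.  The same container is used for simulated truth trees and
for trees reconstructed from a genotype matrix.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional


@dataclass
class TreeNode:
    """One node; the branch is the edge from the parent to this node."""

    node_id: str
    parent: Optional["TreeNode"] = None
    children: list["TreeNode"] = field(default_factory=list)
    #: number of somatic mutations on the branch above this node
    branch_length: float = 0.0
    #: identifiers of the mutations assigned to this branch
    mutations: list[str] = field(default_factory=list)
    #: clone attached here (leaves only)
    sample: Optional[str] = None
    #: developmental stage of the branch (filled by rates_staging)
    stage: Optional[str] = None
    #: somatic L1 retrotransposition events on this branch
    sol1r_events: list = field(default_factory=list)
    #: endogenous point mutations on this branch (molecular clock)
    epm: float = 0.0
    #: cell generations spanned by this branch (simulated trees)
    generations: int = 0

    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.node_id!r}, len={self.branch_length}, sample={self.sample!r})"


class LineageTree:
    """Rooted developmental phylogeny of clones."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- traversal -----------------------------------------------------
    def nodes(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def branches(self) -> Iterator[TreeNode]:
        """All nodes except the root (each represents one branch)."""
        for node in self.nodes():
            if node.parent is not None:
                yield node

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes() if n.is_leaf()]

    def leaf_by_sample(self, sample: str) -> TreeNode:
        for leaf in self.leaves():
            if leaf.sample == sample:
                return leaf
        raise KeyError(f"no leaf for sample {sample!r}")

    def path_to_root(self, node: TreeNode) -> list[TreeNode]:
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        return path

    # -- molecular time ------------------------------------------------
    def molecular_time(self, node: TreeNode) -> float:
        """Mutation count accumulated from the zygote to the end of ``node``'s branch."""
        return sum(n.branch_length for n in self.path_to_root(node))

    def molecular_time_start(self, node: TreeNode) -> float:
        """Molecular time at the *start* of the branch above ``node``."""
        return self.molecular_time(node) - node.branch_length

    def mrca(self, a: TreeNode, b: TreeNode) -> TreeNode:
        ancestors = set(id(n) for n in self.path_to_root(a))
        for node in self.path_to_root(b):
            if id(node) in ancestors:
                return node
        raise ValueError("nodes share no ancestor (disconnected tree)")

    def mrca_time(self, sample_a: str, sample_b: str) -> float:
        """Molecular time of the most recent common ancestor of two clones."""
        node = self.mrca(self.leaf_by_sample(sample_a), self.leaf_by_sample(sample_b))
        return self.molecular_time(node)

    def total_branch_length(self) -> float:
        return sum(n.branch_length for n in self.branches())

    # -- cluster view (for oracle comparisons) -------------------------
    def clusters(self) -> dict[frozenset, float]:
        """Map each branch's leaf-sample set to its branch length.

        Two trees over the same samples are topologically identical with the
        same mutation assignment iff their cluster maps are equal.
        """
        out: dict[frozenset, float] = {}
        for node in self.branches():
            samples = frozenset(
                leaf.sample for leaf in self._subtree_leaves(node) if leaf.sample is not None
            )
            out[samples] = out.get(samples, 0.0) + node.branch_length
        return out

    def _subtree_leaves(self, node: TreeNode) -> list[TreeNode]:
        stack, leaves = [node], []
        while stack:
            n = stack.pop()
            if n.is_leaf():
                leaves.append(n)
            stack.extend(n.children)
        return leaves

    # -- serialization -------------------------------------------------
    def to_newick(self) -> str:
        return self._newick(self.root) + ";"

    def _newick(self, node: TreeNode) -> str:
        label = _quote_label(node.sample or node.node_id)
        if node.is_leaf():
            body = label
        else:
            inner = ",".join(self._newick(c) for c in sorted(node.children, key=_child_key))
            body = f"({inner}){label}"
        if node.parent is None:
            return body
        return f"{body}:{_fmt_len(node.branch_length)}"

    @classmethod
    def from_newick(cls, text: str) -> "LineageTree":
        """Parse the subset of newick this package writes (labels + lengths)."""
        s = text.strip()
        if s.endswith(";"):
            s = s[:-1]
        counter = itertools.count()
        pos = 0

        def parse_label_and_length(node: TreeNode) -> None:
            nonlocal pos
            if pos < len(s) and s[pos] == "'":
                match = re.match(r"'((?:[^']|'')*)'", s[pos:])
                node.node_id = match.group(1).replace("''", "'")
                pos += match.end()
            else:
                match = re.match(r"[^(),:;]*", s[pos:])
                if match.group(0):
                    node.node_id = match.group(0)
                pos += match.end()
            if pos < len(s) and s[pos] == ":":
                match = re.match(r":([0-9.eE+\-]+)", s[pos:])
                node.branch_length = float(match.group(1))
                pos += match.end()

        def parse_node() -> TreeNode:
            nonlocal pos
            node = TreeNode(node_id=f"n{next(counter)}")
            if pos < len(s) and s[pos] == "(":
                pos += 1
                while True:
                    node.add_child(parse_node())
                    if pos < len(s) and s[pos] == ",":
                        pos += 1
                    else:
                        break
                if pos >= len(s) or s[pos] != ")":
                    raise ValueError("unbalanced parentheses in newick string")
                pos += 1
            parse_label_and_length(node)
            if node.is_leaf():
                node.sample = node.node_id
            return node

        root = parse_node()
        if pos != len(s):
            raise ValueError(f"trailing characters in newick string at offset {pos}")
        return cls(root)


def _quote_label(label: str) -> str:
    if re.search(r"[\s(),:;]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_len(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else f"{x:g}"


def _child_key(node: TreeNode) -> str:
    return node.sample or node.node_id
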