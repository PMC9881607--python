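"""Guide-tree machinery for embedded-reference benchmarks.

A guide-tree encodes the order of profile merges in progressive alignment.
When reference sequences with known structure are embedded in a large family,
the sum-of-pairs score only probes the *effective* alignment: the smallest
profile that contains every reference, produced by the smallest clade of the
guide-tree subtending all of them (the *effective guide-tree*).  This module
computes that clade, and re-roots trees so that its leaf count can be
guaranteed to exceed a configurable minimum — the device that makes SP scores
of embedded references comparable across aligners.

Trees are plain parent/child node structures with optional branch lengths.
Only the topology matters for effective-size arguments; branch lengths are
carried along (and split 50/50 when a new root lands on an edge) purely so
that round-trips through Newick are faithful.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional


class TreeError(ValueError):
    """Structural problem with a guide-tree or a tree operation."""


class UnrootedTreeError(TreeError):
    """Operation requires a rooted tree."""


class TreeNode:
    """A node of a guide-tree; leaves carry sequence-id labels."""

    __slots__ = ("label", "children", "parent", "length")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        self.length = length

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        """Pre-order traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]

    def leaf_count(self) -> int:
        return sum(1 for n in self.walk() if n.is_leaf)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {kind} {self.label!r}>"


class GuideTree:
    """Rooted or unrooted tree with uniquely labeled leaves.

    A tree is *rooted* when its root has exactly two children (the binary
    merge order of progressive alignment); a trifurcating root marks the
    conventional unrooted Newick dialect.
    """

    def __init__(self, root: TreeNode, rooted: Optional[bool] = None):
        self.root = root
        self.rooted = (len(root.children) == 2) if rooted is None else rooted
        self._validate()

    def _validate(self) -> None:
        labels: set[str] = set()
        for node in self.root.walk():
            if node.is_leaf:
                if not node.label:
                    raise TreeError("unlabeled leaf")
                if node.label in labels:
                    raise TreeError(f"duplicate leaf label {node.label!r}")
                labels.add(node.label)
            elif node is not self.root and len(node.children) < 2:
                raise TreeError("internal node with a single child")
        if not self.root.is_leaf and len(self.root.children) < 2:
            raise TreeError("root must have at least two children")

    # -- basic queries ----------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return self.root.leaf_count()

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    def leaf(self, label: str) -> TreeNode:
        for node in self.root.leaves():
            if node.label == label:
                return node
        raise TreeError(f"no leaf labeled {label!r}")

    def is_binary(self) -> bool:
        return all(
            len(n.children) == 2 for n in self.root.walk() if not n.is_leaf
        )

    def copy(self) -> "GuideTree":
        new_root = TreeNode(self.root.label, self.root.length)
        stack = [(self.root, new_root)]
        while stack:
            old, new = stack.pop()
            for child in old.children:
                stack.append((child, new.add(TreeNode(child.label, child.length))))
        return GuideTree(new_root, rooted=self.rooted)

    # -- Newick serialization --------------------------------------------

    def to_newick(self) -> str:
        # explicit stack: trees from real aligners can be deep enough to
        # exceed the interpreter recursion limit
        out: list[str] = []
        stack: list[object] = [self.root]
        while stack:
            item = stack.pop()
            if isinstance(item, str):
                out.append(item)
                continue
            node = item
            suffix = "" if node.length is None else ":" + repr(float(node.length))
            if node.is_leaf:
                out.append(_quote_label(node.label) + suffix)
            else:
                stack.append(")" + suffix)
                for i, child in enumerate(reversed(node.children)):
                    stack.append(child)
                    if i < len(node.children) - 1:
                        stack.append(",")
                stack.append("(")
        return "".join(out) + ";"

    def splits(self) -> set[frozenset[str]]:
        """Unrooted split set: for every internal edge, the smaller-or-
        lexicographically-first side's leaf-label set.  Invariant under
        re-rooting, so it certifies topology preservation."""
        all_labels = frozenset(self.leaf_labels())
        out: set[frozenset[str]] = set()
        for node in self.root.walk():
            if node is self.root:
                continue
            below = frozenset(n.label for n in node.leaves())
            if 1 < len(below) < len(all_labels) - 1:
                other = all_labels - below
                out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
        return out

    def __repr__(self) -> str:  # pragma: no cover
        kind = "rooted" if self.rooted else "unrooted"
        return f"<GuideTree {kind}, {self.n_leaves} leaves>"


def _quote_label(label: str) -> str:
    if any(c in label for c in "()[]{}:;,= \t\n'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Effective subtree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectiveSubtreeResult:
    """MRCA clade of the reference leaves and its size."""

    mrca: TreeNode
    effective_size: int
    total_size: int

    @property
    def ratio(self) -> float:
        return self.effective_size / self.total_size


def effective_subtree(tree: GuideTree, ref_ids: Iterable[str]) -> EffectiveSubtreeResult:
    """Smallest clade of a rooted tree containing all reference leaves.

    The leaf count of this clade is the *effective guide-tree size*: only
    these sequences can influence the relative alignment of the references
    under progressive alignment.
    """
    refs = list(dict.fromkeys(ref_ids))
    if not refs:
        raise TreeError("need at least one reference id")
    if not tree.rooted:
        raise UnrootedTreeError(
            "effective subtree is defined for rooted trees; root the tree first"
        )
    leaf_map = {n.label: n for n in tree.root.leaves()}
    for r in refs:
        if r not in leaf_map:
            raise TreeError(f"reference id {r!r} is not a leaf of the tree")

    # path of first reference up to the root; MRCA is the deepest node of
    # that path which is an ancestor of every other reference
    path: list[TreeNode] = []
    node: Optional[TreeNode] = leaf_map[refs[0]]
    while node is not None:
        path.append(node)
        node = node.parent
    index = {id(n): i for i, n in enumerate(path)}

    mrca_idx = 0
    for r in refs[1:]:
        node = leaf_map[r]
        while id(node) not in index:
            node = node.parent
            assert node is not None
        mrca_idx = max(mrca_idx, index[id(node)])

    mrca = path[mrca_idx]
    return EffectiveSubtreeResult(
        mrca=mrca,
        effective_size=mrca.leaf_count(),
        total_size=tree.n_leaves,
    )


# ---------------------------------------------------------------------------
# Re-rooting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RerootConfig:
    """Search configuration for the minimum-effective-size guarantee.

    ``min_effective_size`` defaults to 900, the published threshold for
    families of 1000 taxa.  ``strategy`` is ``"first-passing"`` (seeded
    random-order search, first rooting whose effective size passes) or
    ``"maximize"`` (deterministic exhaustive maximum, enumeration-order
    tie-break).
    """

    min_effective_size: int = 900
    strategy: str = "first-passing"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_effective_size < 1:
            raise TreeError("min_effective_size must be >= 1")
        if self.strategy not in ("first-passing", "maximize"):
            raise TreeError(f"unknown strategy {self.strategy!r}")


class _Adjacency:
    """Undirected view of a tree, root suppressed when binary-rooted."""

    def __init__(self, tree: GuideTree):
        nodes = list(tree.root.walk())
        self.ids = {id(n): i for i, n in enumerate(nodes)}
        self.labels = {self.ids[id(n)]: n.label for n in nodes if n.is_leaf}
        self.neighbors: dict[int, list[int]] = {self.ids[id(n)]: [] for n in nodes}
        self.edge_len: dict[tuple[int, int], Optional[float]] = {}
        suppress = tree.rooted and len(tree.root.children) == 2
        root_id = self.ids[id(tree.root)]
        for n in nodes:
            for c in n.children:
                if suppress and n is tree.root:
                    continue
                self._connect(self.ids[id(n)], self.ids[id(c)], c.length)
        if suppress:
            c1, c2 = tree.root.children
            l1, l2 = c1.length, c2.length
            combined = None if (l1 is None and l2 is None) else (l1 or 0.0) + (l2 or 0.0)
            self._connect(self.ids[id(c1)], self.ids[id(c2)], combined)
            del self.neighbors[root_id]

    def _connect(self, a: int, b: int, length: Optional[float]) -> None:
        self.neighbors[a].append(b)
        self.neighbors[b].append(a)
        self.edge_len[(min(a, b), max(a, b))] = length

    def edges(self) -> list[tuple[int, int]]:
        return sorted(self.edge_len)

    def root_at_edge(self, edge: tuple[int, int]) -> GuideTree:
        a, b = edge
        length = self.edge_len[edge]
        half = None if length is None else length / 2.0
        root = TreeNode()
        root.add(_build_iterative(self, a, b, half))
        root.add(_build_iterative(self, b, a, half))
        return GuideTree(root, rooted=True)


def _build_iterative(adj: _Adjacency, start: int, avoid: int,
                     start_length: Optional[float]) -> TreeNode:
    first = TreeNode(adj.labels.get(start), start_length)
    stack: list[tuple[int, int, TreeNode]] = [(start, avoid, first)]
    while stack:
        nid, parent, node = stack.pop()
        for nb in adj.neighbors[nid]:
            if nb == parent:
                continue
            key = (min(nid, nb), max(nid, nb))
            child = TreeNode(adj.labels.get(nb), adj.edge_len[key])
            node.add(child)
            stack.append((nb, nid, child))
    return first


def enumerate_rootings(tree: GuideTree) -> Iterator[tuple[tuple[int, int], GuideTree]]:
    """Yield every rooting of the unrooted version of ``tree``.

    One candidate per edge: 2n-3 for a binary tree with n leaves.  Each
    candidate preserves the leaf set and the unrooted split set; branch
    lengths, when present, are halved across the new root.
    """
    if tree.n_leaves < 2:
        raise TreeError("need at least two leaves to enumerate rootings")
    adj = _Adjacency(tree)
    for edge in adj.edges():
        yield edge, adj.root_at_edge(edge)


def resolve_multifurcations(tree: GuideTree, seed: int = 0) -> GuideTree:
    """Binarize multifurcating nodes arbitrarily but deterministically.

    Progressive alignment merges are pairwise, so effective-size arguments
    assume binary trees; aligners occasionally emit multifurcations.  Child
    order is shuffled with ``seed`` then folded pairwise; inserted edges get
    length 0 when the tree carries lengths.
    """
    out = tree.copy()
    has_lengths = any(
        n.length is not None for n in out.root.walk() if n is not out.root
    )
    fill = 0.0 if has_lengths else None
    rng = random.Random(seed)
    for node in list(out.root.walk()):
        if len(node.children) <= 2:
            continue
        kids = node.children[:]
        rng.shuffle(kids)
        while len(kids) > 2:
            a = kids.pop(0)
            b = kids.pop(0)
            joint = TreeNode(None, fill)
            joint.add(a)
            joint.add(b)
            kids.append(joint)
        node.children = []
        for k in kids:
            node.add(k)
    return GuideTree(out.root, rooted=(len(out.root.children) == 2))


def reroot_for_effective_size(
    tree: GuideTree,
    ref_ids: Iterable[str],
    config: Optional[RerootConfig] = None,
) -> tuple[GuideTree, EffectiveSubtreeResult]:
    """Find a rooting whose effective size meets ``config.min_effective_size``.

    Rooting on any edge of the minimal subtree spanning the references
    places references in both root children, so the effective size equals
    the total leaf count; a passing rooting therefore always exists for any
    threshold up to the leaf count, and the search cannot fail on valid
    input.

    ``first-passing`` scans candidate rootings in seeded random order and
    returns the first that passes (if the input is already rooted and
    passes, it is returned unchanged).  ``maximize`` returns the candidate
    with the largest effective size, ties broken by enumeration order.
    """
    config = config or RerootConfig()
    refs = list(dict.fromkeys(ref_ids))
    if len(refs) < 2:
        raise TreeError("need at least two reference ids to re-root")
    labels = set(tree.leaf_labels())
    for r in refs:
        if r not in labels:
            raise TreeError(f"reference id {r!r} is not a leaf of the tree")
    n = tree.n_leaves
    if config.min_effective_size > n:
        raise TreeError(
            f"min_effective_size {config.min_effective_size} exceeds leaf count {n}"
        )

    work = tree if tree.is_binary() else resolve_multifurcations(tree, seed=config.seed)

    if config.strategy == "first-passing":
        if work.rooted:
            current = effective_subtree(work, refs)
            if current.effective_size >= config.min_effective_size:
                return work, current
        adj = _Adjacency(work)
        edges = adj.edges()
        rng = random.Random(config.seed)
        rng.shuffle(edges)
        for edge in edges:
            candidate = adj.root_at_edge(edge)
            result = effective_subtree(candidate, refs)
            if result.effective_size >= config.min_effective_size:
                return candidate, result
        raise AssertionError(
            "no passing rooting found; the spanning-subtree guarantee was violated"
        )  # pragma: no cover - unreachable for valid input

    best: Optional[tuple[GuideTree, EffectiveSubtreeResult]] = None
    for _, candidate in enumerate_rootings(work):
        result = effective_subtree(candidate, refs)
        if best is None or result.effective_size > best[1].effective_size:
            best = (candidate, result)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Balance diagnostics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceBalance:
    """How evenly the references are spread over the guide-tree.

    ``balance`` is min/max over the leaf counts of the reference-containing
    children of the overall MRCA; ``pair_splits`` gives, for every reference
    pair, the sizes of the two child clades of their MRCA that hold them.
    """

    effective: EffectiveSubtreeResult
    balance: float
    pair_splits: dict[tuple[str, str], tuple[int, int]]

    @property
    def ratio(self) -> float:
        return self.effective.ratio


def reference_balance(tree: GuideTree, ref_ids: Iterable[str]) -> ReferenceBalance:
    refs = sorted(dict.fromkeys(ref_ids))
    if len(refs) < 2:
        raise TreeError("need at least two reference ids")
    overall = effective_subtree(tree, refs)

    ref_set = set(refs)
    child_sizes = []
    for child in overall.mrca.children:
        below = {n.label for n in child.leaves()}
        if below & ref_set:
            child_sizes.append(len(below))
    balance = min(child_sizes) / max(child_sizes)

    pair_splits: dict[tuple[str, str], tuple[int, int]] = {}
    for i, a in enumerate(refs):
        for b in refs[i + 1:]:
            pair = effective_subtree(tree, [a, b])
            size_a = size_b = 0
            for child in pair.mrca.children:
                below = {n.label for n in child.leaves()}
                if a in below:
                    size_a = len(below)
                if b in below:
                    size_b = len(below)
            pair_splits[(a, b)] = (size_a, size_b)

    return ReferenceBalance(effective=overall, balance=balance, pair_splits=pair_splits)
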