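"""Unrooted phylogenetic trees: Newick I/O, bipartition algebra, NNI moves,
majority-rule consensus and bipartition-frequency convergence diagnostics.

Trees are stored internally in rooted form (a root node of degree >= 3 for
unrooted semantics); rooted display is a presentation concern only.  Branch
lengths are expected substitutions per site; per-internal-edge supports are
kept on a 0-100 scale regardless of whether they entered as bootstrap
percentages or posterior probabilities (the provenance is recorded on the
tree as ``support_kind``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Node",
    "Tree",
    "Bipartition",
    "TreeSample",
    "NewickError",
    "TreeError",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "splits_compatible",
    "is_compatible",
    "rf_distance",
    "nni_neighbors",
    "majority_consensus",
    "bipartition_maxdiff",
    "resolve_polytomies",
    "restrict",
]


class NewickError(ValueError):
    """Malformed Newick input; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)


class TreeError(ValueError):
    """Structural or taxon-set violation on a tree operation."""


class Node:
    """A tree node.  Leaves carry a taxon ``name``; internal edges may carry
    a ``support`` value (0-100 scale).  ``length`` is the length of the edge
    to the parent; ``None`` means "not stated" (a sentinel, never 0)."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None,
                 support: float | None = None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, len={self.length}, k={len(self.children)})"


class Tree:
    """A phylogenetic tree over uniquely named leaves.

    Parameters
    ----------
    root : Node
        Root of the (possibly derooted) node structure.
    rooted : bool
        Whether the tree is to be interpreted as rooted.  Unrooted trees are
        stored with a root of degree >= 3 (for n >= 3 leaves).
    support_kind : str
        Provenance of the support values: ``"bp"`` (bootstrap percentage),
        ``"pp"`` (posterior probability, rescaled to 0-100) or ``"none"``.
    """

    def __init__(self, root: Node, rooted: bool = False, support_kind: str = "none"):
        self.root = root
        self.rooted = rooted
        self.support_kind = support_kind
        self._validate()

    # -- basic structure ---------------------------------------------------

    def _validate(self) -> None:
        names = [n.name for n in self.leaves()]
        if len(set(names)) != len(names):
            dup = sorted({x for x in names if names.count(x) > 1})
            raise TreeError(f"duplicate leaf labels: {dup}")
        for node in self.preorder():
            if node.length is not None and node.length < 0:
                raise TreeError(f"negative branch length {node.length} on edge above "
                                f"{node.name or 'an internal node'}")

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(n.name for n in self.leaves())

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def internal_edges(self) -> list[Node]:
        """Internal edges, each identified by its child node (non-leaf,
        non-root), in preorder."""
        return [n for n in self.preorder()
                if n is not self.root and not n.is_leaf]

    def is_binary(self) -> bool:
        """True for a fully resolved tree: unrooted => root degree 3 and all
        other internal nodes with exactly 2 children; rooted => root with 2."""
        want_root = 2 if self.rooted else (3 if self.n_leaves > 2 else self.n_leaves)
        if len(self.root.children) != want_root:
            return False
        return all(len(n.children) == 2 for n in self.preorder()
                   if n is not self.root and not n.is_leaf)

    def copy(self) -> "Tree":
        def rec(node: Node) -> Node:
            c = Node(node.name, node.length, node.support)
            for ch in node.children:
                c.add(rec(ch))
            return c
        return Tree(rec(self.root), rooted=self.rooted, support_kind=self.support_kind)

    def deroot(self) -> "Tree":
        """Merge a degree-2 root so the tree has unrooted semantics."""
        t = self.copy()
        while len(t.root.children) == 2 and not all(c.is_leaf for c in t.root.children):
            a, b = t.root.children
            keep, fold = (a, b) if not a.is_leaf else (b, a)
            # fold's edge merges into keep's children list
            if fold.length is None and keep.length is None:
                fold.length = None
            else:
                fold.length = (fold.length or 0.0) + (keep.length or 0.0)
            if fold.support is None:
                fold.support = keep.support  # the surviving copy of the root edge
            t.root = keep
            keep.parent = None
            keep.length = None
            keep.support = None
            keep.add(fold)
        t.rooted = False
        return t

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.preorder() if n is not self.root)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({self.n_leaves} leaves, rooted={self.rooted})"


@dataclass(frozen=True)
class Bipartition:
    """A two-block partition of a taxon set induced by deleting one edge.

    Canonicalized so equality is order-independent: ``block`` is the side
    that does *not* contain the lexicographically smallest taxon.
    """

    taxa: frozenset
    block: frozenset

    @staticmethod
    def make(side: Iterable[str], taxa: Iterable[str]) -> "Bipartition":
        taxa = frozenset(taxa)
        side = frozenset(side)
        if not side or not (taxa - side):
            raise TreeError("both blocks of a bipartition must be non-empty")
        if not side <= taxa:
            raise TreeError("bipartition block is not a subset of the taxon set")
        anchor = min(taxa)
        block = side if anchor not in side else taxa - side
        return Bipartition(taxa=taxa, block=block)

    @property
    def blocks(self) -> tuple[frozenset, frozenset]:
        return (self.taxa - self.block, self.block)

    @property
    def is_trivial(self) -> bool:
        return min(len(b) for b in self.blocks) <= 1

    def __str__(self) -> str:
        a, b = self.blocks
        return ",".join(sorted(a)) + " | " + ",".join(sorted(b))


@dataclass
class TreeSample:
    """A collection of trees over an identical taxon set (bootstrap
    replicates or MCMC samples), implicitly equally weighted."""

    trees: list = field(default_factory=list)

    def __post_init__(self):
        if self.trees:
            taxa = self.trees[0].taxa
            for i, t in enumerate(self.trees):
                if t.taxa != taxa:
                    raise TreeError(f"tree {i} has a different leaf set")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    @property
    def taxa(self) -> frozenset:
        if not self.trees:
            raise TreeError("empty tree sample")
        return self.trees[0].taxa

    def split_frequencies(self) -> dict:
        """Frequency (0-1) of each non-trivial bipartition in the sample."""
        counts: dict[Bipartition, int] = {}
        for t in self.trees:
            for b in bipartitions(t):
                counts[b] = counts.get(b, 0) + 1
        n = len(self.trees)
        return {b: c / n for b, c in counts.items()}


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _tokenize_label(text: str, i: int) -> tuple[str, int]:
    if i < len(text) and text[i] in "'\"":
        q = text[i]
        j = text.find(q, i + 1)
        if j < 0:
            raise NewickError("unterminated quoted label", i)
        return text[i + 1:j], j + 1
    j = i
    while j < len(text) and text[j] not in "(),:;[":
        j += 1
    return text[i:j].strip(), j


def parse_newick(text: str, support_scale: str = "bp", deroot: bool = True,
                 floor_negative: bool = False) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Internal node labels that parse as numbers are interpreted as support
    values; ``support_scale='pp'`` treats them as posterior probabilities on
    0-1 and rescales to 0-100.  Missing branch lengths stay ``None`` (a
    sentinel, not zero).  Negative lengths are rejected unless
    ``floor_negative`` is set, in which case they are clamped to 0 (used for
    distance-method outputs).

    Raises
    ------
    NewickError
        On malformed input, with the character offset.
    TreeError
        On duplicate leaf labels or negative branch lengths.
    """
    s = text.strip()
    if not s:
        raise NewickError("empty Newick string", 0)
    if not s.endswith(";"):
        raise NewickError("missing terminating ';'", len(text) - 1)
    i = 0
    scale = 100.0 if support_scale == "pp" else 1.0

    def parse_clade(i: int) -> tuple[Node, int]:
        node = Node()
        if s[i] == "(":
            i += 1
            while True:
                child, i = parse_clade(i)
                node.add(child)
                if i >= len(s):
                    raise NewickError("unbalanced parenthesis", i)
                if s[i] == ",":
                    i += 1
                    continue
                if s[i] == ")":
                    i += 1
                    break
                raise NewickError(f"unexpected character {s[i]!r}", i)
            label, i = _tokenize_label(s, i)
            if label:
                try:
                    node.support = float(label) * scale
                except ValueError:
                    node.name = label  # named internal node, kept as-is
        else:
            label, i = _tokenize_label(s, i)
            if not label:
                raise NewickError("expected a taxon label", i)
            node.name = label  # names are opaque; no underscore unescaping
        if i < len(s) and s[i] == ":":
            j = i + 1
            k = j
            while k < len(s) and s[k] not in "(),;":
                k += 1
            try:
                length = float(s[j:k])
            except ValueError:
                raise NewickError(f"bad branch length {s[j:k]!r}", j)
            if length < 0:
                if floor_negative:
                    length = 0.0
                else:
                    raise TreeError(f"negative branch length {length} in Newick input")
            node.length = length
            i = k
        return node, i

    root, i = parse_clade(0)
    if i >= len(s) or s[i] != ";":
        raise NewickError("trailing characters before ';'", i)
    kind = "none"
    if any(n.support is not None for n in _preorder_node(root)):
        kind = support_scale if support_scale in ("bp", "pp") else "bp"
    tree = Tree(root, rooted=not deroot, support_kind=kind)
    if deroot and len(root.children) == 2 and tree.n_leaves >= 3:
        tree = tree.deroot()
    return tree


def _preorder_node(node: Node) -> Iterator[Node]:
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def _escape(name: str) -> str:
    return name.replace(" ", "_")


def write_newick(t: Tree, lengths: bool = True, supports: bool = True,
                 length_fmt: str = "%.6g") -> str:
    """Serialize a tree to Newick.  Whitespace in taxon names is
    underscore-escaped; supports are written as internal node labels."""

    def rec(node: Node) -> str:
        if node.is_leaf:
            out = _escape(node.name)
        else:
            out = "(" + ",".join(rec(c) for c in node.children) + ")"
            if supports and node.support is not None:
                out += ("%g" % node.support)
            elif node.name:
                out += _escape(node.name)
        if lengths and node.length is not None and node.parent is not None:
            out += ":" + (length_fmt % node.length)
        return out

    return rec(t.root) + ";"


# ---------------------------------------------------------------------------
# Bipartition algebra
# ---------------------------------------------------------------------------

def bipartitions(t: Tree) -> set:
    """The set of non-trivial bipartitions of ``t`` (one per internal edge).

    For an unrooted binary tree on n >= 4 leaves this has exactly n-3
    elements.  Trees with fewer than 4 leaves yield the empty set.
    """
    taxa = t.taxa
    if len(taxa) < 4:
        return set()
    out = set()
    below: dict[int, frozenset] = {}
    for node in t.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            if node is not t.root:
                b = below[id(node)]
                if 1 < len(b) < len(taxa) - 1:
                    out.add(Bipartition.make(b, taxa))
    return out


def splits_compatible(b1: Bipartition, b2: Bipartition) -> bool:
    """Pairwise split compatibility: true iff one of the four block
    intersections is empty (both splits can coexist on one tree)."""
    if b1.taxa != b2.taxa:
        raise TreeError("bipartitions are over different taxon sets")
    a1, a2 = b1.blocks
    c1, c2 = b2.blocks
    return (not (a1 & c1) or not (a1 & c2) or not (a2 & c1) or not (a2 & c2))


def is_compatible(b: Bipartition, t: Tree) -> bool:
    """True iff ``b`` could be added to ``t``'s split set without
    contradiction, i.e. it is pairwise compatible with every split of ``t``."""
    if b.taxa != t.taxa:
        raise TreeError(
            "bipartition taxon set differs from the tree's leaf set; restrict "
            "the tree (or the bipartition) to the shared taxa first")
    return all(splits_compatible(b, s) for s in bipartitions(t))


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    two trees' non-trivial bipartition sets.  0 iff topologically identical."""
    if t1.taxa != t2.taxa:
        raise TreeError("trees have different leaf sets")
    return len(bipartitions(t1) ^ bipartitions(t2))


# ---------------------------------------------------------------------------
# NNI
# ---------------------------------------------------------------------------

def _find_by_path(t: Tree, path: tuple[int, ...]) -> Node:
    node = t.root
    for k in path:
        node = node.children[k]
    return node


def _node_path(t: Tree, target: Node) -> tuple[int, ...]:
    path: list[int] = []
    node = target
    while node.parent is not None:
        path.append(node.parent.children.index(node))
        node = node.parent
    return tuple(reversed(path))


def nni_neighbors(t: Tree) -> list:
    """All nearest-neighbor-interchange neighbors of an unrooted binary tree.

    Two neighbors per internal edge, 2(n-3) in total; each differs from
    ``t`` by exactly one bipartition (RF distance 2).  Branch lengths travel
    with their subtrees; the central edge keeps its length.
    """
    if not t.is_binary():
        raise TreeError("NNI requires a binary tree; resolve polytomies first")
    out = []
    for edge_child in t.internal_edges():
        path_v = _node_path(t, edge_child)
        parent = edge_child.parent
        # a fixed neighbor of the parent on the far side of the edge
        sib = next(c for c in parent.children if c is not edge_child)
        path_s = _node_path(t, sib)
        for which in (0, 1):
            c = t.copy()
            v = _find_by_path(c, path_v)
            s = _find_by_path(c, path_s)
            p = v.parent
            x = v.children[which]
            # swap x <-> s across the internal edge
            v.children[v.children.index(x)] = s
            p.children[p.children.index(s)] = x
            x.parent, s.parent = p, v
            # the moved subtrees invalidate supports on the central edge
            v.support = None
            out.append(c)
    return out


def resolve_polytomies(t: Tree, seed: int | None = None) -> Tree:
    """Randomly refine all polytomies to obtain a binary tree (new internal
    edges get zero length and no support).  Deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    t = t.copy()
    for node in list(t.preorder()):
        want = 3 if (node is t.root and not t.rooted and t.n_leaves > 2) else 2
        while len(node.children) > want:
            idx = sorted(rng.choice(len(node.children), size=2, replace=False))
            a = node.children[idx[1]]
            b = node.children[idx[0]]
            node.children = [c for c in node.children if c is not a and c is not b]
            merged = Node(length=0.0)
            merged.add(b)
            merged.add(a)
            node.add(merged)
    return t


# ---------------------------------------------------------------------------
# Consensus and convergence diagnostics
# ---------------------------------------------------------------------------

def majority_consensus(sample: TreeSample, threshold: float = 0.5,
                       greedy: bool = False) -> Tree:
    """Majority-rule consensus of a tree sample.

    Contains exactly the bipartitions whose frequency exceeds ``threshold``
    (strict), each annotated with frequency x 100 as support; the result may
    be multifurcating.  With ``greedy=True``, remaining splits are added in
    decreasing frequency order when compatible with everything accepted
    (greedy extension).
    """
    if len(sample) == 0:
        raise TreeError("cannot take the consensus of an empty sample")
    freqs = sample.split_frequencies()
    taxa = sorted(sample.taxa)
    accepted: list[tuple[Bipartition, float]] = []
    ordered = sorted(freqs.items(), key=lambda kv: (-kv[1], str(kv[0])))
    for b, f in ordered:
        if f > threshold:
            accepted.append((b, f))
        elif greedy and all(splits_compatible(b, a) for a, _ in accepted):
            accepted.append((b, f))

    # build a star tree then insert blocks, largest first
    anchor = taxa[0]
    root = Node()
    for name in taxa:
        root.add(Node(name=name))
    tree = Tree(root, rooted=False, support_kind="bp")
    leafsets: dict[int, frozenset] = {id(n): frozenset([n.name]) if n.is_leaf else None
                                      for n in tree.preorder()}

    def subtree_set(node: Node) -> frozenset:
        v = leafsets.get(id(node))
        if v is None:
            v = frozenset().union(*(subtree_set(c) for c in node.children))
            leafsets[id(node)] = v
        return v

    for b, f in sorted(accepted, key=lambda kv: -max(len(x) for x in kv[0].blocks)):
        block = b.block if anchor not in b.block else b.taxa - b.block
        # deepest node whose subtree covers the block
        node = tree.root
        while True:
            nxt = next((c for c in node.children
                        if not c.is_leaf and block <= subtree_set(c)), None)
            if nxt is None:
                break
            node = nxt
        members = [c for c in node.children if subtree_set(c) <= block]
        if frozenset().union(*(subtree_set(c) for c in members)) != block:
            continue  # incompatible with already-inserted splits (sub-majority greedy case)
        if len(members) == len(node.children):
            node.support = f * 100.0
            continue
        new = Node(support=f * 100.0)
        node.children = [c for c in node.children if c not in members]
        node.add(new)
        for m in members:
            new.add(m)
        leafsets[id(new)] = block
    return tree


def bipartition_maxdiff(s1: TreeSample, s2: TreeSample) -> float:
    """Maximum absolute difference in bipartition frequencies between two
    tree samples (the two-chain MCMC convergence diagnostic; values below
    0.1 are conventionally taken as acceptable convergence)."""
    if s1.taxa != s2.taxa:
        raise TreeError("tree samples are over different leaf sets")
    f1 = s1.split_frequencies()
    f2 = s2.split_frequencies()
    keys = set(f1) | set(f2)
    if not keys:
        return 0.0
    return max(abs(f1.get(k, 0.0) - f2.get(k, 0.0)) for k in keys)


# ---------------------------------------------------------------------------
# Restriction (pruning to a taxon subset)
# ---------------------------------------------------------------------------

def restrict(t: Tree, taxa: Iterable[str]) -> Tree:
    """Prune the tree to the given taxon subset, suppressing degree-2 nodes
    (their edge lengths add; the support of the surviving child edge is
    kept).  The result keeps unrooted semantics."""
    keep = frozenset(taxa)
    missing = keep - t.taxa
    if missing:
        raise TreeError(f"taxa not in tree: {sorted(missing)}")
    if len(keep) < 2:
        raise TreeError("cannot restrict to fewer than 2 taxa")
    t = t.copy()

    def prune(node: Node) -> Node | None:
        if node.is_leaf:
            return node if node.name in keep else None
        kept = [c for c in (prune(c) for c in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            return child
        node.children = []
        for c in kept:
            node.add(c)
        return node

    new_root = prune(t.root)
    assert new_root is not None
    new_root.parent = None
    new_root.length = None
    out = Tree(new_root, rooted=False, support_kind=t.support_kind)
    if len(out.root.children) == 2 and out.n_leaves >= 3:
        out = out.deroot()
    return out
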