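"""Phylogenies: parsing, writing, scaling, and rate adjustment.

Trees are rooted, with named leaves and non-negative branch lengths measured
in expected substitutions per site.  The supported Newick dialect is
deliberately narrow: unquoted labels, decimal branch lengths, no comments;
internal labels are permitted and preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "TreeNode",
    "Phylogeny",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "scale_tree",
    "adjust_branch_lengths",
    "overall_rate_factor",
]


class NewickParseError(ValueError):
    """Malformed Newick input; ``pos`` is the 0-based offset of the problem."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


@dataclass
class TreeNode:
    name: str | None = None
    length: float | None = None  # branch to parent; None for root
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Phylogeny:
    """A rooted tree with unique, non-empty leaf names."""

    root: TreeNode

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def branches(self) -> list[TreeNode]:
        """All non-root nodes, in preorder (each carries its parent branch)."""
        return [n for n in self.preorder() if n is not self.root]

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.branches())

    def branch_lengths(self) -> list[float]:
        return [n.length or 0.0 for n in self.branches()]

    def set_branch_lengths(self, lengths) -> None:
        branches = self.branches()
        if len(lengths) != len(branches):
            raise ValueError(
                f"expected {len(branches)} branch lengths, got {len(lengths)}"
            )
        for node, value in zip(branches, lengths):
            value = float(value)
            if not value >= 0.0:
                raise ValueError(f"branch length must be >= 0, got {value}")
            node.length = value

    def copy(self) -> "Phylogeny":
        def _copy(node: TreeNode) -> TreeNode:
            return TreeNode(node.name, node.length, [_copy(c) for c in node.children])

        return Phylogeny(_copy(self.root))

    def validate(self) -> None:
        names = self.leaf_names()
        if any(not n for n in names):
            raise ValueError("leaf names must be non-empty")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf names: {dupes}")
        for node in self.branches():
            length = node.length or 0.0
            if not (length >= 0.0 and length == length and length != float("inf")):
                raise ValueError(f"invalid branch length {node.length!r} on {node.name!r}")

    def prune_to(self, keep: list[str]) -> "Phylogeny":
        """Restriction of the tree to the given leaves.

        Unary internal nodes created by pruning are collapsed, with their
        branch lengths summed onto the surviving child.
        """
        keep_set = set(keep)
        missing = keep_set - set(self.leaf_names())
        if missing:
            raise ValueError(f"unknown leaves: {sorted(missing)}")

        def _prune(node: TreeNode) -> TreeNode | None:
            if node.is_leaf:
                return TreeNode(node.name, node.length) if node.name in keep_set else None
            kids = [k for k in (_prune(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                child = kids[0]
                if node.length is not None:
                    child.length = (child.length or 0.0) + node.length
                return child
            return TreeNode(node.name, node.length, kids)

        root = _prune(self.root)
        if root is None or root.is_leaf:
            raise ValueError("pruning must retain at least two leaves")
        root.length = None
        tree = Phylogeny(root)
        tree.validate()
        return tree

    def leaf_distances_from(self, reference: str) -> dict[str, float]:
        """Path distance (sum of branch lengths) from a reference leaf to each leaf."""
        parent: dict[int, TreeNode | None] = {id(self.root): None}
        nodes: dict[int, TreeNode] = {}
        for node in self.preorder():
            nodes[id(node)] = node
            for child in node.children:
                parent[id(child)] = node
        ref = next((n for n in self.leaves() if n.name == reference), None)
        if ref is None:
            raise ValueError(f"unknown reference leaf {reference!r}")
        # distances from ref to every node via simple relaxation up then down
        dist: dict[int, float] = {id(ref): 0.0}
        node = ref
        while parent[id(node)] is not None:
            up = parent[id(node)]
            dist[id(up)] = dist[id(node)] + (node.length or 0.0)
            node = up
        for n in self.preorder():
            for child in n.children:
                if id(child) not in dist:
                    dist[id(child)] = dist[id(n)] + (child.length or 0.0)
        return {leaf.name: dist[id(leaf)] for leaf in self.leaves()}


_LABEL_FORBIDDEN = set("():,;[]' \t\n")


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick expression (terminated by ';') into a Phylogeny.

    Raises :class:`NewickParseError` on malformed input, naming the offending
    position, and on negative branch lengths.
    """
    s = text.strip()
    if not s:
        raise NewickParseError("empty input", 0)
    pos = 0

    def error(msg: str) -> NewickParseError:
        return NewickParseError(msg, pos)

    def parse_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in _LABEL_FORBIDDEN:
            pos += 1
        return s[start:pos]

    def parse_length() -> float | None:
        nonlocal pos
        if pos >= len(s) or s[pos] != ":":
            return None
        pos += 1
        start = pos
        while pos < len(s) and (s[pos].isdigit() or s[pos] in "+-.eE"):
            pos += 1
        token = s[start:pos]
        try:
            value = float(token)
        except ValueError:
            raise NewickParseError(f"bad branch length {token!r}", start) from None
        if value < 0:
            raise NewickParseError(f"negative branch length {token}", start)
        if value != value or value == float("inf"):
            raise NewickParseError(f"non-finite branch length {token}", start)
        return value

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(s):
                    raise error("unbalanced parentheses: unexpected end of input")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"expected ',' or ')', found {s[pos]!r}")
        label = parse_label()
        node.name = label or None
        if node.is_leaf and not label:
            raise error("empty leaf label")
        node.length = parse_length()
        return node

    root = parse_node()
    if pos >= len(s) or s[pos] != ";":
        raise NewickParseError("expected ';' terminator", pos)
    if s[pos + 1 :].strip():
        raise NewickParseError("trailing characters after ';'", pos + 1)
    tree = Phylogeny(root)
    tree.validate()
    return tree


def _format_length(x: float) -> str:
    text = repr(float(x))
    return text[:-2] if text.endswith(".0") else text


def write_newick(tree: Phylogeny) -> str:
    def _write(node: TreeNode) -> str:
        if node.is_leaf:
            out = node.name or ""
        else:
            out = "(" + ",".join(_write(c) for c in node.children) + ")" + (node.name or "")
        if node.length is not None:
            out += f":{_format_length(node.length)}"
        return out

    return _write(tree.root) + ";"


def scale_tree(tree: Phylogeny, factor: float) -> Phylogeny:
    """Multiply every branch length by ``factor`` (> 0); topology unchanged."""
    if not factor > 0:
        raise ValueError(f"scale factor must be > 0, got {factor}")
    scaled = tree.copy()
    for node in scaled.branches():
        if node.length is not None:
            node.length *= factor
    return scaled


def overall_rate_factor(alpha: float, beta: float) -> float:
    """Ratio of block-averaged (overall) rate to the neutral rate.

    A fraction ``alpha`` of sites evolves at ``beta`` times the neutral rate
    and the rest at the neutral rate, so overall/neutral = alpha*beta + 1 - alpha.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0,1], got {alpha}")
    if not 0.0 < beta <= 1.0:
        raise ValueError(f"beta must be in (0,1], got {beta}")
    factor = alpha * beta + 1.0 - alpha
    if not factor > 0:
        raise ValueError("alpha*beta + 1 - alpha must be positive")
    return factor


def adjust_branch_lengths(tree: Phylogeny, alpha: float, beta: float) -> Phylogeny:
    """Convert overall (block-averaged) branch lengths to neutral-scale lengths.

    Each branch length is divided by ``alpha*beta + 1 - alpha``, the overall/
    neutral rate ratio under conserved-block coverage ``alpha`` with relative
    block rate ``beta``.
    """
    factor = overall_rate_factor(alpha, beta)
    return scale_tree(tree, 1.0 / factor)
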