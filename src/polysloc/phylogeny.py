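"""Distance-matrix construction and neighbor-joining tree inference.

The tree machinery used to place S-locus haplogroup sequences relative to
their parental-species orthologs: a labeled symmetric distance matrix
(p, Jukes–Cantor or Kimura two-parameter distances with pairwise deletion)
and the Saitou–Nei neighbor-joining algorithm with Newick output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .alignment import Alignment
from .seqdiv import SaturationError, corrected_distance


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.values < 0).any():
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)


def build_matrix(
    aln: Alignment,
    method: str = "K2P",
    deletion: str = "pairwise",
) -> DistanceMatrix:
    """All-pairs distance matrix from an alignment.

    Saturated pairs (beyond the correction's domain) abort with an error
    listing the offending pairs rather than silently producing NaNs.
    """
    if aln.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    columns = aln.comparable_columns() if deletion == "complete" else None
    n = aln.n_sequences
    d = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = corrected_distance(
                    aln.rows[i], aln.rows[j], method, columns=columns
                ).d
            except SaturationError:
                saturated.append((aln.labels[i], aln.labels[j]))
    if saturated:
        raise SaturationError(f"saturated pairs: {saturated}")
    return DistanceMatrix(list(aln.labels), d)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of an (unrooted) tree, stored rooted at the final NJ join."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    root: TreeNode

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def splits(self) -> dict[frozenset[str], float]:
        """Leaf bipartitions (as the smaller-side leaf set keyed by one
        side) mapped to the length of the branch inducing them. Trivial
        splits (single leaves) are included; the root trifurcation
        contributes one entry per child subtree."""
        all_leaves = frozenset(self.leaves())
        out: dict[frozenset[str], float] = {}

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset()
            for child, length in node.children:
                cset = walk(child)
                key = min(cset, all_leaves - cset, key=lambda s: (len(s), sorted(s)))
                out[key] = out.get(key, 0.0) + length
                below |= cset
            return below

        walk(self.root)
        return out

    def total_length(self) -> float:
        def walk(node: TreeNode) -> float:
            return sum(length + walk(child) for child, length in node.children)

        return walk(self.root)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining.

    At each step joins the pair minimizing
    ``Q(i,j) = (n-2) d(i,j) - r_i - r_j`` (row sums ``r``); ties broken by
    the lowest (row, column) index pair for cross-platform determinism.
    Negative branch lengths are clamped to zero with the deficit
    transferred to the sister branch of the same join, preserving the
    joined pair's path length.
    """
    if dm.n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in dm.labels]
    d = dm.values.astype(float).copy()
    active = list(range(dm.n))

    while len(active) > 3:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        best_q = np.inf
        for a in range(n):
            for b in range(a + 1, n):
                q = (n - 2) * sub[a, b] - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q, best = q, (a, b)
        a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (n - 2))
        lj = dij - li
        # clamp-and-transfer: keep li + lj = dij
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for c in range(n):
            k = active[c]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    i, j, k = active
    # final trifurcation: three-point formulas
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    branches = [li, lj, lk]
    for idx in range(3):
        if branches[idx] < 0:
            deficit = branches[idx]
            branches[idx] = 0.0
            other = min(range(3), key=lambda t: branches[t] if t != idx else np.inf)
            branches[other] += deficit
    root = TreeNode(children=[
        (nodes[i], branches[0]), (nodes[j], branches[1]), (nodes[k], branches[2])
    ])
    return Tree(root)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_NEEDS_QUOTE = set(" ()[]':;,")


def _escape(label: str) -> str:
    if not label:
        raise ValueError("empty leaf label cannot be written to Newick")
    if any(ch in _NEEDS_QUOTE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree, precision: int = 6) -> str:
    """Newick string with branch lengths at fixed decimal precision."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return _escape(node.label)
        inner = ",".join(
            f"{fmt(child)}:{length:.{precision}f}"
            for child, length in node.children
        )
        return f"({inner})"

    return fmt(tree.root) + ";"


def parse_newick(text: str) -> Tree:
    """Parse a Newick string produced by :func:`write_newick` (labels,
    branch lengths, quoted-label escaping)."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    s = text[:-1]
    pos = 0

    def parse_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while True:
                if pos >= len(s):
                    raise ValueError("unterminated quoted label")
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    break
                out.append(s[pos])
                pos += 1
            return "".join(out)
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos]

    def parse_length() -> float:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),;":
                pos += 1
            return float(s[start:pos])
        return 0.0

    def parse_node() -> tuple[TreeNode, float]:
        nonlocal pos
        if s[pos] == "(":
            pos += 1
            children = []
            while True:
                children.append(parse_node())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise ValueError(f"unexpected character at {pos}: {s[pos]!r}")
            label = parse_label()
            node = TreeNode(label=label or None, children=children)
            return node, parse_length()
        label = parse_label()
        return TreeNode(label=label), parse_length()

    node, _ = parse_node()
    if pos != len(s):
        raise ValueError("trailing characters after tree")
    return Tree(node)


def write_matrix_tsv(dm: DistanceMatrix, path, precision: int = 6) -> None:
    """Square, labeled TSV distance matrix."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(dm.labels) + "\n")
        for lab, row in zip(dm.labels, dm.values):
            fh.write(lab + "\t" + "\t".join(f"{v:.{precision}f}" for v in row) + "\n")
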