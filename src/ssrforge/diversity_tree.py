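"""Nei (1983) DA distances and neighbor-joining trees.

DA between two accessions over L shared loci:

    DA = 1 - (1/L) * sum_loci sum_alleles sqrt(x_a * y_a)

Neighbor joining follows Saitou & Nei with the standard Q-criterion
Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k); ties are broken by
the smallest (i, j) index pair so the tree is reproducible.  Negative
branch lengths are clamped to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidDistanceMatrixError, NoSharedLociError
from .genotype_stats import GenotypeMatrix

__all__ = [
    "TreeNode",
    "nei_da",
    "locus_profiles",
    "distance_matrix",
    "neighbor_joining",
    "write_newick",
    "parse_newick",
    "leaf_names",
    "path_lengths",
]

Profile = dict[int, float]  # allele -> frequency at one locus


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; ``children`` pairs a child with the
    length of the edge above it."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


def nei_da(profiles_x: list[Profile], profiles_y: list[Profile]) -> float:
    """DA distance from per-locus allele-frequency profiles (same loci,
    same order, in both lists)."""
    if len(profiles_x) != len(profiles_y):
        raise ValueError("profile lists must cover the same loci")
    if not profiles_x:
        raise NoSharedLociError("no shared loci")
    total = 0.0
    for px, py in zip(profiles_x, profiles_y):
        for tol in (abs(sum(px.values()) - 1.0), abs(sum(py.values()) - 1.0)):
            if tol > 1e-6:
                raise ValueError("per-locus frequencies must sum to 1")
        total += sum(math.sqrt(px[a] * py.get(a, 0.0)) for a in px)
    da = 1.0 - total / len(profiles_x)
    return min(1.0, max(0.0, da))


def locus_profiles(matrix: GenotypeMatrix, accession: str) -> dict[str, Profile]:
    """Per-locus frequency profile of one accession's own calls (1 for a
    homozygote allele, 1/2 each for a heterozygote)."""
    out: dict[str, Profile] = {}
    for marker in matrix.markers:
        call = matrix.call(marker, accession)
        if call is None:
            continue
        prof: Profile = {}
        for allele in call:
            prof[allele] = prof.get(allele, 0.0) + 1.0 / len(call)
        out[marker] = prof
    return out


def distance_matrix(
    matrix: GenotypeMatrix, deletion: str = "pairwise"
) -> tuple[list[str], np.ndarray]:
    """Pairwise Nei DA over accessions.

    ``pairwise`` deletion uses, for each pair, the loci where both calls
    are non-missing; ``complete`` restricts every pair to loci with no
    missing call in any accession.  A pair with zero shared loci is an
    error.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    ids = list(matrix.accessions)
    if len(ids) < 2:
        raise ValueError("need >= 2 accessions")
    profiles = {a: locus_profiles(matrix, a) for a in ids}
    if deletion == "complete":
        keep = [m for m in matrix.markers if all(m in profiles[a] for a in ids)]
        profiles = {a: {m: p[m] for m in keep} for a, p in profiles.items()}
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = [m for m in matrix.markers if m in profiles[ids[i]] and m in profiles[ids[j]]]
            if not shared:
                raise NoSharedLociError(f"accessions {ids[i]!r} and {ids[j]!r} share no loci")
            val = nei_da(
                [profiles[ids[i]][m] for m in shared],
                [profiles[ids[j]][m] for m in shared],
            )
            d[i, j] = d[j, i] = val
    return ids, d


def neighbor_joining(ids: list[str], dmat: np.ndarray) -> TreeNode:
    """Saitou-Nei neighbor joining; returns the tree rooted at the final
    internal node (a trifurcation for n >= 3, a single edge for n = 2)."""
    d = np.asarray(dmat, dtype=float)
    n = len(ids)
    if d.shape != (n, n):
        raise InvalidDistanceMatrixError("matrix shape does not match ids")
    if not np.allclose(d, d.T, atol=1e-12):
        raise InvalidDistanceMatrixError("matrix must be symmetric")
    if (d < 0).any():
        raise InvalidDistanceMatrixError("matrix must be non-negative")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise InvalidDistanceMatrixError("diagonal must be zero")
    if n < 2:
        raise ValueError("need >= 2 taxa")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    d = d.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best_pair = None
        best_q = math.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-15:
                    best_q = q
                    best_pair = (i, j)
        i, j = best_pair
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode(children=[(nodes[i], max(0.0, li)), (nodes[j], max(0.0, lj))])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = new_d[keep]
        d2[:-1, -1] = new_d[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        d = d2

    if len(nodes) == 2:
        half = d[0, 1] / 2.0
        return TreeNode(children=[(nodes[0], max(0.0, half)), (nodes[1], max(0.0, half))])
    # final trifurcation: three-point formulas
    l0 = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    l1 = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    l2 = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    return TreeNode(
        children=[
            (nodes[0], max(0.0, l0)),
            (nodes[1], max(0.0, l1)),
            (nodes[2], max(0.0, l2)),
        ]
    )


_SPECIALS = set(" ()[]:;,'\t\n")


def _quote(name: str) -> str:
    if any(c in _SPECIALS for c in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: TreeNode) -> str:
    """Serialize with 6-decimal branch lengths and a trailing semicolon."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return _quote(node.name or "")
        inner = ",".join(f"{render(child)}:{length:.6f}" for child, length in node.children)
        return f"({inner})" + (_quote(node.name) if node.name else "")

    return render(tree) + ";"


def parse_newick(text: str) -> TreeNode:
    """Minimal Newick reader matching :func:`write_newick` output."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("newick string must end with ';'")
    s = text[:-1]
    pos = 0

    def parse_name() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while True:
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
        while pos < len(s) and s[pos] not in "():,;":
            pos += 1
        return s[start:pos]

    def parse_length() -> float:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and (s[pos].isdigit() or s[pos] in ".-+eE"):
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
            name = parse_name()
            length = parse_length()
            return TreeNode(name=name or None, children=children), length
        name = parse_name()
        length = parse_length()
        return TreeNode(name=name), length

    node, _ = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters in newick at {pos}")
    return node


def leaf_names(tree: TreeNode) -> list[str]:
    if tree.is_leaf:
        return [tree.name or ""]
    out: list[str] = []
    for child, _ in tree.children:
        out.extend(leaf_names(child))
    return out


def path_lengths(tree: TreeNode) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths along the tree's edges."""
    dists: dict[tuple[str, str], float] = {}

    def collect(node: TreeNode) -> list[tuple[str, float]]:
        if node.is_leaf:
            return [(node.name or "", 0.0)]
        groups = []
        for child, length in node.children:
            groups.append([(name, dist + length) for name, dist in collect(child)])
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a, da in groups[gi]:
                    for b, db in groups[gj]:
                        key = (a, b) if a <= b else (b, a)
                        dists[key] = da + db
        return [pair for grp in groups for pair in grp]

    collect(tree)
    return dists


def is_monophyletic(tree: TreeNode, group: set[str]) -> bool:
    """True iff ``group`` is exactly the leaf set of some edge-defined side
    of the (unrooted) tree."""
    all_leaves = set(leaf_names(tree))
    if not group or not group <= all_leaves:
        return False
    result = False

    def walk(node: TreeNode) -> set[str]:
        nonlocal result
        if node.is_leaf:
            below = {node.name or ""}
        else:
            below = set()
            for child, _ in node.children:
                below |= walk(child)
        if below == group or (all_leaves - below) == group:
            result = True
        return below

    walk(tree)
    return result
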