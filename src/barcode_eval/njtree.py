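"""Neighbour-joining trees, Newick round-trip and species-monophyly scoring.

Saitou–Nei neighbour joining with the Studier–Keppler criterion::

    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

The pair minimising Q is joined; on ties the lowest (row, column) index pair
in the current label order wins, which makes the output deterministic.
Branch lengths follow the standard allocation and are clamped at zero
(clamping changes lengths only, never topology). The final three clusters
are joined at a single internal node, giving an unrooted binary tree with
2n - 3 edges stored with an arbitrary internal node as traversal root.

A species is monophyletic on the unrooted tree iff some edge's bipartition
has one side exactly equal to the species' leaf set. Tree-based
identification counts a species (>= 2 individuals) as discriminated iff it
is monophyletic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .errors import InputError, StageError, UndefinedDistanceError

__all__ = [
    "Node",
    "UnrootedTree",
    "MonophylyRecord",
    "MonophylyReport",
    "nj_build",
    "newick_string",
    "write_newick",
    "read_newick",
    "species_monophyly",
    "species_monophyly_by_rooting",
]

LABEL_SEP = "|"


@dataclass
class Node:
    """Tree node; leaves carry sample_id (name) and species."""

    name: str = ""
    species: str = ""
    length: float = 0.0  # branch to parent; unused on the traversal root
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out


@dataclass
class UnrootedTree:
    """Unrooted tree stored with an arbitrary internal traversal root."""

    root: Node

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def species_of(self) -> dict[str, str]:
        return {lf.name: lf.species for lf in self.leaves()}

    def n_edges(self) -> int:
        count = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            count += len(node.children)
            stack.extend(node.children)
        return count

    def bipartitions(self) -> set[frozenset[str]]:
        """One side (the child side) of every edge, as leaf-name sets."""
        sides: set[frozenset[str]] = set()

        def walk(node: Node) -> frozenset[str]:
            if node.is_leaf:
                side = frozenset([node.name])
            else:
                side = frozenset().union(*(walk(ch) for ch in node.children))
            if node is not self.root:
                sides.add(side)
            return side

        walk(self.root)
        return sides

    def path_lengths(self) -> pd.DataFrame:
        """All-pairs leaf-to-leaf path lengths (sums of branch lengths)."""
        depth: dict[str, float] = {}
        clades: list[tuple[frozenset[str], float]] = []

        def walk(node: Node, d: float) -> frozenset[str]:
            if node.is_leaf:
                depth[node.name] = d
                return frozenset([node.name])
            below = frozenset()
            for ch in node.children:
                below |= walk(ch, d + ch.length)
            clades.append((below, d))
            return below

        for ch in self.root.children:
            walk(ch, ch.length)
        clades.append((frozenset(depth), 0.0))
        names = sorted(depth)
        mat = pd.DataFrame(0.0, index=names, columns=names)
        for a_i, a in enumerate(names):
            for b in names[a_i + 1 :]:
                # deepest clade containing both = most recent common ancestor
                mrca = max(
                    (d for cl, d in clades if a in cl and b in cl),
                    default=0.0,
                )
                dist = depth[a] + depth[b] - 2 * mrca
                mat.loc[a, b] = mat.loc[b, a] = dist
        return mat


def nj_build(dm: DistanceMatrix) -> UnrootedTree:
    """Neighbour joining of a fully defined distance matrix.

    Raises :class:`UndefinedDistanceError` naming the first offending pair if
    any entry is undefined; requires >= 3 records.
    """
    n = dm.n
    if n < 3:
        raise StageError("neighbour joining needs at least 3 records")
    bad = np.argwhere(np.isnan(dm.values))
    if bad.size:
        i, j = bad[0]
        raise UndefinedDistanceError(
            f"undefined distance between {dm.labels[i]!r} and {dm.labels[j]!r}"
        )
    D = dm.values.astype(float).copy()
    nodes: list[Node] = [
        Node(name=lbl, species=sp) for lbl, sp in zip(dm.labels, dm.species)
    ]
    while len(nodes) > 3:
        m = len(nodes)
        sums = D.sum(axis=1)
        Q = (m - 2) * D - sums[:, None] - sums[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin = lowest (row, column) pair on ties
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (sums[i] - sums[j]) / (2.0 * (m - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(0.0, li)
        child_j.length = max(0.0, lj)
        new = Node(children=[child_i, child_j])
        du = 0.5 * (D[i, :] + D[j, :] - dij)
        # new cluster takes slot i; slot j removed
        D[i, :] = du
        D[:, i] = du
        D[i, i] = 0.0
        keep = [k for k in range(m) if k != j]
        D = D[np.ix_(keep, keep)]
        nodes[i] = new
        del nodes[j]
    # join the last three clusters at one internal node (closed form)
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.length = max(0.0, 0.5 * (dac + dbc - dab))
    return UnrootedTree(root=Node(children=[a, b, c]))


def _quote(label: str) -> str:
    if any(ch in label for ch in " \t(),:;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def newick_string(tree: UnrootedTree) -> str:
    """Newick with branch lengths; leaf labels are ``sample_id|species``."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            body = _quote(node.name + LABEL_SEP + node.species)
        else:
            body = "(" + ",".join(fmt(ch) for ch in node.children) + ")"
        return f"{body}:{node.length:.10g}"

    return "(" + ",".join(fmt(ch) for ch in tree.root.children) + ");"


def write_newick(tree: UnrootedTree, path: str | Path) -> None:
    Path(path).write_text(newick_string(tree) + "\n")


def read_newick(source: str | Path) -> UnrootedTree:
    """Read a Newick tree whose leaf labels follow ``sample_id|species``.

    Accepts a path or a Newick string; malformed input raises
    :class:`InputError` with the parser's position information.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("(")
    ):
        text = Path(source).read_text()
    else:
        text = source
    try:
        dtree = dendropy.Tree.get(
            file=io.StringIO(text),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise InputError(f"malformed Newick: {exc}") from None

    def convert(dnode: dendropy.Node) -> Node:
        length = float(dnode.edge.length) if dnode.edge.length is not None else 0.0
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else ""
            if LABEL_SEP in label:
                sample_id, species = label.split(LABEL_SEP, 1)
            else:
                sample_id, species = label, ""
            return Node(name=sample_id, species=species, length=length)
        return Node(
            length=length,
            children=[convert(ch) for ch in dnode.child_nodes()],
        )

    return UnrootedTree(root=convert(dtree.seed_node))


@dataclass(frozen=True)
class MonophylyRecord:
    species: str
    n_individuals: int
    is_monophyletic: bool


@dataclass
class MonophylyReport:
    records: list[MonophylyRecord]
    skipped_singletons: list[str] = field(default_factory=list)

    @property
    def n_assessed(self) -> int:
        return len(self.records)

    @property
    def n_monophyletic(self) -> int:
        return sum(r.is_monophyletic for r in self.records)

    @property
    def pct_discriminated(self) -> float:
        if not self.records:
            raise StageError("no species with >= 2 individuals to assess")
        return 100.0 * self.n_monophyletic / self.n_assessed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.species, r.n_individuals, r.is_monophyletic) for r in self.records],
            columns=["species", "n_individuals", "monophyletic"],
        )


def _species_sets(tree: UnrootedTree) -> dict[str, frozenset[str]]:
    sets: dict[str, set[str]] = {}
    for leaf in tree.leaves():
        sets.setdefault(leaf.species, set()).add(leaf.name)
    return {sp: frozenset(names) for sp, names in sets.items()}


def species_monophyly(tree: UnrootedTree) -> MonophylyReport:
    """Score each species (>= 2 individuals) for monophyly via bipartitions.

    Singletons are trivially monophyletic and excluded from the denominator.
    """
    sides = tree.bipartitions()
    all_leaves = frozenset(tree.leaf_names())
    records: list[MonophylyRecord] = []
    skipped: list[str] = []
    for sp, members in sorted(_species_sets(tree).items()):
        if len(members) < 2:
            skipped.append(sp)
            continue
        mono = members in sides or (all_leaves - members) in sides
        records.append(MonophylyRecord(sp, len(members), mono))
    return MonophylyReport(records=records, skipped_singletons=skipped)


def species_monophyly_by_rooting(tree: UnrootedTree) -> MonophylyReport:
    """Independent monophyly check: root at a leaf and test rooted clades.

    Rooting the unrooted tree on the pendant edge of an arbitrary leaf L
    turns every other edge into a rooted clade; a species not containing L
    is monophyletic iff its leaf set equals some clade, and L's own species
    is monophyletic iff the complement of its leaf set is a clade.
    """
    sides: set[frozenset[str]] = set()

    def walk(node: Node) -> frozenset[str]:
        if node.is_leaf:
            below = frozenset([node.name])
        else:
            below = frozenset().union(*(walk(ch) for ch in node.children))
        sides.add(below)
        return below

    all_leaves = frozenset()
    for ch in tree.root.children:
        all_leaves |= walk(ch)
    root_leaf = min(all_leaves)
    # rooted clade of each edge = the side away from the root leaf
    rooted_clades = {
        side if root_leaf not in side else all_leaves - side for side in sides
    }
    records: list[MonophylyRecord] = []
    skipped: list[str] = []
    for sp, members in sorted(_species_sets(tree).items()):
        if len(members) < 2:
            skipped.append(sp)
            continue
        if root_leaf in members:
            # the group contains the root: monophyletic iff everything else
            # hangs together as one rooted clade
            mono = (all_leaves - members) in rooted_clades
        else:
            mono = members in rooted_clades
        records.append(MonophylyRecord(sp, len(members), mono))
    return MonophylyReport(records=records, skipped_singletons=skipped)
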