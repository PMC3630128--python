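"""Identity distances, Neighbor-Joining trees and clade partitions.

The classifier's ensemble construction needs to know how the members of a
substrate group distribute over the evolutionary tree.  This module
computes simple p-distances from an alignment, reconstructs the classic
Saitou–Nei Neighbor-Joining tree (with deterministic lexicographic
tie-breaking, so results never depend on input order), and partitions a
substrate group into clade-consistent subgroups on a midpoint-rooted
tree.  A partition can alternatively be supplied explicitly from a parts
table when the grouping comes from elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np

from .io_formats import GAP, AnnotationTable, MultipleAlignment

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not fit the id list")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < -1e-12).any():
            raise ValueError("negative distances")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])


def pairwise_distances(alignment: MultipleAlignment) -> DistanceMatrix:
    """p-distances: mismatches over columns where both rows have residues.

    Pairs sharing no comparable column get distance 1 (with a warning).
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 rows")
    rows = np.array([list(r) for r in alignment.rows])
    n = len(alignment)
    d = np.zeros((n, n))
    nongap = rows != GAP
    for i in range(n):
        for j in range(i + 1, n):
            comparable = nongap[i] & nongap[j]
            total = int(comparable.sum())
            if total == 0:
                logger.warning(
                    "rows %s and %s share no comparable columns; distance set to 1",
                    alignment.ids[i], alignment.ids[j],
                )
                d[i, j] = d[j, i] = 1.0
            else:
                mism = int((rows[i][comparable] != rows[j][comparable]).sum())
                d[i, j] = d[j, i] = mism / total
    return DistanceMatrix(list(alignment.ids), d)


def neighbor_joining(matrix: DistanceMatrix) -> dendropy.Tree:
    """Classic Saitou–Nei Neighbor-Joining.

    Joins the pair minimizing ``Q(i,j) = (n-2) d(i,j) - r_i - r_j``;
    branch lengths ``L(i,u) = d(i,j)/2 + (r_i - r_j) / (2(n-2))``.
    Minimal-Q ties are broken by the lexicographically lowest pair of
    cluster labels (a cluster is labelled by its smallest leaf id).
    Negative branch lengths are clamped to 0 with the deficit moved to
    the sister branch.  Returns an unrooted tree whose seed node has
    degree 3.
    """
    if len(matrix.ids) < 3:
        raise ValueError("Neighbor-Joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(list(matrix.ids))
    nodes: dict[int, dendropy.Node] = {}
    labels: dict[int, str] = {}
    dist: dict[tuple[int, int], float] = {}
    active: list[int] = []
    for idx, seq_id in enumerate(matrix.ids):
        node = dendropy.Node(taxon=tns.get_taxon(seq_id))
        nodes[idx] = node
        labels[idx] = seq_id
        active.append(idx)
    for i in range(len(matrix.ids)):
        for j in range(i + 1, len(matrix.ids)):
            dist[(i, j)] = float(matrix.d[i, j])
    next_key = len(matrix.ids)

    def d_of(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    while len(active) > 3:
        n = len(active)
        r = {i: sum(d_of(i, j) for j in active if j != i) for i in active}
        best: tuple | None = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (n - 2) * d_of(i, j) - r[i] - r[j]
                lab = tuple(sorted((labels[i], labels[j])))
                key = (q, lab[0], lab[1])
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d_of(i, j)
        li = dij / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        u = next_key
        next_key += 1
        nodes[u] = parent
        labels[u] = min(labels[i], labels[j])
        for k in active:
            if k in (i, j):
                continue
            dist[(min(u, k), max(u, k))] = (d_of(i, k) + d_of(j, k) - dij) / 2
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = sorted(active, key=lambda k: labels[k])
    dab, dac, dbc = d_of(a, b), d_of(a, c), d_of(b, c)
    lengths = {
        a: (dab + dac - dbc) / 2,
        b: (dab + dbc - dac) / 2,
        c: (dac + dbc - dab) / 2,
    }
    root = dendropy.Node()
    for k in (a, b, c):
        root.add_child(nodes[k])
        nodes[k].edge.length = max(lengths[k], 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def tree_path_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (additivity oracle)."""
    pdm = tree.phylogenetic_distance_matrix()
    ids = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[ids[i]], taxa[ids[j]])
    return DistanceMatrix(ids, d)


@dataclass
class CladePartition:
    """Disjoint clade-consistent subgroups of one substrate group."""

    group: str
    subgroups: list[list[str]]
    provenance: list[str]
    not_subdivided: bool = False

    def __post_init__(self) -> None:
        flat = [m for part in self.subgroups for m in part]
        if len(flat) != len(set(flat)):
            raise ValueError("partition subgroups are not disjoint")

    @property
    def members(self) -> set[str]:
        return {m for part in self.subgroups for m in part}


def substrate_subgroups(
    tree: dendropy.Tree,
    labels: AnnotationTable | Mapping[str, str],
    group: str,
    max_parts: int = 4,
    min_part_size: int = 2,
) -> CladePartition:
    """Partition a substrate group into clade-consistent subgroups.

    Deterministic procedure: midpoint-root the tree; take the maximal
    clades whose leaves all belong to the group as initial parts; then
    repeatedly merge the smallest part with its topologically nearest
    part until at most ``max_parts`` parts remain and every part has at
    least ``min_part_size`` members.  Groups too small to split (fewer
    than ``2 * min_part_size`` members) come back as a single part with
    the ``not_subdivided`` flag set.
    """
    if not 2 <= max_parts <= 4:
        raise ValueError("max_parts must lie in [2, 4]")
    label_of = (
        labels.substrate_of if isinstance(labels, AnnotationTable) else labels.__getitem__
    )
    leaf_ids = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    members = sorted(i for i in leaf_ids if label_of(i) == group)
    missing = [
        r.seq_id
        for r in (labels.rows if isinstance(labels, AnnotationTable) else [])
        if r.substrate == group and r.seq_id not in leaf_ids
    ]
    if missing:
        raise ValueError(f"tree lacks group members: {', '.join(missing)}")
    if not members:
        raise ValueError(f"no members of group {group!r} in the tree")
    if len(members) < 2 * min_part_size:
        return CladePartition(group, [members], ["whole-group"], not_subdivided=True)

    rooted = dendropy.Tree(tree)
    rooted.reroot_at_midpoint(update_bipartitions=False)
    member_set = set(members)

    pure: dict[dendropy.Node, bool] = {}
    for node in rooted.postorder_node_iter():
        if node.is_leaf():
            pure[node] = node.taxon.label in member_set
        else:
            pure[node] = all(pure[c] for c in node.child_nodes())
    parts: list[tuple[list[str], dendropy.Node]] = []
    for node in rooted.preorder_node_iter():
        if pure[node] and (node.parent_node is None or not pure[node.parent_node]):
            ids = sorted(leaf.taxon.label for leaf in node.leaf_iter())
            parts.append((ids, node))

    depth: dict[dendropy.Node, int] = {}
    for node in rooted.preorder_node_iter():
        depth[node] = 0 if node.parent_node is None else depth[node.parent_node] + 1

    def node_distance(u: dendropy.Node, v: dendropy.Node) -> int:
        du, dv = depth[u], depth[v]
        steps = 0
        while du > dv:
            u, du, steps = u.parent_node, du - 1, steps + 1
        while dv > du:
            v, dv, steps = v.parent_node, dv - 1, steps + 1
        while u is not v:
            u, v, steps = u.parent_node, v.parent_node, steps + 2
        return steps

    def lca(u: dendropy.Node, v: dendropy.Node) -> dendropy.Node:
        du, dv = depth[u], depth[v]
        while du > dv:
            u, du = u.parent_node, du - 1
        while dv > du:
            v, dv = v.parent_node, dv - 1
        while u is not v:
            u, v = u.parent_node, v.parent_node
        return u

    while len(parts) > 1 and (
        len(parts) > max_parts or min(len(p[0]) for p in parts) < min_part_size
    ):
        smallest = min(parts, key=lambda p: (len(p[0]), p[0][0]))
        others = [p for p in parts if p is not smallest]
        partner = min(
            others, key=lambda p: (node_distance(smallest[1], p[1]), p[0][0])
        )
        merged = (
            sorted(smallest[0] + partner[0]),
            lca(smallest[1], partner[1]),
        )
        parts = [p for p in parts if p not in (smallest, partner)] + [merged]

    parts.sort(key=lambda p: p[0][0])
    subgroups = [p[0] for p in parts]
    provenance = ["clade:" + ",".join(p[0][:3]) + ("..." if len(p[0]) > 3 else "") for p in parts]
    return CladePartition(
        group, subgroups, provenance, not_subdivided=len(parts) == 1
    )


# ---------------------------------------------------------------------------
# explicit parts tables (seq_id, substrate, part_index)
# ---------------------------------------------------------------------------


def write_partition_table(partitions: Mapping[str, CladePartition], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("seq_id\tsubstrate\tpart_index\n")
        for substrate in sorted(partitions):
            for index, part in enumerate(partitions[substrate].subgroups, start=1):
                for seq_id in part:
                    fh.write(f"{seq_id}\t{substrate}\t{index}\n")


def read_partition_table(path: str | Path) -> dict[str, CladePartition]:
    groups: dict[str, dict[int, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["seq_id", "substrate", "part_index"]:
            raise ValueError(f"bad parts-table header: {header!r}")
        for line in fh:
            if not line.strip():
                continue
            seq_id, substrate, index = line.rstrip("\n").split("\t")
            groups.setdefault(substrate, {}).setdefault(int(index), []).append(seq_id)
    out: dict[str, CladePartition] = {}
    for substrate, by_index in groups.items():
        subgroups = [sorted(by_index[i]) for i in sorted(by_index)]
        out[substrate] = CladePartition(
            substrate,
            subgroups,
            [f"file:part{i}" for i in sorted(by_index)],
            not_subdivided=len(subgroups) == 1,
        )
    return out
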