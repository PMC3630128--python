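"""Independent oracles used by the test suite.

These deliberately re-derive expected values by brute force (exhaustive
path enumeration, exhaustive topology search, simulation at tiny n) and
share no code path with the implementation they check.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np

from subspec.io_formats import AMINO_ACIDS

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# exhaustive Viterbi oracle
# ---------------------------------------------------------------------------


def brute_force_viterbi_bits(hmm, residues: str) -> float:
    """Maximum log-odds (bits) over exhaustive enumeration of legal state paths.

    Architecture mirrored independently: begin = M_0; M_k -> {M, I, D},
    I_k -> {M, I}, D_k -> {M, D}; end after node M.  Emissions score
    log2(p/background) (0 for X); transitions log2(p).
    """
    m = hmm.match_count
    length = len(residues)
    x = [_AA_INDEX.get(aa) for aa in residues]

    def elog(p: float) -> float:
        return math.log2(p) if p > 0 else NEG_INF

    def em_bits(k: int, i: int) -> float:  # match emission, node k, residue i
        if x[i] is None:
            return 0.0
        return elog(hmm.match_emissions[k - 1][x[i]]) - elog(hmm.background[x[i]])

    def ei_bits(k: int, i: int) -> float:
        if x[i] is None:
            return 0.0
        return elog(hmm.insert_emissions[k][x[i]]) - elog(hmm.background[x[i]])

    best = [NEG_INF]

    def walk(state: str, k: int, i: int, score: float) -> None:
        if score == NEG_INF:
            return
        if state == "M":
            t_end, t_ins, t_del = hmm.t_match[k]
        elif state == "I":
            t_end, t_ins = hmm.t_insert[k]
            t_del = 0.0
        else:
            t_end, t_del = hmm.t_delete[k]
            t_ins = 0.0
        # advance to node k+1 via M (or finish)
        if k == m:
            if i == length:
                best[0] = max(best[0], score + elog(t_end))
        else:
            if i < length:
                walk("M", k + 1, i + 1, score + elog(t_end) + em_bits(k + 1, i))
            walk("D", k + 1, i, score + elog(t_del))
        if state in ("M", "I") and i < length:
            walk("I", k, i + 1, score + elog(t_ins) + ei_bits(k, i))

    walk("M", 0, 0, 0.0)
    return best[0]


def random_profile(rng: np.random.Generator, m: int):
    """A random, fully smoothed profile HMM for oracle comparisons."""
    from subspec.profile_hmm import ProfileHMM

    background = rng.dirichlet(np.full(20, 5.0))
    match = rng.dirichlet(np.ones(20), size=m)
    insert = rng.dirichlet(np.ones(20), size=m + 1)
    t_match = rng.dirichlet(np.ones(3), size=m + 1)
    t_match[m, 2] = 0.0
    t_match[m] /= t_match[m].sum()
    t_insert = rng.dirichlet(np.ones(2), size=m + 1)
    t_delete = rng.dirichlet(np.ones(2), size=m + 1)
    t_delete[0] = (1.0, 0.0)
    t_delete[m] = (1.0, 0.0)
    return ProfileHMM(
        name="random",
        substrate="?",
        subgroup_index=0,
        match_emissions=match,
        insert_emissions=insert,
        t_match=t_match,
        t_insert=t_insert,
        t_delete=t_delete,
        background=background,
    )


# ---------------------------------------------------------------------------
# exhaustive tree search
# ---------------------------------------------------------------------------


def all_unrooted_topologies(n: int) -> list[list[tuple[int, int]]]:
    """Edge lists of every unrooted binary topology over leaves 0..n-1.

    Internal nodes are numbered from n upward.  (1, 3, 15, 105 topologies
    for n = 3..6.)
    """
    assert n >= 3
    base_internal = n
    trees = [[(0, base_internal), (1, base_internal), (2, base_internal)]]
    for leaf in range(3, n):
        new_trees = []
        for edges in trees:
            for idx in range(len(edges)):
                u, v = edges[idx]
                mid = max(max(e) for e in edges) + 1
                new = [e for k, e in enumerate(edges) if k != idx]
                new += [(u, mid), (v, mid), (leaf, mid)]
                new_trees.append(new)
        trees = new_trees
    return trees


def _paths(edges: list[tuple[int, int]], n_leaves: int) -> dict[tuple[int, int], list[int]]:
    adj: dict[int, list[tuple[int, int]]] = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    out = {}
    for a in range(n_leaves):
        stack = [(a, None, [])]
        seen = {a}
        while stack:
            node, _parent, path = stack.pop()
            for nxt, eidx in adj[node]:
                if nxt in seen:
                    continue
                seen.add(nxt)
                np_ = path + [eidx]
                if nxt < n_leaves and nxt > a:
                    out[(a, nxt)] = np_
                stack.append((nxt, node, np_))
    return out


def ols_tree_length(edges: list[tuple[int, int]], d: np.ndarray) -> float:
    """Total branch length of the ordinary-least-squares fit of d to the topology."""
    n = d.shape[0]
    paths = _paths(edges, n)
    pairs = sorted(paths)
    a_mat = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        for eidx in paths[(i, j)]:
            a_mat[r, eidx] = 1.0
        y[r] = d[i, j]
    lengths, *_ = np.linalg.lstsq(a_mat, y, rcond=None)
    return float(lengths.sum())


def bipartitions(edges: list[tuple[int, int]], n_leaves: int) -> frozenset[frozenset[int]]:
    """Non-trivial leaf splits induced by the internal edges of a topology."""
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    splits = set()
    for u, v in edges:
        if u < n_leaves or v < n_leaves:
            continue
        stack, seen = [u], {u, v}
        side = set()
        while stack:
            node = stack.pop()
            if node < n_leaves:
                side.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        rest = frozenset(range(n_leaves)) - frozenset(side)
        splits.add(frozenset((frozenset(side), rest)))
    return frozenset(splits)


def random_additive_tree(rng: np.random.Generator, n: int, min_branch: float = 0.05,
                         max_branch: float = 0.3) -> dendropy.Tree:
    """Random unrooted binary tree with branch lengths in [min_branch, max_branch]."""
    tns = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    nodes = [dendropy.Node(taxon=tns.get_taxon(f"t{i}")) for i in range(n)]
    for node in nodes:
        node.edge.length = float(rng.uniform(min_branch, max_branch))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(min_branch, max_branch))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for node in nodes:
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def rf_distance(a: dendropy.Tree, b: dendropy.Tree) -> int:
    """Robinson–Foulds distance (dendropy), with namespace migration."""
    from dendropy.calculate import treecompare

    b.migrate_taxon_namespace(a.taxon_namespace)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return treecompare.symmetric_difference(a, b)
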