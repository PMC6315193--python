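"""Distance-based whole-genome phylogeny with pseudo-bootstrap support.

Trees are inferred from GBDP distance matrices with neighbor joining
(scikit-bio) optionally refined by NNI hill-climbing under the balanced
minimum evolution criterion (Pauplin's tree length), which mirrors the
default behaviour of FastME-style programs.  Support comes from a
pseudo-bootstrap that resamples the trimmed HSP set of every genome pair
with replacement and recomputes the distance, so no re-alignment is needed
per replicate.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from . import constants
from .indexes import PairwiseResults, distance_from_stats


class TreeValidationError(ValueError):
    pass


def _as_skbio_dm(dm) -> DistanceMatrix:
    if isinstance(dm, DistanceMatrix):
        data, ids = dm.data, dm.ids
    elif isinstance(dm, pd.DataFrame):
        data, ids = dm.values, list(dm.index)
        if list(dm.columns) != ids:
            raise TreeValidationError("distance matrix rows and columns disagree")
    else:
        raise TreeValidationError("expected a DataFrame or skbio DistanceMatrix")
    data = np.asarray(data, dtype=float)
    if np.isnan(data).any():
        raise TreeValidationError("distance matrix contains NaN")
    if not np.allclose(data, data.T):
        raise TreeValidationError("distance matrix is not symmetric")
    return DistanceMatrix((data + data.T) / 2.0, ids)


# ---------------------------------------------------------------------------
# Adjacency representation (for NNI) and helpers
# ---------------------------------------------------------------------------


def _tree_to_adj(tree: TreeNode):
    """Unrooted adjacency: node-id -> set of neighbor ids; leaves carry labels."""
    adj: dict[int, set[int]] = {}
    labels: dict[int, str] = {}
    counter = itertools.count()
    ids: dict[int, int] = {}

    def nid(node) -> int:
        key = id(node)
        if key not in ids:
            ids[key] = next(counter)
        return ids[key]

    for node in tree.traverse(include_self=True):
        i = nid(node)
        adj.setdefault(i, set())
        if node.is_tip():
            labels[i] = node.name
        for child in node.children:
            j = nid(child)
            adj.setdefault(j, set())
            adj[i].add(j)
            adj[j].add(i)
    # suppress a degree-2 root (rooted binary input)
    for i in list(adj):
        if len(adj[i]) == 2 and i not in labels:
            a, b = adj[i]
            adj[a].discard(i)
            adj[b].discard(i)
            adj[a].add(b)
            adj[b].add(a)
            del adj[i]
    return adj, labels


def _adj_to_tree(adj, labels) -> TreeNode:
    """Rebuild a TreeNode (rooted at an arbitrary internal node)."""
    internal = [i for i in adj if i not in labels]
    root_id = internal[0] if internal else next(iter(adj))

    def build(i, parent):
        node = TreeNode(name=labels.get(i))
        for j in sorted(adj[i] - ({parent} if parent is not None else set())):
            node.append(build(j, i))
        return node

    return build(root_id, None)


def _topo_dists(adj, labels) -> dict[tuple[int, int], int]:
    """Topological (edge-count) distances between all leaf pairs (BFS)."""
    leaves = sorted(labels)
    out: dict[tuple[int, int], int] = {}
    for src in leaves:
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for dst in leaves:
            if dst > src:
                out[(src, dst)] = dist[dst]
    return out


def _bme_length(adj, labels, dmat: DistanceMatrix) -> float:
    """Pauplin's balanced minimum evolution tree length."""
    index = {name: k for k, name in enumerate(dmat.ids)}
    total = 0.0
    for (i, j), t in _topo_dists(adj, labels).items():
        d = dmat.data[index[labels[i]], index[labels[j]]]
        total += d * 2.0 ** (1 - t)
    return total


def _nni_neighbors(adj, labels):
    """Yield NNI moves as (u, a, v, b): swap subtree a (neighbor of u) with
    subtree b (neighbor of v) across internal edge (u, v)."""
    for u in adj:
        if u in labels:
            continue
        for v in adj[u]:
            if v in labels or v < u:
                continue
            u_side = sorted(adj[u] - {v})
            v_side = sorted(adj[v] - {u})
            a = u_side[0]
            for b in v_side:
                yield (u, a, v, b)


def _apply_nni(adj, u, a, v, b):
    adj[u].discard(a)
    adj[a].discard(u)
    adj[v].discard(b)
    adj[b].discard(v)
    adj[u].add(b)
    adj[b].add(u)
    adj[v].add(a)
    adj[a].add(v)


def _edge_bipartitions(adj, labels):
    """(u, v, leafset-on-v-side) for every edge, via DFS from v away from u."""
    out = []
    for u in adj:
        for v in adj[u]:
            if v < u:
                continue
            side = set()
            stack = [(v, u)]
            seen = {u, v}
            if v in labels:
                side.add(v)
            while stack:
                node, parent = stack.pop()
                for w in adj[node]:
                    if w != parent and w not in seen:
                        seen.add(w)
                        if w in labels:
                            side.add(w)
                        stack.append((w, node))
            out.append((u, v, frozenset(labels[x] for x in side)))
    return out


def _canonical_side(side: frozenset, all_leaves: frozenset) -> frozenset:
    """Canonical representative of an unrooted bipartition: the side not
    containing the lexicographically smallest leaf."""
    ref = min(all_leaves)
    return all_leaves - side if ref in side else side


def _ols_branch_lengths(adj, labels, dmat: DistanceMatrix) -> dict[frozenset, float]:
    """Ordinary least squares branch lengths given the topology, keyed by
    canonical edge bipartition.

    Exact for additive matrices (the design-matrix system is then
    consistent); negative estimates are clamped to zero.
    """
    edges = _edge_bipartitions(adj, labels)
    ids = list(dmat.ids)
    all_leaves = frozenset(ids)
    pairs = [(i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([dmat.data[i, j] for i, j in pairs])
    for e, (_, _, side) in enumerate(edges):
        for r, (i, j) in enumerate(pairs):
            if (ids[i] in side) != (ids[j] in side):
                A[r, e] = 1.0
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    return {
        _canonical_side(side, all_leaves): max(0.0, float(b))
        for (_, _, side), b in zip(edges, sol)
    }


def infer_tree(dm, method: str = "bme") -> TreeNode:
    """Infer an unrooted distance tree (trifurcating root representation).

    ``method='nj'`` is plain neighbor joining with negative branch-length
    estimates clamped to zero.  ``method='bme'`` (default) refines the NJ
    topology by NNI hill-climbing under the balanced minimum evolution
    criterion and re-estimates branch lengths by OLS — an in-package
    approximation of FastME's default behaviour.  Deterministic for a fixed
    matrix and method.
    """
    dmat = _as_skbio_dm(dm)
    if dmat.shape[0] < 3:
        raise TreeValidationError("need at least 3 taxa")
    tree = nj(dmat)
    if method == "nj":
        for node in tree.traverse():
            if node.length is not None and node.length < 0:
                node.length = 0.0
        return tree
    if method != "bme":
        raise ValueError(f"unknown method {method!r}")
    adj, labels = _tree_to_adj(tree)
    best = _bme_length(adj, labels, dmat)
    improved = True
    while improved:
        improved = False
        best_move = None
        for move in _nni_neighbors(adj, labels):
            _apply_nni(adj, *move)
            length = _bme_length(adj, labels, dmat)
            _apply_nni(adj, move[0], move[3], move[2], move[1])  # undo
            if length < best - 1e-12:
                best = length
                best_move = move
        if best_move is not None:
            _apply_nni(adj, *best_move)
            improved = True
    lengths = _ols_branch_lengths(adj, labels, dmat)
    out = _adj_to_tree(adj, labels)
    all_leaves = frozenset(t.name for t in out.tips())
    for node in out.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips()) or frozenset({node.name})
        node.length = lengths.get(_canonical_side(side, all_leaves), 0.0)
    out.length = None
    return out


# ---------------------------------------------------------------------------
# Pseudo-bootstrap and bipartition support
# ---------------------------------------------------------------------------


def pseudo_bootstrap(
    results: PairwiseResults,
    replicates: int = 100,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Replicate distance matrices by resampling trimmed HSPs per pair.

    For every replicate and every genome pair, each search direction's
    retained HSP list is resampled with replacement (same cardinality) and
    the GBDP distance recomputed; a direction with no HSP contributes the
    formula's capped maximum.  Fully seeded and reproducible.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    ids = results.ids
    formula = results.gbdp_formula
    cap = constants.GBDP_MAX_DISTANCE[formula]
    out: list[pd.DataFrame] = []
    pairs = sorted(results.hsp_stats)
    for _ in range(replicates):
        mat = pd.DataFrame(0.0, index=ids, columns=ids)
        for a, b in pairs:
            stats = results.hsp_stats[(a, b)]
            la = results.genome_lengths[a]
            lb = results.genome_lengths[b]
            dsum = 0.0
            for direction, (l1, l2) in zip(stats, ((la, lb), (lb, la))):
                if not direction:
                    dsum += cap
                    continue
                pick = rng.integers(0, len(direction), size=len(direction))
                resampled = [direction[k] for k in pick]
                dsum += distance_from_stats(resampled, l1, l2, formula)
            mat.loc[a, b] = mat.loc[b, a] = dsum / 2.0
        out.append(mat)
    return out


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Canonical non-trivial bipartitions induced by the tree's internal
    edges (rooting-independent)."""
    all_leaves = frozenset(t.name for t in tree.tips())
    n = len(all_leaves)
    parts: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= n - 2:
            parts.add(_canonical_side(side, all_leaves))
    return parts


def map_support(main: TreeNode, replicate_trees: Sequence[TreeNode]) -> TreeNode:
    """Annotate internal edges with bootstrap support (percent of replicate
    trees containing the same bipartition, rounded to nearest integer).

    All trees must share one leaf set.  Supports are written as internal
    node names, the common Newick dialect.
    """
    main_leaves = frozenset(t.name for t in main.tips())
    counts: dict[frozenset, int] = {}
    for rep in replicate_trees:
        rep_leaves = frozenset(t.name for t in rep.tips())
        if rep_leaves != main_leaves:
            raise TreeValidationError(
                "replicate tree leaf set differs from the main tree"
            )
        for part in tree_bipartitions(rep):
            counts[part] = counts.get(part, 0) + 1
    tree = main.copy()
    n = len(main_leaves)
    nrep = len(replicate_trees)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= n - 2 and nrep:
            c = counts.get(_canonical_side(side, main_leaves), 0)
            node.name = str(round(100.0 * c / nrep))
    return tree


def _support_of(node: TreeNode) -> int | None:
    try:
        return int(node.name)
    except (TypeError, ValueError):
        return None


def collapse_low_support(tree: TreeNode, threshold: float = 50) -> TreeNode:
    """Contract internal edges with support <= threshold into polytomies
    ("50% or less"); leaves and remaining supports are untouched."""
    out = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(out.non_tips(include_self=False)):
            sup = _support_of(node)
            if sup is not None and sup <= threshold and node.parent is not None:
                parent = node.parent
                for child in list(node.children):
                    node.remove(child)
                    parent.append(child)
                parent.remove(node)
                changed = True
    return out


def root_with_outgroup(tree: TreeNode, outgroup_ids: Sequence[str]) -> TreeNode:
    """Root the tree on the edge separating the outgroup from the ingroup.

    The outgroup must be monophyletic in the unrooted sense; otherwise the
    error names the conflicting (foreign) leaves found inside the smallest
    clade containing the outgroup.
    """
    outgroup = set(outgroup_ids)
    leaves = {t.name for t in tree.tips()}
    missing = outgroup - leaves
    if missing:
        raise TreeValidationError(f"outgroup ids not in tree: {sorted(missing)}")
    if not outgroup or outgroup == leaves:
        raise TreeValidationError("outgroup must be a proper non-empty leaf subset")
    work = tree.copy()
    # reroot at a non-outgroup leaf so a monophyletic outgroup forms a clade
    anchor_name = min(leaves - outgroup)
    work = work.root_at(work.find(anchor_name), above=True)
    target = None
    for node in work.traverse(include_self=False):
        side = {t.name for t in node.tips()} or {node.name}
        if side == outgroup:
            target = node
            break
    if target is None:
        lca = work.lca([work.find(name) for name in sorted(outgroup)])
        inside = {t.name for t in lca.tips()}
        raise TreeValidationError(
            "outgroup is not monophyletic; conflicting leaves: "
            f"{sorted(inside - outgroup)}"
        )
    rooted = work.root_at(target, above=True, branch_attrs=[])
    return rooted


def tree_to_distance_matrix(tree: TreeNode) -> pd.DataFrame:
    """Leaf-to-leaf path-length (patristic) distances."""
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_phylip(dm: pd.DataFrame, path) -> None:
    """Square PHYLIP distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"    {len(dm)}\n")
        for name in dm.index:
            row = " ".join(f"{v:.6f}" for v in dm.loc[name])
            fh.write(f"{name:<12s}{row}\n")
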