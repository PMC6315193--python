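"""Independent oracles and utilities for the test suite.

Everything here is deliberately naive (full dynamic programming, exhaustive
enumeration) so it can serve as a reference implementation against the
package's optimized code paths.
"""

from __future__ import annotations

import itertools

import numpy as np


def smith_waterman(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> tuple[float, int, int]:
    """Full affine-gap Smith-Waterman oracle.

    Returns (best score, identities, alignment columns) of the optimal local
    alignment, via O(nm) dynamic programming with traceback.  Only suitable
    for sequences up to a few kb.
    """
    n, m = len(a), len(b)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (left)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (up)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 left, 3 up
    best = 0.0
    best_pos = (0, 0)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open + gap_extend, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open + gap_extend, F[i - 1, j] + gap_extend)
            s = match if ai == b[j - 1] else mismatch
            diag = H[i - 1, j - 1] + s
            h = max(0.0, diag, E[i, j], F[i, j])
            H[i, j] = h
            if h == 0:
                ptr[i, j] = 0
            elif h == diag:
                ptr[i, j] = 1
            elif h == E[i, j]:
                ptr[i, j] = 2
            else:
                ptr[i, j] = 3
            if h > best:
                best = h
                best_pos = (i, j)
    # traceback for identity count
    i, j = best_pos
    ident = cols = 0
    while i > 0 and j > 0 and H[i, j] > 0 and ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            ident += a[i - 1] == b[j - 1]
            cols += 1
            i, j = i - 1, j - 1
        elif p == 2:
            cols += 1
            j -= 1
        else:
            cols += 1
            i -= 1
    return best, ident, cols


def mutate(seq: str, fraction: float, rng: np.random.Generator) -> tuple[str, int]:
    """Substitute a Bernoulli(fraction) set of sites; returns (seq, n_sub)."""
    arr = np.array(list(seq))
    pos = np.nonzero(rng.random(len(seq)) < fraction)[0]
    for i in pos:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr), len(pos)


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def rand_index(part_a: dict[str, str], part_b: dict[str, str]) -> float:
    """Rand index between two partitions given as item -> block label."""
    items = sorted(part_a)
    assert sorted(part_b) == items
    agree = total = 0
    for x, y in itertools.combinations(items, 2):
        same_a = part_a[x] == part_a[y]
        same_b = part_b[x] == part_b[y]
        agree += same_a == same_b
        total += 1
    return agree / total if total else 1.0


def random_additive_tree(
    n_taxa: int, rng: np.random.Generator
) -> tuple[str, "np.ndarray", list[str]]:
    """A random binary unrooted tree with positive branch lengths and its
    exact path-length distance matrix (the inverse problem for infer_tree)."""
    import io

    from skbio import TreeNode

    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [f"{lab}:{rng.uniform(0.5, 5):.3f}" for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False), reverse=True)
        a = nodes.pop(i)
        b = nodes.pop(j)
        nodes.append(f"({a},{b}):{rng.uniform(0.5, 5):.3f}")
    newick = f"({','.join(nodes)});"
    tree = TreeNode.read(io.StringIO(newick))
    dm = tree.tip_tip_distances()
    import pandas as pd

    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    df = df.loc[labels, labels]
    return newick, df, labels


def brute_force_clades(tree) -> set[frozenset]:
    """All tip sets of a rooted tree, by direct traversal."""
    out = set()
    for node in tree.traverse(include_self=True):
        tips = frozenset(t.name for t in node.tips()) or frozenset({node.name})
        out.add(tips)
    return out
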