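"""Independent reference implementations used only to cross-check the
package: deliberately written in a different style (dict-based, recursive)
from the production code they validate."""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# EF-hand loop: explicit per-position check, no regex

_EF_RULES = {
    0: lambda a: a == "D",
    2: lambda a: a in "DNS",
    3: lambda a: a not in "ILVFYW",
    4: lambda a: a in "DENSTG",
    5: lambda a: a in "DNQGHRK",
    6: lambda a: a not in "GP",
    7: lambda a: a in "LIVMC",
    8: lambda a: a in "DENQSTAGC",
    11: lambda a: a in "DE",
    12: lambda a: a in "LIVMFYW",
}


def ef_loop_matches_at(seq: str, pos: int) -> bool:
    if pos + 13 > len(seq):
        return False
    return all(rule(seq[pos + off]) for off, rule in _EF_RULES.items())


def ef_hand_starts(seq: str) -> list[int]:
    """Greedy leftmost non-overlapping EF-hand loop matches."""
    out, i = [], 0
    while i + 13 <= len(seq):
        if ef_loop_matches_at(seq, i):
            out.append(i)
            i += 13
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# kinase triad predicate (order + spacing recheck for any claimed span)

def kinase_triad_present(seq: str, gap_min: int = 10, gap_max: int = 120) -> bool:
    n = len(seq)
    vaik = [
        i for i in range(n - 3)
        if seq[i] in "LIVMF" and seq[i + 2] in "LIVMF" and seq[i + 3] == "K"
    ]
    hrd = [i for i in range(n - 2) if seq[i:i + 3] == "HRD"]
    dfg = [i for i in range(n - 2) if seq[i:i + 3] == "DFG"]
    for v in vaik:
        for h in hrd:
            if not gap_min <= h - (v + 4) <= gap_max:
                continue
            for d in dfg:
                if gap_min <= d - (h + 3) <= gap_max:
                    return True
    return False


# ---------------------------------------------------------------------------
# exhaustive global alignment with affine gaps (tiny sequences only)

def best_alignment_score(
    a: str, b: str, score, gap_open: float, gap_extend: float
) -> float:
    """Enumerate every global alignment path recursively; affine gap cost:
    the first column of a gap costs the open penalty, each continuation
    column the extend penalty."""

    best = [-np.inf]

    def recurse(i: int, j: int, acc: float, last: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], acc)
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, acc + score(a[i], b[j]), "m")
        if i < len(a):
            cost = gap_extend if last == "a" else gap_open
            recurse(i + 1, j, acc - cost, "a")
        if j < len(b):
            cost = gap_extend if last == "b" else gap_open
            recurse(i, j + 1, acc - cost, "b")

    recurse(0, 0, 0.0, "m")
    return best[0]


# ---------------------------------------------------------------------------
# naive neighbor joining over dict-of-dicts, recomputing Q from scratch

def nj_bipartitions(labels, matrix) -> tuple[set[frozenset], list[float]]:
    """Run textbook NJ and return the unrooted bipartitions (canonicalised
    as the side without the smallest label) plus the sorted branch-length
    multiset (negatives clamped to zero)."""
    clusters = [frozenset([lab]) for lab in labels]
    d = {
        frozenset((clusters[i], clusters[j])): float(matrix[i][j])
        for i, j in itertools.combinations(range(len(labels)), 2)
    }
    lengths: list[float] = []
    splits: set[frozenset] = set()

    def dist(x, y):
        return d[frozenset((x, y))]

    while len(clusters) > 3:
        m = len(clusters)
        r = {x: sum(dist(x, y) for y in clusters if y != x) for x in clusters}
        best_pair, best_q = None, None
        for x, y in sorted(
            itertools.combinations(clusters, 2),
            key=lambda p: tuple(sorted((min(p[0]), min(p[1])))),
        ):
            q = (m - 2) * dist(x, y) - r[x] - r[y]
            if best_q is None or q < best_q - 1e-12:
                best_pair, best_q = (x, y), q
        x, y = best_pair
        dxy = dist(x, y)
        lx = 0.5 * dxy + (r[x] - r[y]) / (2 * (m - 2))
        ly = dxy - lx
        lengths += [max(lx, 0.0), max(ly, 0.0)]
        merged = x | y
        splits.add(merged)
        for z in clusters:
            if z in (x, y):
                continue
            d[frozenset((merged, z))] = 0.5 * (dist(x, z) + dist(y, z) - dxy)
        clusters = [z for z in clusters if z not in (x, y)] + [merged]

    (a, b, c) = clusters
    dab, dac, dbc = dist(a, b), dist(a, c), dist(b, c)
    lengths += [
        max(0.5 * (dab + dac - dbc), 0.0),
        max(0.5 * (dab + dbc - dac), 0.0),
        max(0.5 * (dac + dbc - dab), 0.0),
    ]

    all_leaves = frozenset(labels)
    anchor = min(labels)
    canon = set()
    for s in splits:
        if len(s) < 2 or len(s) > len(labels) - 2:
            continue
        canon.add(all_leaves - s if anchor in s else s)
    return canon, sorted(lengths)


# ---------------------------------------------------------------------------
# brute-force complete-linkage agglomeration

def complete_linkage_heights(points: np.ndarray) -> list[float]:
    """Merge heights of complete-linkage clustering, smallest-first."""
    clusters = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            h = max(
                float(np.linalg.norm(points[p] - points[q]))
                for p in clusters[i]
                for q in clusters[j]
            )
            if best is None or h < best[0]:
                best = (h, i, j)
        h, i, j = best
        heights.append(h)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return heights


def random_additive_matrix(rng: np.random.Generator, n: int):
    """Random unrooted binary tree on n leaves; returns (labels, distance
    matrix, bipartition set) with distances summed along tree paths."""
    labels = [chr(ord("A") + i) for i in range(n)]
    # random sequential join of subtrees; leaf->root paths tracked by edges
    import networkx as nx

    g = nx.Graph()
    nodes = list(labels)
    g.add_nodes_from(nodes)
    nxt = 0
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        inner = f"n{nxt}"
        nxt += 1
        g.add_edge(nodes[i], inner, weight=float(rng.uniform(0.5, 3.0)))
        g.add_edge(nodes[j], inner, weight=float(rng.uniform(0.5, 3.0)))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [inner]
    center = f"n{nxt}"
    for x in nodes:
        g.add_edge(x, center, weight=float(rng.uniform(0.5, 3.0)))
    dmat = np.zeros((n, n))
    paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    for i, j in itertools.combinations(range(n), 2):
        dmat[i, j] = dmat[j, i] = paths[labels[i]][labels[j]]
    # true bipartitions from internal edges
    all_leaves = frozenset(labels)
    anchor = min(labels)
    splits = set()
    for u, v in g.edges():
        if str(u).startswith("n") and str(v).startswith("n"):
            h = g.copy()
            h.remove_edge(u, v)
            comp = nx.node_connected_component(h, u)
            side = frozenset(x for x in comp if not str(x).startswith("n"))
            if 2 <= len(side) <= n - 2:
                splits.add(all_leaves - side if anchor in side else side)
    return labels, dmat, splits
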