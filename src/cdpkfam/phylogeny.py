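"""Distance-based phylogeny: pairwise global alignment, p-distances,
Saitou-Nei neighbor joining with bootstrap supports, and clade-based group
assignment against labelled reference sequences.

Pairwise alignments use Needleman-Wunsch with affine gaps (BLOSUM62,
open 10 / extend 0.5 by default) via Biopython's PairwiseAligner; the
neighbor-joining algorithm itself, bootstrap bipartition counting and the
reference-clade group assignment are implemented here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import TreeNode

from .errors import InputError, InvariantError
from .seqio import ProteinRecord

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5
DEFAULT_MATRIX = "BLOSUM62"


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences, as gapped strings."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise InvariantError("aligned strings differ in length")


@dataclass(frozen=True)
class PairwiseStats:
    coverage: float
    identity: float
    identity_undefined: bool = False


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise InvariantError("distance matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise InputError("duplicate labels in distance matrix")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise InputError("distance matrix is not symmetric")
        if (np.diag(self.d) != 0).any():
            raise InvariantError("nonzero diagonal in distance matrix")
        if (self.d < -1e-12).any():
            raise InvariantError("negative distances")


def _make_aligner(gap_open: float, gap_extend: float, matrix: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_align(
    a: str,
    b: str,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    matrix: str = DEFAULT_MATRIX,
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences (affine gaps)."""
    if not a or not b:
        raise InputError("cannot align an empty sequence")
    for name, seq in (("first", a), ("second", b)):
        bad = set(seq.upper()) - PROTEIN_ALPHABET
        if bad:
            raise InputError(f"non-residue characters in {name} sequence: {bad}")
    aligner = _make_aligner(gap_open, gap_extend, matrix)
    aln = aligner.align(a.upper(), b.upper())[0]
    return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score))


def pairwise_stats(alignment: PairwiseAlignment, len_longer: int) -> PairwiseStats:
    """Coverage and identity of an alignment.

    coverage  = residue-residue columns / length of the longer sequence
    identity  = identical columns / residue-residue columns (gap-excluded)
    A fully gapped alignment has identity reported as 0 with a flag.
    """
    both = matches = 0
    for x, y in zip(alignment.aligned_a, alignment.aligned_b):
        if x != "-" and y != "-":
            both += 1
            if x == y:
                matches += 1
    coverage = both / len_longer if len_longer else 0.0
    if both == 0:
        return PairwiseStats(0.0, 0.0, identity_undefined=True)
    return PairwiseStats(coverage, matches / both)


def pairwise_identity(a: str, b: str, **align_kwargs) -> PairwiseStats:
    """Convenience: align two sequences and report coverage/identity."""
    aln = global_align(a, b, **align_kwargs)
    return pairwise_stats(aln, max(len(a), len(b)))


def p_distance_matrix(records: list[ProteinRecord], **align_kwargs) -> DistanceMatrix:
    """All-against-all p-distances (1 - gap-excluded alignment identity)."""
    if len(records) < 3:
        raise InputError("need at least 3 records for a distance matrix")
    labels = [r.id for r in records]
    if len(set(labels)) != len(labels):
        raise InputError("duplicate record ids")
    n = len(records)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        stats = pairwise_identity(records[i].sequence, records[j].sequence,
                                  **align_kwargs)
        d[i, j] = d[j, i] = 1.0 - stats.identity
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classical Saitou-Nei neighbor joining.

    Iteratively joins the pair (i, j) minimising
    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k),
    with branch lengths from the standard formulas.  Ties in Q are broken
    by the lexicographically smallest sorted label pair, negative branch
    estimates are clamped to zero, and the result is an unrooted tree
    (trifurcation at the root) with n - 2 internal nodes.
    """
    n = len(dm.labels)
    if n < 3:
        raise InputError("neighbor joining needs at least 3 taxa")
    # active nodes and the working copy of the distance matrix
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    # sort key per active node: smallest leaf label under it (for tie-breaks)
    keys: list[str] = list(dm.labels)
    d = dm.d.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None  # (q, labelpair, i, j)
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair, i, j)
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and pair < best[1]
                ):
                    best = cand
        _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        # distances from the new node to every other active node
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_next = np.zeros((m - 1, m - 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = d_next[:-1, -1] = dnew[keep]
        d = d_next
        new_key = min(keys[i], keys[j])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [new_key]

    # final trifurcation: three-taxon closed form
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = max(0.5 * (dab + dac - dbc), 0.0)
    b.length = max(0.5 * (dab + dbc - dac), 0.0)
    c.length = max(0.5 * (dac + dbc - dab), 0.0)
    # deterministic child order at the root
    order = np.argsort([keys[0], keys[1], keys[2]])
    root = TreeNode()
    root.extend([nodes[k] for k in order])
    return root


# ---------------------------------------------------------------------------
# Bootstrap

def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalised as the leaf set NOT
    containing the lexicographically smallest leaf label."""
    leaves = sorted(t.name for t in tree.tips())
    if len(leaves) < 4:
        return set()
    anchor = leaves[0]
    all_leaves = frozenset(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        if anchor in side:
            side = all_leaves - side
        out.add(side)
    return out


def msa_p_distances(labels: list[str], rows: list[str]) -> DistanceMatrix:
    """p-distances from aligned rows, ignoring columns where either has a gap."""
    if len({len(r) for r in rows}) != 1:
        raise InputError("aligned rows have unequal lengths (ragged MSA)")
    n = len(rows)
    d = np.zeros((n, n))
    arr = np.array([list(r.upper()) for r in rows])
    gap = arr == "-"
    for i, j in itertools.combinations(range(n), 2):
        ok = ~(gap[i] | gap[j])
        n_ok = int(ok.sum())
        d[i, j] = d[j, i] = (
            float((arr[i, ok] != arr[j, ok]).mean()) if n_ok else 1.0
        )
    return DistanceMatrix(list(labels), d)


def bootstrap_supports(
    labels: list[str],
    rows: list[str],
    n_replicates: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """NJ tree from an MSA with bootstrap supports on internal nodes.

    Columns are resampled with replacement per replicate; the support of
    each internal bipartition of the point-estimate tree is the percentage
    of replicate trees containing it, stored as an integer internal node
    name.  Fully reproducible for a fixed seed, and invariant to the input
    row order because distances and tie-breaks depend only on labels.
    """
    if n_replicates < 1:
        raise InputError("n_replicates must be >= 1")
    # canonical row order by label: makes supports independent of input order
    order = np.argsort(labels, kind="stable")
    labels = [labels[k] for k in order]
    rows = [rows[k] for k in order]

    point = neighbor_joining(msa_p_distances(labels, rows))
    target = _bipartitions(point)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    ncol = len(rows[0])
    arr = np.array([list(r) for r in rows])
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = ["".join(row) for row in arr[:, cols]]
        rep_tree = neighbor_joining(msa_p_distances(labels, rep_rows))
        for bp in _bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1
    for node in point.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        leaves = sorted(t.name for t in point.tips())
        if leaves and leaves[0] in side:
            side = frozenset(leaves) - side
        if side in counts:
            node.name = str(round(100.0 * counts[side] / n_replicates))
    return point


# ---------------------------------------------------------------------------
# Group assignment

def assign_groups(
    tree: TreeNode, reference_labels: dict[str, str]
) -> dict[str, str]:
    """Assign each non-reference leaf to a group by reference-clade purity.

    For each query leaf, consider every bipartition side containing the
    query and at least one reference; take the smallest such side.  If all
    references on it carry one group label, the query gets that label,
    otherwise "unassigned".
    """
    from collections import Counter

    group_sizes = Counter(reference_labels.values())
    small = [g for g, c in group_sizes.items() if c < 2]
    if small:
        raise InputError(f"reference groups with < 2 members: {small}")
    leaf_names = [t.name for t in tree.tips()]
    missing = set(reference_labels) - set(leaf_names)
    if missing:
        raise InputError(f"reference leaves missing from tree: {sorted(missing)}")

    all_leaves = frozenset(leaf_names)
    sides: list[frozenset[str]] = []
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 0 < len(side) < len(all_leaves):
            sides.append(side)
            sides.append(all_leaves - side)
    refs = set(reference_labels)

    result: dict[str, str] = {}
    for query in leaf_names:
        if query in refs:
            continue
        candidates = [
            s for s in sides if query in s and any(r in s for r in refs)
        ]
        if not candidates:
            result[query] = "unassigned"
            continue
        smallest = min(candidates, key=lambda s: (len(s), tuple(sorted(s))))
        groups = {reference_labels[r] for r in smallest & refs}
        result[query] = groups.pop() if len(groups) == 1 else "unassigned"
    return result
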