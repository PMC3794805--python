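"""Distance-based phylogeny: progressive multiple alignment, p-distances,
neighbor joining and column-resampling bootstrap.

The tree stage follows the classic survey recipe: align the full-length
protein sequences, compute pairwise p-distances (fraction of differing
positions over columns where both sequences carry a residue), build a
neighbor-joining tree, and attach bootstrap support as the percentage of
column-resampled replicate trees containing each internal bipartition.

Numerical conventions: the Q-minimal pair is joined with ties broken by
the lexicographically smallest (leaf-label) pair; negative NJ branch
length estimates are clamped to zero and counted on the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import ScoringScheme, global_align, _named_matrix
from .seqio import logger

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}


@dataclass
class Msa:
    """Equal-length gapped rows, ordered as the input."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(set(len(r) for r in self.rows)) > 1:
            raise ValueError("MSA rows have unequal lengths")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_matrix(self) -> np.ndarray:
        return np.frombuffer("".join(self.rows).encode(), dtype=np.uint8
                             ).reshape(len(self.rows), -1)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(m, m.T) or (np.diag(m) != 0).any() or (m < 0).any():
            raise ValueError("distance matrix must be symmetric, "
                             "non-negative, zero-diagonal")
        self.matrix = m


@dataclass
class TreeNode:
    """Node of a (rooted representation of an) unrooted binary tree."""

    name: str | None = None  # leaf label
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None  # bootstrap %, internal edges only

    def leaves(self) -> list[str]:
        if self.name is not None:
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def is_leaf(self) -> bool:
        return self.name is not None


@dataclass
class PhyloTree:
    root: TreeNode
    negative_branches_clamped: int = 0

    def leaf_names(self) -> list[str]:
        return self.root.leaves()

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalized as the side not
        containing the globally smallest leaf label."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        n = len(all_leaves)
        out: set[frozenset] = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                below |= walk(child)
            if 2 <= len(below) <= n - 2:
                side = below if anchor not in below else all_leaves - below
                if 2 <= len(side) <= n - 2:
                    out.add(side)
            return below

        walk(self.root)
        return out

    def newick(self, with_support: bool = False) -> str:
        def fmt(node: TreeNode, length: float | None) -> str:
            if node.is_leaf():
                body = node.name
            else:
                inner = ",".join(fmt(c, ln) for c, ln in node.children)
                label = ""
                if with_support and node.support is not None:
                    label = f"{node.support:g}"
                body = f"({inner}){label}"
            if length is None:
                return body
            return f"{body}:{length:.6g}"
        return fmt(self.root, None) + ";"


def p_distance(msa: Msa) -> DistanceMatrix:
    """Pairwise mismatch fractions over columns where both rows carry a
    residue; a pair with no comparable columns is an error."""
    if len(msa.rows) < 2:
        raise ValueError("need >= 2 rows")
    mat = msa.to_matrix()
    gap = mat == ord("-")
    n = len(msa.rows)
    d = np.zeros((n, n))
    for i in range(n):
        both = ~gap[i] & ~gap[i + 1:]
        comparable = both.sum(axis=1)
        if (comparable == 0).any():
            j = int(np.argmax(comparable == 0)) + i + 1
            raise ValueError(f"no comparable columns between rows {i} and {j}")
        diff = ((mat[i] != mat[i + 1:]) & both).sum(axis=1)
        d[i, i + 1:] = diff / comparable
    d = d + d.T
    return DistanceMatrix(msa.ids, d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei agglomeration with deterministic tie-breaking.

    Q(i,j) = (n-2) d(i,j) - r_i - r_j; the Q-minimal pair joins first
    (ties to the smallest leaf-label pair); branch lengths use the
    rate-corrected split formula and are clamped at zero when the
    estimate is negative.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("neighbor joining needs >= 2 taxa")
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    if n == 2:
        d = dm.matrix[0, 1]
        root = TreeNode(children=[(TreeNode(name=dm.ids[0]), d / 2),
                                  (TreeNode(name=dm.ids[1]), d / 2)])
        return PhyloTree(root, 0)

    nodes = [TreeNode(name=i) for i in dm.ids]
    keys = list(dm.ids)  # smallest leaf label under each active node
    D = dm.matrix.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        best = min(
            ((a, b) for a, b in ties if a < b),
            key=lambda ab: tuple(sorted((keys[active[ab[0]]],
                                         keys[active[ab[1]]]))),
        )
        ia, ib = best
        i, j = active[ia], active[ib]
        dij = D[i, j]
        li = dij / 2 + (r[ia] - r[ib]) / (2 * (m - 2))
        lj = dij - li
        new = TreeNode(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        # distances from the new node to the remaining actives
        dnew = np.zeros(D.shape[0] + 1)
        rest = [k for k in active if k not in (i, j)]
        for k in rest:
            dnew[k] = (D[i, k] + D[j, k] - dij) / 2
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = dnew[:-1]
        D[:-1, -1] = dnew[:-1]
        nodes.append(new)
        keys.append(min(keys[i], keys[j]))
        active = rest + [len(nodes) - 1]

    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    root = TreeNode(children=[(nodes[a], clamp(la)), (nodes[b], clamp(lb)),
                              (nodes[c], clamp(lc))])
    tree = PhyloTree(root, clamped)
    if clamped:
        logger.warning("neighbor_joining: clamped %d negative branch "
                       "lengths to 0", clamped)
    return tree


# ------------------------------------------------------- progressive MSA

def _substitution_matrix_20(scoring: ScoringScheme | None) -> np.ndarray:
    name = (scoring.matrix_name if scoring and scoring.matrix_name
            else "BLOSUM62")
    arr = _named_matrix(name)
    m = np.zeros((20, 20))
    for i, x in enumerate(_AA):
        for j, y in enumerate(_AA):
            m[i, j] = arr[x, y]
    return m


def _profile_counts(rows: list[str]) -> np.ndarray:
    L = len(rows[0])
    counts = np.zeros((L, 20))
    for row in rows:
        idx = np.array([_AA_INDEX.get(c, -1) for c in row])
        ok = idx >= 0
        counts[np.nonzero(ok)[0], idx[ok]] += 1
    return counts


def _align_profiles(rows_a: list[str], rows_b: list[str], m20: np.ndarray,
                    gap: float) -> tuple[list[str], list[str]]:
    """Linear-gap profile-profile alignment by sum-of-pairs score;
    deterministic traceback (diagonal > up > left)."""
    pa = _profile_counts(rows_a)
    pb = _profile_counts(rows_b)
    La, Lb = pa.shape[0], pb.shape[0]
    S = pa @ m20 @ pb.T  # (La, Lb) sum-of-pairs column scores
    D = np.full((La + 1, Lb + 1), -np.inf)
    D[0, 0] = 0.0
    D[1:, 0] = -gap * np.arange(1, La + 1)
    D[0, 1:] = -gap * np.arange(1, Lb + 1)
    for i in range(1, La + 1):
        cand = np.maximum(D[i - 1, :-1] + S[i - 1], D[i - 1, 1:] - gap)
        # running-max trick for the left (gap in A) dependency
        row = np.empty(Lb + 1)
        row[0] = D[i, 0]
        shifted = np.empty(Lb + 1)
        shifted[0] = row[0]
        shifted[1:] = cand
        jj = np.arange(Lb + 1)
        acc = np.maximum.accumulate(shifted + gap * jj)
        row = acc - gap * jj
        D[i] = row
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = La, Lb
    gap_a = "-" * len(rows_a)
    gap_b = "-" * len(rows_b)
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(D[i, j], D[i - 1, j - 1] + S[i - 1, j - 1]):
            out_a.append("".join(r[i - 1] for r in rows_a))
            out_b.append("".join(r[j - 1] for r in rows_b))
            i, j = i - 1, j - 1
        elif i > 0 and np.isclose(D[i, j], D[i - 1, j] - gap):
            out_a.append("".join(r[i - 1] for r in rows_a))
            out_b.append(gap_b)
            i -= 1
        else:
            out_a.append(gap_a)
            out_b.append("".join(r[j - 1] for r in rows_b))
            j -= 1
    cols_a = out_a[::-1]
    cols_b = out_b[::-1]
    new_a = ["".join(col[k] for col in cols_a) for k in range(len(rows_a))]
    new_b = ["".join(col[k] for col in cols_b) for k in range(len(rows_b))]
    return new_a, new_b


def progressive_msa(entries, scoring: ScoringScheme | None = None) -> Msa:
    """Progressive alignment: NJ guide tree on pairwise global-alignment
    p-distances, profiles merged in guide-tree (post-)order."""
    ids = [e.id for e in entries]
    seqs = [e.sequence for e in entries]
    if len(seqs) == 0:
        raise ValueError("no sequences")
    if len(seqs) == 1:
        return Msa(ids, [seqs[0]])
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[i], seqs[j], scoring)
            mism = sum(1 for x, y in zip(aln.aligned_a, aln.aligned_b)
                       if x != "-" and y != "-" and x != y)
            d[i, j] = d[j, i] = (mism / aln.aligned_length
                                 if aln.aligned_length else 1.0)
    if n == 2:
        aln = global_align(seqs[0], seqs[1], scoring)
        return Msa(ids, [aln.aligned_a, aln.aligned_b])
    guide = neighbor_joining(DistanceMatrix([str(i) for i in range(n)], d))
    m20 = _substitution_matrix_20(scoring)
    gap = ((scoring.gap_open + scoring.gap_extend) if scoring
           else 11.0)

    def merge(node: TreeNode) -> tuple[list[int], list[str]]:
        if node.is_leaf():
            k = int(node.name)
            return [k], [seqs[k]]
        parts = [merge(child) for child, _ in node.children]
        idx, rows = parts[0]
        for idx_b, rows_b in parts[1:]:
            rows, rows_b = _align_profiles(rows, rows_b, m20, gap)
            idx = idx + idx_b
            rows = rows + rows_b
        return idx, rows

    idx, rows = merge(guide.root)
    order = np.argsort(idx)
    return Msa([ids[idx[k]] for k in order], [rows[k] for k in order])


def bootstrap_support(msa: Msa, replicates: int = 1000,
                      seed: int | None = 0) -> PhyloTree:
    """NJ tree from the full MSA with bootstrap supports.

    Columns are resampled with replacement; the p-distance + NJ pipeline
    is rebuilt per replicate; each internal edge of the point tree gets
    the percentage of replicate trees containing its bipartition.
    """
    if len(msa.rows) < 4:
        raise ValueError("bootstrap needs >= 4 sequences")
    point = neighbor_joining(p_distance(msa))
    rng = np.random.default_rng(seed)
    mat = msa.to_matrix()
    gap = mat == ord("-")
    counts: dict[frozenset, int] = {bp: 0 for bp in point.bipartitions()}
    n = len(msa.rows)
    L = msa.n_columns
    for _ in range(replicates):
        cols = rng.integers(0, L, L)
        sub = mat[:, cols]
        subgap = gap[:, cols]
        d = np.zeros((n, n))
        ok = True
        for i in range(n):
            both = ~subgap[i] & ~subgap[i + 1:]
            comparable = both.sum(axis=1)
            if (comparable == 0).any():
                ok = False
                break
            diff = ((sub[i] != sub[i + 1:]) & both).sum(axis=1)
            d[i, i + 1:] = diff / comparable
        if not ok:
            continue
        rep = neighbor_joining(DistanceMatrix(msa.ids, d + d.T))
        rep_bp = rep.bipartitions()
        for bp in counts:
            if bp in rep_bp:
                counts[bp] += 1

    def attach(node: TreeNode, all_leaves: frozenset, anchor: str) -> frozenset:
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset()
        for child, _ in node.children:
            below |= attach(child, all_leaves, anchor)
        side = below if anchor not in below else all_leaves - below
        if side in counts:
            node.support = 100.0 * counts[side] / replicates
        return below

    leaves = frozenset(point.leaf_names())
    attach(point.root, leaves, min(leaves))
    return point
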