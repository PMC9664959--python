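"""Distance-based phylogeny: Poisson-corrected distances, neighbor joining,
Newick I/O, and anchor-based clade assignment.

This is the desk-scale stand-in for a maximum-likelihood protein tree: the
pairwise distance between two aligned rows is the Poisson correction
``d = -ln(1 - p)`` of the mismatch fraction ``p`` over columns where neither
row has a gap (pairwise gap deletion); neighbor joining is the classic
Saitou-Nei agglomeration with the Q-criterion, deterministic tie-breaking
(first minimal pair in input order), and negative branch lengths clamped to
zero with the deficit moved to the sister branch. Trees are scikit-bio
``TreeNode`` objects, so Newick round-trips through ``skbio``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

#: Mismatch fractions at or above this are capped (the Poisson correction
#: diverges as p -> 1).
MAX_P = 0.95


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    capped: np.ndarray  # boolean mask of capped entries

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        self.matrix = m


def pairwise_distance(a: str, b: str) -> tuple[float, bool]:
    """Poisson-corrected distance between two equal-length aligned rows.

    Columns where either row has a gap are skipped; returns ``(d, capped)``
    where ``capped`` marks mismatch fractions >= 0.95 truncated at
    ``-ln(0.05)``. Raises if no comparable columns remain.
    """
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    compared = 0
    mismatch = 0
    for ca, cb in zip(a, b):
        if ca == "-" or cb == "-":
            continue
        compared += 1
        if ca != cb:
            mismatch += 1
    if compared == 0:
        raise ValueError("no comparable (gap-free) columns between rows")
    p = mismatch / compared
    if p >= MAX_P:
        return -math.log(1.0 - MAX_P), True
    return (0.0 if p == 0 else -math.log(1.0 - p)), False


def distance_matrix(ids, rows) -> DistanceMatrix:
    """All pairwise Poisson-corrected distances over aligned rows."""
    ids = list(ids)
    rows = list(rows)
    n = len(ids)
    m = np.zeros((n, n))
    capped = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            d, c = pairwise_distance(rows[i], rows[j])
            m[i, j] = m[j, i] = d
            capped[i, j] = capped[j, i] = c
    return DistanceMatrix(ids=ids, matrix=m, capped=capped)


# --------------------------------------------------------------------------
# Neighbor joining
# --------------------------------------------------------------------------


def nj_tree(D: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Ties in the Q-criterion are broken by the first minimal (i, j) pair in
    the current working order (derived from the input id order), which makes
    the output deterministic. Requires >= 3 taxa; 2 taxa return the trivial
    two-leaf tree as a documented special case.
    """
    n = len(D.ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes = [TreeNode(name=i) for i in D.ids]
    if n == 2:
        root = TreeNode()
        a, b = nodes
        a.length = D.matrix[0, 1] / 2.0
        b.length = D.matrix[0, 1] / 2.0
        root.extend([a, b])
        return root
    d = D.matrix.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        best_q = math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        # clamp negatives; the deficit moves to the sister branch
        li = max(li, 0.0)
        lj = max(d[i, j] - li, 0.0)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        # distances from the new node u: d(u,k) = (d(i,k)+d(j,k)-d(i,j))/2
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = max((d[i, k] + d[j, k] - d[i, j]) / 2.0, 0.0)
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        d[u, :-1] = new_row[:-1]
        d[:-1, u] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [u]
    # three remaining nodes join a central node; closed-form branch lengths
    i, j, k = active
    li = (d[i, j] + d[i, k] - d[j, k]) / 2.0
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2.0
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
    root = TreeNode()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(ln, 0.0)
        root.append(nodes[idx])
    return root


# --------------------------------------------------------------------------
# Newick I/O
# --------------------------------------------------------------------------


def write_newick(tree: TreeNode, path=None, decimals: int = 6) -> str:
    """Serialize with branch lengths rounded to ``decimals``; rewriting the
    parsed output reproduces the same bytes."""
    t = tree.copy()
    for node in t.traverse():
        if node.length is not None:
            node.length = round(node.length, decimals)
    buf = io.StringIO()
    t.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_newick(source) -> TreeNode:
    if isinstance(source, str) and source.lstrip().startswith("("):
        return TreeNode.read(io.StringIO(source), format="newick")
    return TreeNode.read(str(source), format="newick")


# --------------------------------------------------------------------------
# Clade assignment
# --------------------------------------------------------------------------


def assign_clades(tree: TreeNode, anchors: dict[str, str]) -> dict[str, str | None]:
    """Assign every leaf the clade of its nearest anchor by path length.

    ``anchors`` maps leaf name -> clade label; every clade must have at least
    one anchor present in the tree. Leaves equidistant from anchors of
    different clades are left unassigned (``None``).
    """
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(anchors) - tips)
    if missing:
        raise ValueError(f"anchor leaves not in tree: {missing}")
    clades = sorted(set(anchors.values()))
    if not clades:
        raise ValueError("no anchors supplied")
    dm = tree.tip_tip_distances()
    out: dict[str, str | None] = {}
    for leaf in tips:
        if leaf in anchors:
            out[leaf] = anchors[leaf]
            continue
        best: dict[str, float] = {}
        for anchor, clade in anchors.items():
            dist = dm[leaf, anchor]
            if clade not in best or dist < best[clade]:
                best[clade] = dist
        ranked = sorted(best.items(), key=lambda kv: kv[1])
        if len(ranked) > 1 and math.isclose(
            ranked[0][1], ranked[1][1], rel_tol=0, abs_tol=1e-12
        ):
            out[leaf] = None
        else:
            out[leaf] = ranked[0][0]
    return out


def write_distance_matrix(D: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(D.ids) + "\n")
        for i, name in enumerate(D.ids):
            fh.write(
                name + "\t" + "\t".join(f"{v:.6f}" for v in D.matrix[i]) + "\n"
            )
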