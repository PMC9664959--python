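"""Pairwise protein alignment with affine gap penalties and Karlin-Altschul statistics.

In-package replacements for the BLAST and CD-HIT steps of the
similarity-network pipeline: Needleman-Wunsch global and Smith-Waterman local
alignment under BLOSUM62 with affine gap cost ``gap(k) = gap_open +
k * gap_extend`` (BLAST's 11/1 convention, so a length-1 gap costs 12),
E-values from the Karlin-Altschul formula ``E = K * m * n * exp(-lambda * S)``,
and greedy incremental redundancy reduction at an identity threshold
(CD-HIT-style, longest sequence first).

Scores are integers throughout (BLOSUM62 entries and gap penalties are
integers), which makes traceback tie-breaking exact: ties are resolved
diagonal > up > left, deterministically.

The dynamic-programming inner loops are JIT-compiled with numba; everything
else is plain numpy/Python.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

# --------------------------------------------------------------------------
# Alphabet, scoring matrix, background frequencies
# --------------------------------------------------------------------------

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

#: BLOSUM62 amino-acid background frequencies (Robinson-Robinson style set
#: used with BLOSUM62), normalized to sum to 1. Order follows :data:`AA`.
_BG = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}
BACKGROUND = np.array([_BG[a] for a in AA], dtype=np.float64)
BACKGROUND /= BACKGROUND.sum()


def _load_blosum62() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20), dtype=np.int64)
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            out[i, j] = int(m[a, b])
    return out


BLOSUM62 = _load_blosum62()

_NEG = -(1 << 40)  # effectively -infinity for int64 DP


@dataclass
class ScoringParams:
    """Alignment scoring model plus Karlin-Altschul statistics.

    ``lam``/``K`` default to the standard gapped BLOSUM62 (11/1) constants;
    ``search_space_m``/``search_space_n`` default to the lengths of the two
    sequences being compared when left unset.
    """

    matrix: np.ndarray = field(default_factory=lambda: BLOSUM62.copy())
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    search_space_m: int | None = None
    search_space_n: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.shape != (20, 20):
            raise ValueError("substitution matrix must be 20x20")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be positive")


@dataclass
class AlignmentResult:
    """A directed pairwise-alignment result (one BLAST-like hit)."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    e_value: float
    identity: float
    query_coverage: float
    subject_coverage: float
    #: 1-based (query_pos, subject_pos) pairs; ``None`` marks a gap.
    aligned_pairs: list[tuple[int | None, int | None]] | None = None

    @property
    def n_columns(self) -> int:
        return 0 if self.aligned_pairs is None else len(self.aligned_pairs)


def encode(seq: str, seq_id: str = "sequence") -> np.ndarray:
    """Encode a protein string as int8 indices into :data:`AA`.

    Raises ``ValueError`` naming the offending symbol and its 1-based
    position on any character outside the 20-letter alphabet.
    """
    out = np.empty(len(seq), dtype=np.int8)
    for i, c in enumerate(seq):
        idx = AA_INDEX.get(c)
        if idx is None:
            raise ValueError(
                f"illegal residue {c!r} at position {i + 1} in {seq_id}"
            )
        out[i] = idx
    return out


# --------------------------------------------------------------------------
# DP kernels (numba)
# --------------------------------------------------------------------------


@njit(cache=True)
def _global_dp(x, y, smat, go, ge):
    n = x.shape[0]
    m = y.shape[0]
    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in subject (up)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in query (left)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = -(go + i * ge)
    for j in range(1, m + 1):
        Y[0, j] = -(go + j * ge)
    oe = go + ge
    for i in range(1, n + 1):
        xi = x[i - 1]
        for j in range(1, m + 1):
            s = smat[xi, y[j - 1]]
            d = M[i - 1, j - 1]
            if X[i - 1, j - 1] > d:
                d = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > d:
                d = Y[i - 1, j - 1]
            if d > _NEG:
                M[i, j] = d + s
            a = M[i - 1, j] - oe
            b = Y[i - 1, j] - oe
            c = X[i - 1, j] - ge
            v = a
            if b > v:
                v = b
            if c > v:
                v = c
            X[i, j] = v
            a = M[i, j - 1] - oe
            b = X[i, j - 1] - oe
            c = Y[i, j - 1] - ge
            v = a
            if b > v:
                v = b
            if c > v:
                v = c
            Y[i, j] = v
    return M, X, Y


@njit(cache=True)
def _global_traceback(x, y, smat, go, ge, M, X, Y):
    n = x.shape[0]
    m = y.shape[0]
    oe = go + ge
    qpos = np.empty(n + m, dtype=np.int32)
    spos = np.empty(n + m, dtype=np.int32)
    k = 0
    i, j = n, m
    # end state: prefer M (diagonal) > X (up) > Y (left)
    best = M[n, m]
    state = 0
    if X[n, m] > best:
        best, state = X[n, m], 1
    if Y[n, m] > best:
        best, state = Y[n, m], 2
    while i > 0 or j > 0:
        if state == 0:
            qpos[k] = i
            spos[k] = j
            k += 1
            target = M[i, j] - smat[x[i - 1], y[j - 1]]
            i -= 1
            j -= 1
            if M[i, j] == target:
                state = 0
            elif X[i, j] == target:
                state = 1
            else:
                state = 2
        elif state == 1:
            qpos[k] = i
            spos[k] = -1
            k += 1
            here = X[i, j]
            i -= 1
            if M[i, j] == here + oe:
                state = 0
            elif X[i, j] == here + ge:
                state = 1
            else:
                state = 2
        else:
            qpos[k] = -1
            spos[k] = j
            k += 1
            here = Y[i, j]
            j -= 1
            if M[i, j] == here + oe:
                state = 0
            elif Y[i, j] == here + ge:
                state = 2
            else:
                state = 1
    return best, qpos[:k][::-1].copy(), spos[:k][::-1].copy()


@njit(cache=True)
def _local_dp(x, y, smat, go, ge):
    n = x.shape[0]
    m = y.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in query (left)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in subject (up)
    oe = go + ge
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        xi = x[i - 1]
        for j in range(1, m + 1):
            e = H[i, j - 1] - oe
            if E[i, j - 1] - ge > e:
                e = E[i, j - 1] - ge
            E[i, j] = e
            f = H[i - 1, j] - oe
            if F[i - 1, j] - ge > f:
                f = F[i - 1, j] - ge
            F[i, j] = f
            h = H[i - 1, j - 1] + smat[xi, y[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=True)
def _local_traceback(x, y, smat, go, ge, H, E, F, bi, bj):
    oe = go + ge
    n = x.shape[0]
    m = y.shape[0]
    qpos = np.empty(n + m, dtype=np.int32)
    spos = np.empty(n + m, dtype=np.int32)
    k = 0
    i, j = bi, bj
    mode = 0  # 0 = H, 1 = F (up run), 2 = E (left run)
    while True:
        if mode == 0:
            if H[i, j] == 0:
                break
            # prefer diagonal > up > left
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + smat[x[i - 1], y[j - 1]]:
                qpos[k] = i
                spos[k] = j
                k += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                mode = 1
            else:
                mode = 2
        elif mode == 1:
            qpos[k] = i
            spos[k] = -1
            k += 1
            here = F[i, j]
            i -= 1
            if H[i, j] == here + oe:
                mode = 0
            # else continue the F run
        else:
            qpos[k] = -1
            spos[k] = j
            k += 1
            here = E[i, j]
            j -= 1
            if H[i, j] == here + oe:
                mode = 0
    return qpos[:k][::-1].copy(), spos[:k][::-1].copy()


# --------------------------------------------------------------------------
# Public alignment API
# --------------------------------------------------------------------------


def estimate_evalue(
    raw_score: float,
    params: ScoringParams,
    m: int | None = None,
    n: int | None = None,
) -> float:
    """Karlin-Altschul expected number of chance hits, E = K*m*n*exp(-lambda*S)."""
    m = params.search_space_m if params.search_space_m is not None else m
    n = params.search_space_n if params.search_space_n is not None else n
    if m is None or n is None or m <= 0 or n <= 0:
        raise ValueError("search space sizes m and n must be positive")
    return params.K * m * n * math.exp(-params.lam * raw_score)


def bit_score(raw_score: float, params: ScoringParams) -> float:
    """Normalized score in bits, S' = (lambda*S - ln K) / ln 2."""
    return (params.lam * raw_score - math.log(params.K)) / math.log(2.0)


def _pairs_from_arrays(qpos: np.ndarray, spos: np.ndarray):
    return [
        (int(q) if q >= 0 else None, int(s) if s >= 0 else None)
        for q, s in zip(qpos, spos)
    ]


def _identity(x: np.ndarray, y: np.ndarray, qpos: np.ndarray, spos: np.ndarray) -> float:
    if len(qpos) == 0:
        return 0.0
    matches = 0
    for q, s in zip(qpos, spos):
        if q >= 0 and s >= 0 and x[q - 1] == y[s - 1]:
            matches += 1
    return matches / len(qpos)


def global_align(
    a: str,
    b: str,
    params: ScoringParams | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
    allow_empty: bool = False,
) -> AlignmentResult:
    """Optimal end-to-end (Needleman-Wunsch) alignment with affine gaps.

    Empty inputs are rejected unless ``allow_empty=True``, in which case the
    score is the full gap cost of the non-empty sequence (0 if both empty).
    """
    params = params or ScoringParams()
    if (not a or not b) and not allow_empty:
        raise ValueError("empty sequence (pass allow_empty=True to permit)")
    x = encode(a, f"query {query_id!r}")
    y = encode(b, f"subject {subject_id!r}")
    if len(a) == 0 or len(b) == 0:
        k = max(len(a), len(b))
        score = 0 if k == 0 else -(params.gap_open + k * params.gap_extend)
        pairs = [(i + 1, None) for i in range(len(a))] or [
            (None, j + 1) for j in range(len(b))
        ]
        if k == 0:
            pairs = []
        return AlignmentResult(
            query_id, subject_id, score, bit_score(score, params),
            estimate_evalue(score, params, max(len(a), 1), max(len(b), 1)),
            0.0, 1.0, 1.0, pairs,
        )
    M, X, Y = _global_dp(x, y, params.matrix, params.gap_open, params.gap_extend)
    score, qpos, spos = _global_traceback(
        x, y, params.matrix, params.gap_open, params.gap_extend, M, X, Y
    )
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=int(score),
        bit_score=bit_score(score, params),
        e_value=estimate_evalue(score, params, len(a), len(b)),
        identity=_identity(x, y, qpos, spos),
        query_coverage=1.0,
        subject_coverage=1.0,
        aligned_pairs=_pairs_from_arrays(qpos, spos),
    )


def local_align(
    a: str,
    b: str,
    params: ScoringParams | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentResult:
    """Optimal local (Smith-Waterman) alignment with affine gaps, floored at 0.

    An empty alignment (score 0) is returned when no positive-scoring pair of
    segments exists; coverage is the aligned span over each full length.
    """
    params = params or ScoringParams()
    if not a or not b:
        raise ValueError("empty sequence")
    x = encode(a, f"query {query_id!r}")
    y = encode(b, f"subject {subject_id!r}")
    H, E, F, best, bi, bj = _local_dp(
        x, y, params.matrix, params.gap_open, params.gap_extend
    )
    if best <= 0:
        return AlignmentResult(
            query_id, subject_id, 0, bit_score(0, params),
            estimate_evalue(0, params, len(a), len(b)), 0.0, 0.0, 0.0, [],
        )
    qpos, spos = _local_traceback(
        x, y, params.matrix, params.gap_open, params.gap_extend, H, E, F, bi, bj
    )
    qcols = qpos[qpos >= 0]
    scols = spos[spos >= 0]
    qspan = int(qcols.max() - qcols.min() + 1)
    sspan = int(scols.max() - scols.min() + 1)
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=int(best),
        bit_score=bit_score(best, params),
        e_value=estimate_evalue(best, params, len(a), len(b)),
        identity=_identity(x, y, qpos, spos),
        query_coverage=qspan / len(a),
        subject_coverage=sspan / len(b),
        aligned_pairs=_pairs_from_arrays(qpos, spos),
    )


def mirror_hit(hit: AlignmentResult) -> AlignmentResult:
    """The same alignment viewed with query and subject roles swapped."""
    return AlignmentResult(
        query_id=hit.subject_id,
        subject_id=hit.query_id,
        raw_score=hit.raw_score,
        bit_score=hit.bit_score,
        e_value=hit.e_value,
        identity=hit.identity,
        query_coverage=hit.subject_coverage,
        subject_coverage=hit.query_coverage,
        aligned_pairs=None
        if hit.aligned_pairs is None
        else [(s, q) for q, s in hit.aligned_pairs],
    )


def all_vs_all(
    records,
    params: ScoringParams | None = None,
    keep_pairs: bool = False,
) -> list[AlignmentResult]:
    """All-versus-all local alignment over ``records`` (objects with
    ``.id``/``.residues``), the in-package stand-in for an all-vs-all BLAST.

    With a symmetric matrix the local score is symmetric, so each unordered
    pair is aligned once and reported in both directions (both directed hits
    carry the same score/E-value; coverages are swapped).
    """
    params = params or ScoringParams()
    hits: list[AlignmentResult] = []
    recs = list(records)
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            h = local_align(a.residues, b.residues, params, a.id, b.id)
            if not keep_pairs:
                h.aligned_pairs = None
            hits.append(h)
            hits.append(mirror_hit(h))
    return hits


# --------------------------------------------------------------------------
# Greedy redundancy reduction (CD-HIT-style)
# --------------------------------------------------------------------------


def reduce_redundancy(seqs, identity_threshold: float):
    """Greedy incremental clustering at an identity threshold.

    Sequences are processed longest-first (ties broken by id); each sequence
    joins the first existing representative to which its global-alignment
    identity (identical columns / alignment length, gap columns included) is
    >= the threshold, otherwise it founds a new representative.

    Returns ``(representatives, membership)`` where membership maps every
    input id to its representative's id.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity threshold must be in (0, 1]")
    seqs = list(seqs)
    if not seqs:
        return [], {}
    order = sorted(seqs, key=lambda r: (-len(r.residues), r.id))
    reps = []
    membership: dict[str, str] = {}
    params = ScoringParams()
    for rec in order:
        assigned = False
        for rep in reps:
            res = global_align(rec.residues, rep.residues, params, rec.id, rep.id)
            if res.identity >= identity_threshold:
                membership[rec.id] = rep.id
                assigned = True
                break
        if not assigned:
            reps.append(rec)
            membership[rec.id] = rec.id
    return reps, membership


# --------------------------------------------------------------------------
# Hit table I/O (BLAST outfmt6-style TSV)
# --------------------------------------------------------------------------

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "evalue", "bitscore", "qcovs", "scovs",
]


def write_hits(hits, path) -> None:
    """Write hits as a BLAST outfmt6-style TSV.

    Columns (fixed order): qseqid, sseqid, pident (%, 2 decimals), length
    (alignment columns), evalue (%.6g), bitscore (2 decimals), qcovs and
    scovs (fractions, 4 decimals).
    """
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{100 * h.identity:.2f}\t"
                f"{h.n_columns}\t{h.e_value:.6g}\t{h.bit_score:.2f}\t"
                f"{h.query_coverage:.4f}\t{h.subject_coverage:.4f}\n"
            )


def read_hits(path) -> list[AlignmentResult]:
    """Read a TSV written by :func:`write_hits` (aligned pairs are not stored)."""
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != HIT_COLUMNS:
            raise ValueError(f"unexpected hit-table header: {header}")
        for line in fh:
            q, s, pid, length, ev, bits, qc, sc = line.rstrip("\n").split("\t")
            hits.append(
                AlignmentResult(
                    query_id=q,
                    subject_id=s,
                    raw_score=0,
                    bit_score=float(bits),
                    e_value=float(ev),
                    identity=float(pid) / 100.0,
                    query_coverage=float(qc),
                    subject_coverage=float(sc),
                    aligned_pairs=None,
                )
            )
    return hits
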