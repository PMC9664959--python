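"""Profile hidden Markov models of the family, built from star MSAs.

A simplified profile HMM in the HMMER tradition: match/insert/delete states
over the columns of a reference-anchored alignment, glocal scoring semantics
(every match state must be traversed, via M or D; unaligned sequence flanks
are absorbed by free insert states at the ends), background-mixture
pseudocounts, and bit scores in log2-odds against a background residue model.
Insert states emit the background distribution, so inserts cost only their
transitions.

The family-definition workflow mirrors the way the PYP model was built:
align members to the reference, drop redundancy at 80% identity, build,
search, fold new hits back into the training set, and repeat to convergence;
then attach noise/gathering/trusted bit-score cutoffs derived from Cys69
conservation - the trusted cutoff (TC) is the lowest-scoring functional
training member, the noise cutoff (NC) is the highest-scoring non-functional
sequence seen, and the gathering cutoff (GA) sits midway between them.

State topology per match index k: M_k -> {M_{k+1}, I_k, D_{k+1}},
I_k -> {M_{k+1}, I_k}, D_k -> {M_{k+1}, D_{k+1}}; begin acts as M_0 and end
follows M_L/I_L/D_L. There are no I<->D transitions; observed-path counts of
such steps (possible in arbitrary MSAs) are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .align import AA, AA_INDEX, BACKGROUND, ScoringParams, reduce_redundancy
from .refmap import StarMSA, call_residues, map_to_reference, star_msa
from .synthdata import SequenceRecord

_LOG2 = math.log(2.0)
_NEG = -1.0e30


@dataclass
class ProfileHMM:
    n_match: int
    emissions_match: np.ndarray  # (L, 20)
    emissions_insert: np.ndarray  # (L+1, 20); defaults to background
    background: np.ndarray  # (20,)
    # transition probability arrays, each length L+1 (index semantics in
    # module docstring; entries that correspond to no legal transition are 0)
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    cutoffs: dict | None = None  # {"GA": bits, "TC": bits, "NC": bits}

    def validate(self, tol: float = 1e-12) -> None:
        L = self.n_match
        if not np.allclose(self.emissions_match.sum(axis=1), 1.0, atol=tol):
            raise AssertionError("match emissions do not sum to 1")
        if not np.allclose(self.emissions_insert.sum(axis=1), 1.0, atol=tol):
            raise AssertionError("insert emissions do not sum to 1")
        for k in range(L + 1):
            out = self.t_mm[k] + self.t_mi[k] + (self.t_md[k] if k < L else 0.0)
            if abs(out - 1.0) > tol:
                raise AssertionError(f"M/B state {k} transitions sum to {out}")
            out = self.t_im[k] + self.t_ii[k]
            if abs(out - 1.0) > tol:
                raise AssertionError(f"I state {k} transitions sum to {out}")
        for k in range(1, L + 1):
            out = self.t_dm[k] + (self.t_dd[k] if k < L else 0.0)
            if abs(out - 1.0) > tol:
                raise AssertionError(f"D state {k} transitions sum to {out}")
        if self.cutoffs is not None:
            ga, tc, nc = (self.cutoffs[k] for k in ("GA", "TC", "NC"))
            if not nc <= ga <= tc:
                raise AssertionError(f"cutoff ordering violated: NC={nc} GA={ga} TC={tc}")


@dataclass
class HmmHit:
    sequence_id: str
    bit_score: float
    passes: frozenset  # subset of {"GA", "TC", "NC"}


# --------------------------------------------------------------------------
# Model construction
# --------------------------------------------------------------------------


def build_hmm(
    msa: StarMSA,
    match_occupancy: float = 0.5,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Build a profile HMM from an alignment.

    Columns whose non-gap occupancy is >= ``match_occupancy`` become match
    states. Match emissions are (counts + pseudocount_weight * background)
    normalized; transitions are counted from each row's observed state path
    and smoothed by adding ``pseudocount_weight`` to every legal option.
    """
    rows = msa.rows
    if not rows:
        raise ValueError("empty MSA")
    bg = BACKGROUND if background is None else np.asarray(background, float)
    n_rows = len(rows)
    width = len(rows[0])
    occupancy = np.array(
        [sum(r[c] != "-" for r in rows) / n_rows for c in range(width)]
    )
    match_cols = [c for c in range(width) if occupancy[c] >= match_occupancy]
    L = len(match_cols)
    if L == 0:
        raise ValueError("no alignment column reaches match occupancy")
    is_match = {c: k + 1 for k, c in enumerate(match_cols)}

    em_counts = np.zeros((L, 20))
    w = float(pseudocount_weight)
    c_mm = np.zeros(L + 1)
    c_mi = np.zeros(L + 1)
    c_md = np.zeros(L + 1)
    c_im = np.zeros(L + 1)
    c_ii = np.zeros(L + 1)
    c_dm = np.zeros(L + 1)
    c_dd = np.zeros(L + 1)

    for r in rows:
        state, k = "M", 0  # begin behaves like M_0
        for c in range(width):
            ch = r[c]
            mk = is_match.get(c)
            if mk is not None:
                if ch != "-":
                    em_counts[mk - 1, AA_INDEX[ch]] += 1
                    nxt = ("M", mk)
                else:
                    nxt = ("D", mk)
            else:
                if ch == "-":
                    continue
                nxt = ("I", k)
            ps, pk = state, k
            ns, nk = nxt
            if ps == "M" and ns == "M":
                c_mm[pk] += 1
            elif ps == "M" and ns == "I":
                c_mi[pk] += 1
            elif ps == "M" and ns == "D":
                c_md[pk] += 1
            elif ps == "I" and ns == "M":
                c_im[pk] += 1
            elif ps == "I" and ns == "I":
                c_ii[pk] += 1
            elif ps == "D" and ns == "M":
                c_dm[pk] += 1
            elif ps == "D" and ns == "D":
                c_dd[pk] += 1
            # I->D and D->I have no edge in the topology: dropped
            state, k = ns, nk
        # final transition to end
        if state == "M":
            c_mm[k] += 1
        elif state == "I":
            c_im[k] += 1
        else:
            c_dm[k] += 1

    em = em_counts + w * bg
    em /= em.sum(axis=1, keepdims=True)

    def _norm(counts_opts):
        total = sum(c for c, _allowed in counts_opts if _allowed)
        n_allowed = sum(1 for _c, allowed in counts_opts if allowed)
        total += w * n_allowed
        if total <= 0:
            return [1.0 / n_allowed if allowed else 0.0 for _c, allowed in counts_opts]
        return [(c + w) / total if allowed else 0.0 for c, allowed in counts_opts]

    t_mm = np.zeros(L + 1)
    t_mi = np.zeros(L + 1)
    t_md = np.zeros(L + 1)
    t_im = np.zeros(L + 1)
    t_ii = np.zeros(L + 1)
    t_dm = np.zeros(L + 1)
    t_dd = np.zeros(L + 1)
    for k in range(L + 1):
        md_allowed = k < L
        t_mm[k], t_mi[k], t_md[k] = _norm(
            [(c_mm[k], True), (c_mi[k], True), (c_md[k], md_allowed)]
        )
        t_im[k], t_ii[k] = _norm([(c_im[k], True), (c_ii[k], True)])
        if k >= 1:
            dd_allowed = k < L
            t_dm[k], t_dd[k] = _norm([(c_dm[k], True), (c_dd[k], dd_allowed)])

    ins = np.tile(bg, (L + 1, 1))
    return ProfileHMM(
        n_match=L,
        emissions_match=em,
        emissions_insert=ins,
        background=bg.copy(),
        t_mm=t_mm, t_mi=t_mi, t_md=t_md,
        t_im=t_im, t_ii=t_ii, t_dm=t_dm, t_dd=t_dd,
    )


# --------------------------------------------------------------------------
# Scoring kernels
# --------------------------------------------------------------------------


@njit(cache=True)
def _lse2(a, b):
    if a < b:
        a, b = b, a
    if a <= _NEG:
        return _NEG
    return a + np.log2(1.0 + 2.0 ** (b - a))


@njit(cache=True)
def _forward_kernel(x, lem, lMM, lMI, lMD, lIM, lII, lDM, lDD):
    L = lem.shape[0] - 1
    n = x.shape[0]
    vM = np.full(L + 1, _NEG)
    vI = np.full(L + 1, _NEG)
    vD = np.full(L + 1, _NEG)
    vM[0] = 0.0
    if L >= 1:
        vD[1] = lMD[0]
        for k in range(2, L + 1):
            vD[k] = vD[k - 1] + lDD[k - 1]
    for i in range(1, n + 1):
        a = x[i - 1]
        nM = np.full(L + 1, _NEG)
        nI = np.full(L + 1, _NEG)
        nD = np.full(L + 1, _NEG)
        for k in range(1, L + 1):
            acc = _lse2(vM[k - 1] + lMM[k - 1], vI[k - 1] + lIM[k - 1])
            if k >= 2:
                acc = _lse2(acc, vD[k - 1] + lDM[k - 1])
            nM[k] = acc + lem[k, a]
        for k in range(0, L + 1):
            nI[k] = _lse2(vM[k] + lMI[k], vI[k] + lII[k])
        # D_1 at i>=1 would need B after an emission: impossible. D_k for
        # k>=2 comes from M_{k-1} or D_{k-1} at the same position i.
        for k in range(2, L + 1):
            nD[k] = _lse2(nM[k - 1] + lMD[k - 1], nD[k - 1] + lDD[k - 1])
        vM, vI, vD = nM, nI, nD
    res = _lse2(vM[L] + lMM[L], vI[L] + lIM[L])
    res = _lse2(res, vD[L] + lDM[L])
    return res


@njit(cache=True)
def _viterbi_kernel(x, lem, lMM, lMI, lMD, lIM, lII, lDM, lDD):
    L = lem.shape[0] - 1
    n = x.shape[0]
    VM = np.full((n + 1, L + 1), _NEG)
    VI = np.full((n + 1, L + 1), _NEG)
    VD = np.full((n + 1, L + 1), _NEG)
    bM = np.zeros((n + 1, L + 1), dtype=np.int8)  # 0=M,1=D,2=I predecessor
    bI = np.zeros((n + 1, L + 1), dtype=np.int8)  # 0=M,2=I
    bD = np.zeros((n + 1, L + 1), dtype=np.int8)  # 0=M,1=D
    VM[0, 0] = 0.0
    if L >= 1:
        VD[0, 1] = lMD[0]
        bD[0, 1] = 0
        for k in range(2, L + 1):
            VD[0, k] = VD[0, k - 1] + lDD[k - 1]
            bD[0, k] = 1
    for i in range(1, n + 1):
        a = x[i - 1]
        for k in range(1, L + 1):
            # predecessor preference M > D > I on ties
            best = VM[i - 1, k - 1] + lMM[k - 1]
            ptr = 0
            cand = VD[i - 1, k - 1] + lDM[k - 1]
            if cand > best:
                best, ptr = cand, 1
            cand = VI[i - 1, k - 1] + lIM[k - 1]
            if cand > best:
                best, ptr = cand, 2
            VM[i, k] = best + lem[k, a]
            bM[i, k] = ptr
        for k in range(0, L + 1):
            best = VM[i - 1, k] + lMI[k]
            ptr = 0
            cand = VI[i - 1, k] + lII[k]
            if cand > best:
                best, ptr = cand, 2
            VI[i, k] = best
            bI[i, k] = ptr
        for k in range(2, L + 1):
            best = VM[i, k - 1] + lMD[k - 1]
            ptr = 0
            cand = VD[i, k - 1] + lDD[k - 1]
            if cand > best:
                best, ptr = cand, 1
            VD[i, k] = best
            bD[i, k] = ptr
    # end transition, preference M > D > I
    best = VM[n, L] + lMM[L]
    end = 0
    cand = VD[n, L] + lDM[L]
    if cand > best:
        best, end = cand, 1
    cand = VI[n, L] + lIM[L]
    if cand > best:
        best, end = cand, 2
    return best, end, bM, bI, bD


def _log_arrays(hmm: ProfileHMM):
    with np.errstate(divide="ignore"):
        lem = np.full((hmm.n_match + 1, 20), _NEG)
        lem[1:] = np.log2(
            np.maximum(hmm.emissions_match, 1e-300) / hmm.background
        )
        lem[1:][hmm.emissions_match <= 0] = _NEG

        def lg(v):
            out = np.full_like(v, _NEG)
            nz = v > 0
            out[nz] = np.log2(v[nz])
            return out

        return (
            lem,
            lg(hmm.t_mm), lg(hmm.t_mi), lg(hmm.t_md),
            lg(hmm.t_im), lg(hmm.t_ii), lg(hmm.t_dm), lg(hmm.t_dd),
        )


def _encode(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int8)
    for i, c in enumerate(seq):
        idx = AA_INDEX.get(c)
        if idx is None:
            raise ValueError(f"illegal residue {c!r} at position {i + 1}")
        out[i] = idx
    return out


def forward(hmm: ProfileHMM, seq: str) -> float:
    """Total-path log2-odds score in bits (always >= the Viterbi score)."""
    if not seq:
        raise ValueError("empty sequence")
    arrays = _log_arrays(hmm)
    return float(_forward_kernel(_encode(seq), *arrays))


def viterbi(hmm: ProfileHMM, seq: str):
    """Best-path log2-odds score in bits plus the state path.

    The path is a list of (state, k) tuples, state in {"M", "I", "D"};
    ties are broken M > D > I.
    """
    if not seq:
        raise ValueError("empty sequence")
    arrays = _log_arrays(hmm)
    score, end, bM, bI, bD = _viterbi_kernel(_encode(seq), *arrays)
    L, n = hmm.n_match, len(seq)
    path = []
    state, k, i = int(end), L, n
    names = {0: "M", 1: "D", 2: "I"}
    while not (state == 0 and k == 0 and i == 0):
        path.append((names[state], k))
        if state == 0:
            state = int(bM[i, k])
            k -= 1
            i -= 1
        elif state == 2:
            state = int(bI[i, k])
            i -= 1
        else:
            state = int(bD[i, k])
            k -= 1
    path.reverse()
    return float(score), path


# --------------------------------------------------------------------------
# Search, cutoffs, iteration
# --------------------------------------------------------------------------


def search(hmm: ProfileHMM, db, cutoff: str | None = None) -> list[HmmHit]:
    """Score every database sequence with the forward algorithm.

    ``cutoff`` selects "GA", "TC", "NC", or ``None`` for no threshold.
    Hits are sorted by bit score (desc), then id (asc).
    """
    if cutoff is not None:
        if hmm.cutoffs is None:
            raise ValueError("model has no cutoffs set")
        if cutoff not in ("GA", "TC", "NC"):
            raise ValueError(f"unknown cutoff {cutoff!r}")
    arrays = _log_arrays(hmm)
    hits = []
    for rec in db:
        score = float(_forward_kernel(_encode(rec.residues), *arrays))
        passes = frozenset(
            name
            for name, thr in (hmm.cutoffs or {}).items()
            if score >= thr
        )
        hits.append(HmmHit(rec.id, score, passes))
    hits.sort(key=lambda h: (-h.bit_score, h.sequence_id))
    if cutoff is None:
        return hits
    return [h for h in hits if cutoff in h.passes]


def set_cutoffs(
    hmm: ProfileHMM,
    scored_db: list[HmmHit],
    calls: dict,
    training_ids=None,
) -> dict:
    """Derive NC/GA/TC bit-score cutoffs from Cys69 conservation.

    ``calls`` maps sequence id -> ResidueCall (or anything with a
    ``functional`` attribute). TC is the minimum score among training-set
    members that are functional; NC the maximum score among scored sequences
    that are not functional (0 bits if there are none); GA the midpoint of
    TC and NC, floored at NC. The dict is stored on the model and returned.
    """
    training = set(training_ids) if training_ids is not None else None
    functional_scores = []
    nonfunctional_scores = []
    for h in scored_db:
        call = calls.get(h.sequence_id)
        is_functional = bool(call is not None and call.functional)
        if is_functional:
            if training is None or h.sequence_id in training:
                functional_scores.append(h.bit_score)
        else:
            nonfunctional_scores.append(h.bit_score)
    if not functional_scores:
        raise ValueError("no functional (Cys69) training sequence was scored")
    tc = min(functional_scores)
    nc = max(nonfunctional_scores) if nonfunctional_scores else 0.0
    ga = max(nc, (tc + nc) / 2.0)
    if ga > tc:  # scores overlap so badly the midpoint exceeds TC
        ga = tc
    hmm.cutoffs = {"GA": ga, "TC": tc, "NC": nc}
    return hmm.cutoffs


@dataclass
class IterationResult:
    hmm: ProfileHMM
    rounds: list[set]  # hit-id set after each round
    training_ids: set
    converged: bool
    oscillating: bool


def iterate_build(
    seed_seqs,
    db,
    reference: SequenceRecord,
    params: ScoringParams | None = None,
    max_rounds: int = 5,
    redundancy_identity: float = 0.8,
    match_occupancy: float = 0.5,
    pseudocount_weight: float = 1.0,
) -> IterationResult:
    """Iterative family-model building.

    Each round: reduce the training set's redundancy at 80% identity, build a
    star MSA against the reference, build the HMM, score the database, set
    Cys69-based cutoffs, and take the GA hits as the next training set
    (unioned with the current one). Stops when the hit set repeats (converged
    if it equals the previous round's, flagged oscillating if it matches an
    earlier one) or after ``max_rounds``.
    """
    seed_seqs = list(seed_seqs)
    if not seed_seqs:
        raise ValueError("empty seed set")
    params = params or ScoringParams()
    db = list(db)
    by_id = {r.id: r for r in db}
    for r in seed_seqs:
        by_id.setdefault(r.id, r)
    refmaps = {r.id: map_to_reference(r, reference, params) for r in by_id.values()}
    calls = {
        rid: call_residues(rm, reference)
        if rm.reliable
        else _nonfunctional_call(rid)
        for rid, rm in refmaps.items()
    }
    training = {r.id for r in seed_seqs}
    history: list[set] = []
    hmm = None
    converged = False
    oscillating = False
    for _round in range(max_rounds):
        train_recs = [by_id[i] for i in sorted(training)]
        reps, _membership = reduce_redundancy(train_recs, redundancy_identity)
        msa = star_msa(reps, reference, params, refmaps)
        hmm = build_hmm(msa, match_occupancy, pseudocount_weight)
        scored = search(hmm, db)
        cut = set_cutoffs(hmm, scored, calls, training_ids=training)
        hit_ids = {h.sequence_id for h in scored if h.bit_score >= cut["GA"]}
        if history and hit_ids == history[-1]:
            converged = True
            history.append(hit_ids)
            break
        if hit_ids in history:
            oscillating = True
            history.append(hit_ids)
            break
        history.append(hit_ids)
        training |= hit_ids
    return IterationResult(
        hmm=hmm,
        rounds=history,
        training_ids=training,
        converged=converged,
        oscillating=oscillating,
    )


def _nonfunctional_call(seq_id: str):
    from .refmap import ResidueCall

    return ResidueCall(
        sequence_id=seq_id, residues_at={}, substitution_labels=[], functional=False
    )


# --------------------------------------------------------------------------
# Serialization (plain text, 6-decimal fixed point, exact rewrite round-trip)
# --------------------------------------------------------------------------

_FMT = "{:.6f}"


def write_hmm(hmm: ProfileHMM, path) -> None:
    with open(path, "w") as fh:
        fh.write("PYPFAM-HMM\t1\n")
        fh.write(f"n_match\t{hmm.n_match}\n")
        if hmm.cutoffs is None:
            fh.write("cutoffs\tnone\n")
        else:
            fh.write(
                "cutoffs\tGA\t{}\tTC\t{}\tNC\t{}\n".format(
                    *(_FMT.format(hmm.cutoffs[k]) for k in ("GA", "TC", "NC"))
                )
            )
        fh.write("background\t" + "\t".join(_FMT.format(v) for v in hmm.background) + "\n")
        for k in range(hmm.n_match):
            fh.write(
                f"match\t{k + 1}\t"
                + "\t".join(_FMT.format(v) for v in hmm.emissions_match[k])
                + "\n"
            )
        for k in range(hmm.n_match + 1):
            vals = [
                hmm.t_mm[k], hmm.t_mi[k], hmm.t_md[k],
                hmm.t_im[k], hmm.t_ii[k], hmm.t_dm[k], hmm.t_dd[k],
            ]
            fh.write(f"trans\t{k}\t" + "\t".join(_FMT.format(v) for v in vals) + "\n")


def read_hmm(path) -> ProfileHMM:
    with open(path) as fh:
        lines = [ln.rstrip("\n").split("\t") for ln in fh if ln.strip()]
    if lines[0][0] != "PYPFAM-HMM":
        raise ValueError("not a PYPFAM-HMM file")
    L = int(lines[1][1])
    cutoffs = None
    if lines[2][1] != "none":
        cutoffs = {
            lines[2][1]: float(lines[2][2]),
            lines[2][3]: float(lines[2][4]),
            lines[2][5]: float(lines[2][6]),
        }
    background = np.array([float(v) for v in lines[3][1:]])
    em = np.zeros((L, 20))
    t = {name: np.zeros(L + 1) for name in ("mm", "mi", "md", "im", "ii", "dm", "dd")}
    for parts in lines[4:]:
        if parts[0] == "match":
            em[int(parts[1]) - 1] = [float(v) for v in parts[2:]]
        elif parts[0] == "trans":
            k = int(parts[1])
            vals = [float(v) for v in parts[2:]]
            for name, v in zip(("mm", "mi", "md", "im", "ii", "dm", "dd"), vals):
                t[name][k] = v
    return ProfileHMM(
        n_match=L,
        emissions_match=em,
        emissions_insert=np.tile(background, (L + 1, 1)),
        background=background,
        t_mm=t["mm"], t_mi=t["mi"], t_md=t["md"],
        t_im=t["im"], t_ii=t["ii"], t_dm=t["dm"], t_dd=t["dd"],
        cutoffs=cutoffs,
    )


def write_hits_tsv(hits, path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tbit_score\tpasses\n")
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.bit_score:.4f}\t"
                + ",".join(sorted(h.passes))
                + "\n"
            )
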