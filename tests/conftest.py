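"""Shared fixtures and independent oracles used across the test suite.

The oracle implementations here (exhaustive alignment enumeration, profile-HMM
path enumeration) are deliberately naive and independent of the package's
dynamic-programming code paths: they enumerate every alignment / state path
explicitly and score it from the definitions.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from pypfam.align import AA_INDEX, BACKGROUND
from pypfam.synthdata import SynthConfig, reference_record

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config() -> SynthConfig:
    return SynthConfig(seed=7)


@pytest.fixture(scope="session")
def reference(config):
    return reference_record(config)


# --------------------------------------------------------------------------
# Exhaustive alignment oracle
# --------------------------------------------------------------------------


def _alignments(n: int, m: int):
    """Every global alignment of an n- and an m-residue sequence, as a move
    string over D (diagonal), U (up / gap in second), L (left / gap in
    first)."""
    if n == 0 and m == 0:
        yield ""
        return
    if n > 0 and m > 0:
        for rest in _alignments(n - 1, m - 1):
            yield "D" + rest
    if n > 0:
        for rest in _alignments(n - 1, m):
            yield "U" + rest
    if m > 0:
        for rest in _alignments(n, m - 1):
            yield "L" + rest


def _score_moves(moves: str, x: str, y: str, matrix, go: int, ge: int) -> int:
    score = 0
    i = j = 0
    run = None
    for mv in moves:
        if mv == "D":
            score += matrix[AA_INDEX[x[i]], AA_INDEX[y[j]]]
            i += 1
            j += 1
            run = None
        else:
            if mv != run:
                score -= go
                run = mv
            score -= ge
            if mv == "U":
                i += 1
            else:
                j += 1
    return int(score)


def brute_force_global(x: str, y: str, matrix, go: int = 11, ge: int = 1) -> int:
    """Max score over every explicitly enumerated global alignment."""
    return max(
        _score_moves(mv, x, y, matrix, go, ge) for mv in _alignments(len(x), len(y))
    )


def brute_force_local(x: str, y: str, matrix, go: int = 11, ge: int = 1) -> int:
    """Max over all substring pairs of the enumerated global score, floored
    at 0 (the empty alignment)."""
    best = 0
    for i1 in range(len(x)):
        for i2 in range(i1 + 1, len(x) + 1):
            for j1 in range(len(y)):
                for j2 in range(j1 + 1, len(y) + 1):
                    s = brute_force_global(x[i1:i2], y[j1:j2], matrix, go, ge)
                    best = max(best, s)
    return best


# --------------------------------------------------------------------------
# Profile-HMM path-enumeration oracle
# --------------------------------------------------------------------------


def enumerate_hmm_paths(hmm, x) -> tuple[float, float]:
    """(total, best) path probability of emitting exactly ``x`` (encoded
    residue indices), by explicit recursion over the state graph."""
    L, n = hmm.n_match, len(x)
    total = [0.0]
    best = [0.0]

    def rec(state, k, i, p):
        if p == 0.0:
            return
        if state == "M":
            opts = [("M", k + 1, hmm.t_mm[k]), ("I", k, hmm.t_mi[k])]
            if k < L:
                opts.append(("D", k + 1, hmm.t_md[k]))
        elif state == "I":
            opts = [("M", k + 1, hmm.t_im[k]), ("I", k, hmm.t_ii[k])]
        else:
            opts = [("M", k + 1, hmm.t_dm[k])]
            if k < L:
                opts.append(("D", k + 1, hmm.t_dd[k]))
        for ns, nk, t in opts:
            if t <= 0:
                continue
            if ns == "M" and nk == L + 1:  # the end state
                if i == n:
                    total[0] += p * t
                    best[0] = max(best[0], p * t)
                continue
            if ns == "M":
                if i < n:
                    rec("M", nk, i + 1, p * t * hmm.emissions_match[nk - 1, x[i]])
            elif ns == "I":
                if i < n:
                    rec("I", nk, i + 1, p * t * hmm.emissions_insert[nk, x[i]])
            else:
                rec("D", nk, i, p * t)

    rec("M", 0, 0, 1.0)
    return total[0], best[0]


def background_probability(x) -> float:
    return float(np.prod(BACKGROUND[np.asarray(x)]))
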