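"""Exhaustive Smith-Waterman oracle for homology-search equivalence tests.

Independent of the package implementation: full-matrix affine-gap local
alignment over the entire genome (numba-compiled scalar DP), iterated
best-hit-and-mask per strand.  Conventions deliberately mirror the
documented search contract: a gap of length L costs open + (L-1)*extend,
alignments start and end on match columns, identity counts matched
columns over all aligned columns, coverage is the aligned query span
over the query length.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
from numba import njit

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)


@njit(cache=False)
def _sw_full(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = len(q), len(t)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (q[i - 1] == t[j - 1] and q[i - 1] != 4) else mismatch
            prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > prev:
                prev = Y[i - 1, j - 1]
            if prev < 0.0:
                prev = 0.0
            M[i, j] = prev + s
            xo = M[i, j - 1] + gap_open
            xe = X[i, j - 1] + gap_extend
            X[i, j] = xo if xo >= xe else xe
            yo = M[i - 1, j] + gap_open
            ye = Y[i - 1, j] + gap_extend
            Y[i, j] = yo if yo >= ye else ye
            if M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j
    return best, bi, bj, M, X, Y


def _traceback(q, t, M, X, Y, bi, bj, match, mismatch, gap_open):
    i, j, state = bi, bj, "M"
    n_match = n_cols = 0
    eps = 1e-9
    while i > 0 and j > 0:
        if state == "M":
            n_cols += 1
            hit = q[i - 1] == t[j - 1] and q[i - 1] != 4
            if hit:
                n_match += 1
            rest = M[i, j] - (match if hit else mismatch)
            i, j = i - 1, j - 1
            if abs(rest) < eps and not (M[i, j] > eps and abs(rest - M[i, j]) < eps):
                break
            if abs(rest - M[i, j]) < eps:
                state = "M"
            elif abs(rest - X[i, j]) < eps:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            n_cols += 1
            if abs(X[i, j] - (M[i, j - 1] + gap_open)) < eps:
                state = "M"
            j -= 1
        else:
            n_cols += 1
            if abs(Y[i, j] - (M[i - 1, j] + gap_open)) < eps:
                state = "M"
            i -= 1
    return i, j, n_match, n_cols


_RC = str.maketrans("ACGUT", "UGCAA")


def oracle_hits(
    query: str,
    genome: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    min_identity: float = 0.30,
    min_coverage: float = 0.25,
    min_score: float = 25.0,
) -> List[Tuple[int, int, str, float, float, float]]:
    """All accepted hits as (start, end, strand, identity, coverage, score)."""
    query = query.upper().replace("T", "U")
    genome = genome.upper().replace("T", "U")
    out = []
    for strand in ("+", "-"):
        q = query if strand == "+" else query.translate(_RC)[::-1]
        qe_arr = _encode(q)
        target = list(genome)
        while True:
            te_arr = _encode("".join(target))
            best, bi, bj, M, X, Y = _sw_full(
                qe_arr, te_arr, match, mismatch, gap_open, gap_extend
            )
            if best < min_score or best <= 0:
                break
            qs, ts, n_match, n_cols = _traceback(
                qe_arr, te_arr, M, X, Y, bi, bj, match, mismatch, gap_open
            )
            identity = n_match / n_cols if n_cols else 0.0
            coverage = (bi - qs) / len(q)
            if identity >= min_identity and coverage >= min_coverage:
                out.append((ts, bj, strand, identity, coverage, best))
            for kpos in range(ts, bj):
                target[kpos] = "N"
    out.sort()
    return out
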