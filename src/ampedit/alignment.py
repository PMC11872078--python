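"""Banded global pairwise alignment with affine gaps (Gotoh algorithm).

This is the single alignment engine shared by the genomic read classifier
and the cDNA isoform classifier.  Alignments are *global*: both sequences
are consumed end to end, so a read either pays for every difference to a
candidate reference or wins outright — the property the category calls
rely on.

Gap convention: a gap of length k costs ``gap_open + (k - 1) * gap_extend``
(the opening base pays ``gap_open``, each additional base ``gap_extend``).

The band is centred on the main diagonal and automatically widened by the
length difference of the two sequences, so net indels of any size (e.g.
a 350-bp deletion read) stay inside the band; ``band_margin`` only has to
absorb diagonal drift from scattered point errors.  With a margin at
least as large as both sequences the computation is the exact full DP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

NEG = np.int64(-(2**40))

# alignment column operation codes
OP_MATCH = 0
OP_MISMATCH = 1
OP_DEL = 2  # reference base aligned to a gap (deletion in the read)
OP_INS = 3  # read base aligned to a gap (insertion relative to reference)

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i  # lowercase

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class Scoring:
    """Match/mismatch/affine-gap scheme for global alignment.

    Defaults separate single-SNP differences from gap artifacts on reads
    with ~1%/nt error.
    """

    match: int = 2
    mismatch: int = -4
    gap_open: int = -4
    gap_extend: int = -2
    band_margin: int = 30

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.band_margin < 1:
            raise ValueError("band_margin must be >= 1")


@njit(cache=True)
def _gotoh_score(a, b, match, mismatch, go, ge, margin):  # pragma: no cover - jitted
    n = a.size
    m = b.size
    lo = min(0, m - n) - margin
    hi = max(0, m - n) + margin
    W = hi - lo + 1

    M = np.full(W, NEG, np.int64)
    X = np.full(W, NEG, np.int64)
    Y = np.full(W, NEG, np.int64)
    # row i = 0
    for j in range(max(0, lo), min(m, hi) + 1):
        k = j - lo
        if j == 0:
            M[k] = 0
        else:
            Y[k] = go + (j - 1) * ge
    Mp = np.empty(W, np.int64)
    Xp = np.empty(W, np.int64)
    Yp = np.empty(W, np.int64)
    for i in range(1, n + 1):
        for k in range(W):
            Mp[k] = M[k]
            Xp[k] = X[k]
            Yp[k] = Y[k]
            M[k] = NEG
            X[k] = NEG
            Y[k] = NEG
        jlo = max(0, i + lo)
        jhi = min(m, i + hi)
        for j in range(jlo, jhi + 1):
            k = j - i - lo
            # X: a[i-1] aligned to gap; from (i-1, j) -> prev-row band index k+1
            if k + 1 < W:
                best = Mp[k + 1] + go
                v = Xp[k + 1] + ge
                if v > best:
                    best = v
                v = Yp[k + 1] + go
                if v > best:
                    best = v
                if best > NEG // 2:
                    X[k] = best
            if j > 0:
                # M: diagonal from (i-1, j-1) -> prev-row band index k
                best = Mp[k]
                if Xp[k] > best:
                    best = Xp[k]
                if Yp[k] > best:
                    best = Yp[k]
                if best > NEG // 2:
                    s = match if a[i - 1] == b[j - 1] else mismatch
                    M[k] = best + s
                # Y: b[j-1] aligned to gap; from (i, j-1) -> band index k-1
                if k - 1 >= 0:
                    best = M[k - 1] + go
                    v = Y[k - 1] + ge
                    if v > best:
                        best = v
                    v = X[k - 1] + go
                    if v > best:
                        best = v
                    if best > NEG // 2:
                        Y[k] = best
    k = m - n - lo
    best = M[k]
    if X[k] > best:
        best = X[k]
    if Y[k] > best:
        best = Y[k]
    return best


@njit(cache=True)
def _gotoh_align(a, b, match, mismatch, go, ge, margin):  # pragma: no cover - jitted
    n = a.size
    m = b.size
    lo = min(0, m - n) - margin
    hi = max(0, m - n) + margin
    W = hi - lo + 1

    M = np.full((n + 1, W), NEG, np.int64)
    X = np.full((n + 1, W), NEG, np.int64)
    Y = np.full((n + 1, W), NEG, np.int64)
    pM = np.zeros((n + 1, W), np.uint8)
    pX = np.zeros((n + 1, W), np.uint8)
    pY = np.zeros((n + 1, W), np.uint8)

    for j in range(max(0, lo), min(m, hi) + 1):
        k = j - lo
        if j == 0:
            M[0, k] = 0
        else:
            Y[0, k] = go + (j - 1) * ge
            pY[0, k] = 2  # chain of Y
    for i in range(1, n + 1):
        jlo = max(0, i + lo)
        jhi = min(m, i + hi)
        for j in range(jlo, jhi + 1):
            k = j - i - lo
            if k + 1 < W:
                best = M[i - 1, k + 1] + go
                src = 0
                v = X[i - 1, k + 1] + ge
                if v > best:
                    best = v
                    src = 1
                v = Y[i - 1, k + 1] + go
                if v > best:
                    best = v
                    src = 2
                if best > NEG // 2:
                    X[i, k] = best
                    pX[i, k] = src
            if j > 0:
                best = M[i - 1, k]
                src = 0
                if X[i - 1, k] > best:
                    best = X[i - 1, k]
                    src = 1
                if Y[i - 1, k] > best:
                    best = Y[i - 1, k]
                    src = 2
                if best > NEG // 2:
                    s = match if a[i - 1] == b[j - 1] else mismatch
                    M[i, k] = best + s
                    pM[i, k] = src
                if k - 1 >= 0:
                    best = M[i, k - 1] + go
                    src = 0
                    v = Y[i, k - 1] + ge
                    if v > best:
                        best = v
                        src = 2
                    v = X[i, k - 1] + go
                    if v > best:
                        best = v
                        src = 1
                    if best > NEG // 2:
                        Y[i, k] = best
                        pY[i, k] = src

    k = m - n - lo
    score = M[n, k]
    state = 0
    if X[n, k] > score:
        score = X[n, k]
        state = 1
    if Y[n, k] > score:
        score = Y[n, k]
        state = 2

    ops = np.empty(n + m, np.uint8)
    p = n + m
    i = n
    j = m
    while i > 0 or j > 0:
        k = j - i - lo
        p -= 1
        if state == 0:
            ops[p] = OP_MATCH if a[i - 1] == b[j - 1] else OP_MISMATCH
            state = pM[i, k]
            i -= 1
            j -= 1
        elif state == 1:
            ops[p] = OP_DEL
            state = pX[i, k]
            i -= 1
        else:
            ops[p] = OP_INS
            state = pY[i, k]
            j -= 1
    return score, ops[p:]


def align_global(ref, query, scoring: Scoring = Scoring(), traceback: bool = False):
    """Globally align ``query`` against ``ref``.

    Parameters accept either strings or pre-encoded uint8 arrays.  Returns
    ``score`` or ``(score, ops)`` where ``ops`` is a uint8 array of
    per-column operation codes (OP_MATCH/OP_MISMATCH/OP_DEL/OP_INS) in
    reference order.
    """
    a = encode(ref) if isinstance(ref, str) else ref
    b = encode(query) if isinstance(query, str) else query
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot align empty sequences")
    args = (
        a,
        b,
        np.int64(scoring.match),
        np.int64(scoring.mismatch),
        np.int64(scoring.gap_open),
        np.int64(scoring.gap_extend),
        int(scoring.band_margin),
    )
    if traceback:
        score, ops = _gotoh_align(*args)
        return int(score), ops
    return int(_gotoh_score(*args))


def ops_to_indels(ops: np.ndarray):
    """Extract indels from an operation list.

    Returns ``(insertions, deletions)`` where insertions are
    ``(ref_interbase_pos, length)`` and deletions ``(ref_start, length)``
    with coordinates on the reference frame (0-based; inter-base position
    ``k`` sits between reference bases ``k-1`` and ``k``).
    """
    insertions = []
    deletions = []
    ref_pos = 0
    i = 0
    L = len(ops)
    while i < L:
        op = ops[i]
        j = i
        while j < L and ops[j] == op:
            j += 1
        run = j - i
        if op == OP_INS:
            insertions.append((ref_pos, run))
        elif op == OP_DEL:
            deletions.append((ref_pos, run))
            ref_pos += run
        else:
            ref_pos += run
        i = j
    return insertions, deletions


def ops_to_ref2query(ops: np.ndarray, ref_len: int) -> np.ndarray:
    """Map each reference position to the query position aligned to it.

    Reference positions aligned to a gap map to -1.
    """
    out = np.full(ref_len, -1, dtype=np.int64)
    ref_pos = 0
    q_pos = 0
    for op in ops:
        if op == OP_DEL:
            ref_pos += 1
        elif op == OP_INS:
            q_pos += 1
        else:
            out[ref_pos] = q_pos
            ref_pos += 1
            q_pos += 1
    return out
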