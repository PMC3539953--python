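"""Dynamic-programming alignment kernels (numba-jitted).

Sequences are encoded as uint8 codes over the 15-letter IUPAC alphabet;
scoring uses a dense 15x15 float matrix (NUC44 by default).  Both global
(Needleman-Wunsch) and local (Smith-Waterman) alignment with a linear gap
penalty are provided, each with an optional diagonal band for near-diagonal
alignments.  Traceback tie order is diagonal > up > left, where "up"
consumes a base of the first sequence.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: index order of the encoded alphabet
ALPHABET = "ACGTRYSWKMBDHVN"

_BASES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_ENCODE = np.full(256, 14, dtype=np.uint8)  # unknowns behave like N
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i
_ENCODE[ord("U")] = ALPHABET.index("T")


def encode(seq: str) -> np.ndarray:
    """Encode an IUPAC nucleotide string into alphabet indices."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def nuc44_matrix(match: float = 5.0, mismatch: float = -4.0) -> np.ndarray:
    """NUC44-style matrix: canonical match/mismatch, ambiguity cells averaged.

    The score of two (possibly ambiguous) codes is the mean of the
    canonical match/mismatch scores over all base pairs the codes denote.
    """
    m = np.zeros((15, 15), dtype=np.float64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            scores = [match if x == y else mismatch
                      for x in _BASES[a] for y in _BASES[b]]
            m[i, j] = float(np.mean(scores))
    return m


NUC44 = nuc44_matrix()

# traceback codes
_STOP, _DIAG, _UP, _LEFT = 0, 1, 2, 3


@njit(cache=True)
def _nw_kernel(a, b, S, gap, band):  # pragma: no cover - exercised via wrapper
    n, m = a.shape[0], b.shape[0]
    NEG = -1e30
    H = np.full((n + 1, m + 1), NEG)
    ptr = np.zeros((n + 1, m + 1), np.uint8)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        if band >= 0 and j > band:
            break
        H[0, j] = -gap * j
        ptr[0, j] = _LEFT
    for i in range(1, n + 1):
        if band < 0 or i <= band:
            H[i, 0] = -gap * i
            ptr[i, 0] = _UP
        jlo, jhi = 1, m
        if band >= 0:
            jlo = max(1, i - band)
            jhi = min(m, i + band)
        for j in range(jlo, jhi + 1):
            best = H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]
            p = _DIAG
            up = H[i - 1, j] - gap
            if up > best:
                best = up
                p = _UP
            left = H[i, j - 1] - gap
            if left > best:
                best = left
                p = _LEFT
            H[i, j] = best
            ptr[i, j] = p
    return H[n, m], ptr


@njit(cache=True)
def _sw_kernel(a, b, S, gap, band, diag):  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        jlo, jhi = 1, m
        if band >= 0:
            jlo = max(1, i + diag - band)
            jhi = min(m, i + diag + band)
        for j in range(jlo, jhi + 1):
            h = H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]
            p = _DIAG
            up = H[i - 1, j] - gap
            if up > h:
                h = up
                p = _UP
            left = H[i, j - 1] - gap
            if left > h:
                h = left
                p = _LEFT
            if h <= 0.0:
                h = 0.0
                p = _STOP
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptr


@njit(cache=True)
def _traceback(ptr, i, j, local):  # pragma: no cover
    """Walk pointers back; returns arrays of per-column (ai, bj) indices.

    Gap columns carry -1 on the side that does not consume a base.
    """
    maxlen = i + j
    ai = np.empty(maxlen, np.int64)
    bj = np.empty(maxlen, np.int64)
    k = 0
    while i > 0 or j > 0:
        p = ptr[i, j]
        if local and p == _STOP:
            break
        if p == _DIAG:
            i -= 1
            j -= 1
            ai[k] = i
            bj[k] = j
        elif p == _UP:
            i -= 1
            ai[k] = i
            bj[k] = -1
        elif p == _LEFT:
            j -= 1
            ai[k] = -1
            bj[k] = j
        else:
            break
        k += 1
    return ai[:k][::-1].copy(), bj[:k][::-1].copy()


def nw_pairs(a: np.ndarray, b: np.ndarray, S: np.ndarray, gap: float,
             band: int | None = None) -> tuple[float, np.ndarray, np.ndarray]:
    """Global alignment; returns (score, a_cols, b_cols).

    ``band`` restricts |i - j| <= band (must be >= |len(a) - len(b)| to
    reach the corner); None means exact full DP.
    """
    if band is not None and band < abs(len(a) - len(b)):
        raise ValueError("band narrower than the length difference")
    score, ptr = _nw_kernel(a, b, S, float(gap), -1 if band is None else int(band))
    ai, bj = _traceback(ptr, len(a), len(b), False)
    return float(score), ai, bj


def sw_pairs(a: np.ndarray, b: np.ndarray, S: np.ndarray, gap: float,
             band: int | None = None, diag: int = 0
             ) -> tuple[float, np.ndarray, np.ndarray]:
    """Local alignment; returns (score, a_cols, b_cols); empty arrays if score 0.

    With a band, cells satisfy |j - i - diag| <= band; ``diag`` is the
    expected offset of b relative to a (e.g. from a k-mer seed).
    """
    score, bi, bj_, ptr = _sw_kernel(
        a, b, S, float(gap), -1 if band is None else int(band),
        int(diag),
    )
    if score <= 0.0:
        return 0.0, np.empty(0, np.int64), np.empty(0, np.int64)
    ai, bj = _traceback(ptr, bi, bj_, True)
    return float(score), ai, bj
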