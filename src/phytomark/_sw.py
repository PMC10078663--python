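"""Numba dynamic-programming kernels for pairwise alignment.

All scores are integers for nucleotide kernels and floats for the generic
matrix kernels. Conventions, fixed so that results are bit-reproducible and
can be mirrored by an independent plain-Python oracle:

* A gap of length ``k`` costs ``|gap_open| + k * |gap_extend|`` (the first gap
  column pays open + extend). ``gap_open`` / ``gap_extend`` are passed as
  negative score increments.
* Local alignment (Smith-Waterman): the optimal cell is the maximal ``H``
  cell; ties are broken by the smallest read index, then the smallest
  reference index. Traceback preference at an ``H`` cell: diagonal, then gap
  in the read (consuming reference), then gap in the reference (consuming
  read). Affine-state ties prefer closing the gap over extending it.
* Nucleotides are coded A=0 C=1 G=2 T=3 N=4; N never matches anything
  (including another N).

The glocal ("query-global, reference-ends-free") kernel is shared by the
redundancy-clustering identity computation, the rRNA miTag classifier
(with unit costs) and the amino-acid profile aligner (with position-specific
scores).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)

# traceback op codes emitted by the glocal kernel
OP_MATCH = 0  # consume query char and one column
OP_DEL = 1  # consume one column, gap in query
OP_INS = 2  # consume query char, not represented in columns


@njit(cache=True)
def sw_score(read: np.ndarray, ref: np.ndarray, match: int, mismatch: int, gap_open: int, gap_extend: int) -> int:
    """Best local alignment score (score only; clamped at 0)."""
    m = read.shape[0]
    n = ref.shape[0]
    H = np.zeros(n + 1, np.int32)
    E = np.full(n + 1, NEG, np.int32)
    best = 0
    for i in range(1, m + 1):
        diag = 0
        F = NEG
        Hleft = 0
        ri = read[i - 1]
        for j in range(1, n + 1):
            E[j] = max(E[j] + gap_extend, H[j] + gap_open + gap_extend)
            F = max(F + gap_extend, Hleft + gap_open + gap_extend)
            s = match if (ri == ref[j - 1] and ri < 4) else mismatch
            h = diag + s
            if E[j] > h:
                h = E[j]
            if F > h:
                h = F
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            Hleft = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def sw_traceback(read, ref, match, mismatch, gap_open, gap_extend):
    """Full Smith-Waterman with traceback under the canonical conventions.

    Returns (score, read_start, read_end, ref_start, ref_end, matches,
    columns); coordinates are 0-based half-open; ``columns`` counts all
    alignment columns including gap columns. Score 0 means "no alignment".
    """
    m = read.shape[0]
    n = ref.shape[0]
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), NEG, np.int32)
    F = np.full((m + 1, n + 1), NEG, np.int32)
    go = gap_open + gap_extend
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        ri = read[i - 1]
        for j in range(1, n + 1):
            e = max(E[i, j - 1] + gap_extend, H[i, j - 1] + go)
            f = max(F[i - 1, j] + gap_extend, H[i - 1, j] + go)
            s = match if (ri == ref[j - 1] and ri < 4) else mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0
    # traceback
    i = bi
    j = bj
    matches = 0
    columns = 0
    state = 0  # 0 = H, 1 = E (gap in read), 2 = F (gap in ref)
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            ri = read[i - 1]
            s = match if (ri == ref[j - 1] and ri < 4) else mismatch
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
                columns += 1
                if ri == ref[j - 1] and ri < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            if E[i, j] == H[i, j - 1] + go:
                state = 0
            j -= 1
        else:
            columns += 1
            if F[i, j] == H[i - 1, j] + go:
                state = 0
            i -= 1
    return best, i, bi, j, bj, matches, columns


@njit(cache=True)
def glocal_matrix(S, gap_open, gap_extend):
    """Query-global, reference-ends-free alignment over a score matrix.

    ``S[i, j]`` is the score of placing query position ``i`` in reference
    column ``j``. Leading and trailing reference columns are free; every
    query position must be consumed (interior gaps and query insertions pay
    affine costs). Returns (score, ops, qstart_col) where ``ops`` is the
    traceback path (OP_* codes, leftmost first, excluding free end columns)
    and ``qstart_col`` the 0-based first reference column on the path.

    Tie-breaks: the optimal end column is the smallest; traceback prefers
    match, then deletion (gap in query), then insertion; affine ties prefer
    closing the gap.
    """
    m, n = S.shape
    go = gap_open + gap_extend
    M = np.full((m + 1, n + 1), -np.inf)
    D = np.full((m + 1, n + 1), -np.inf)
    I = np.full((m + 1, n + 1), -np.inf)
    B = np.full((m + 1, n + 1), -np.inf)
    for j in range(n + 1):
        B[0, j] = 0.0  # free leading columns
    for i in range(1, m + 1):
        if i == 1:
            I[i, 0] = B[0, 0] + go
        else:
            I[i, 0] = I[i - 1, 0] + gap_extend
        B[i, 0] = I[i, 0]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            M[i, j] = B[i - 1, j - 1] + S[i - 1, j - 1]
            D[i, j] = max(D[i, j - 1] + gap_extend, max(M[i, j - 1], I[i, j - 1]) + go)
            ii = max(I[i - 1, j] + gap_extend, max(M[i - 1, j], D[i - 1, j]) + go)
            if i == 1:
                ii = max(ii, B[0, j] + go)
            I[i, j] = ii
            B[i, j] = max(M[i, j], max(D[i, j], I[i, j]))
    # best end: row m, any column (trailing columns free); smallest j wins ties
    best = -np.inf
    bj = 0
    for j in range(n + 1):
        if B[m, j] > best:
            best = B[m, j]
            bj = j
    ops = np.empty(m + n, np.int8)
    nops = 0
    i = m
    j = bj
    # resolve state at the end cell: prefer M, then D, then I
    if B[i, j] == M[i, j]:
        state = 0
    elif B[i, j] == D[i, j]:
        state = 1
    else:
        state = 2
    while i > 0:
        if state == 0:
            ops[nops] = OP_MATCH
            nops += 1
            i -= 1
            j -= 1
            if i == 0:
                break  # boundary: free leading columns
            prev = B[i, j]
            if prev == M[i, j]:
                state = 0
            elif prev == D[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[nops] = OP_DEL
            nops += 1
            val = D[i, j]
            j -= 1
            if val == M[i, j] + go:
                state = 0
            elif val == I[i, j] + go:
                state = 2
            else:
                state = 1
        else:
            ops[nops] = OP_INS
            nops += 1
            val = I[i, j]
            i -= 1
            if i == 0:
                break
            if j > 0 and val == M[i, j] + go:
                state = 0
            elif j > 0 and val == D[i, j] + go:
                state = 1
            else:
                state = 2
    out = ops[:nops][::-1].copy()
    return best, out, j


@njit(cache=True)
def local_matrix_score(S, gap_open, gap_extend):
    """Best local alignment score over a score matrix (score only, >= 0)."""
    m, n = S.shape
    go = gap_open + gap_extend
    H = np.zeros(n + 1)
    E = np.full(n + 1, -np.inf)
    best = 0.0
    for i in range(1, m + 1):
        diag = 0.0
        F = -np.inf
        Hleft = 0.0
        for j in range(1, n + 1):
            E[j] = max(E[j] + gap_extend, H[j] + go)
            F = max(F + gap_extend, Hleft + go)
            h = diag + S[i - 1, j - 1]
            if E[j] > h:
                h = E[j]
            if F > h:
                h = F
            if h < 0.0:
                h = 0.0
            diag = H[j]
            H[j] = h
            Hleft = h
            if h > best:
                best = h
    return best


_CODE = np.full(256, 4, np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("U")] = 3
_CODE[ord("u")] = 3


def encode_nt(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A0 C1 G2 T3, other -> N=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), np.uint8)]


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
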