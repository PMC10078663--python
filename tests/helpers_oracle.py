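"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from scratch in plain Python
(explicit matrices, no numba, no shared helpers with the package) so that
agreement with the implementation is a meaningful check, not a tautology.
"""

from __future__ import annotations

import itertools
import math

NEG = float("-inf")


def sw_oracle(read: str, ref: str, match=1, mismatch=-1, gap_open=-2, gap_extend=-1):
    """Full Smith-Waterman DP with the canonical conventions.

    Gap of length k costs |gap_open| + k * |gap_extend|; N never matches;
    best cell = maximal H, ties to smallest (read index, ref index);
    traceback prefers diagonal, then gap-in-read, then gap-in-ref, closing
    gaps over extending them. Returns (score, read_start, read_end,
    ref_start, ref_end, matches, columns).
    """
    m, n = len(read), len(ref)
    go = gap_open + gap_extend
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + go)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + go)
            s = match if (read[i - 1] == ref[j - 1] and read[i - 1] != "N") else mismatch
            h = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0
    i, j, state = bi, bj, "H"
    matches = columns = 0
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            s = match if (read[i - 1] == ref[j - 1] and read[i - 1] != "N") else mismatch
            if H[i][j] == H[i - 1][j - 1] + s:
                columns += 1
                if read[i - 1] == ref[j - 1] and read[i - 1] != "N":
                    matches += 1
                i -= 1
                j -= 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if E[i][j] == H[i][j - 1] + go:
                state = "H"
            j -= 1
        else:
            columns += 1
            if F[i][j] == H[i - 1][j] + go:
                state = "H"
            i -= 1
    return best, i, bi, j, bj, matches, columns


def revcomp_oracle(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def best_strand_oracle(read: str, ref: str, **scoring):
    """align_read semantics: better strand wins, forward wins ties."""
    fwd = sw_oracle(read, ref, **scoring)
    rev = sw_oracle(revcomp_oracle(read), ref, **scoring)
    if rev[0] > fwd[0]:
        return rev, "-"
    return fwd, "+"


def identity_free_ends_oracle(a: str, b: str) -> float:
    """End-gap-free global identity by exhaustive DP (linear-memory-free).

    The shorter sequence is global, terminal gaps on the longer are free;
    identity = matches / columns of the optimal-score alignment under
    match +1 / mismatch -1, gap open+extend 2+1 per column. Optimal among
    co-optimal paths follows diagonal-first preference.
    """
    if len(a) > len(b):
        a, b = b, a
    m, n = len(a), len(b)
    go, ge = -2, -1
    open_cost = go + ge
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    D = [[NEG] * (n + 1) for _ in range(m + 1)]
    I = [[NEG] * (n + 1) for _ in range(m + 1)]
    B = [[NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        B[0][j] = 0.0
    for i in range(1, m + 1):
        I[i][0] = B[0][0] + open_cost if i == 1 else I[i - 1][0] + ge
        B[i][0] = I[i][0]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = 1 if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else -1
            M[i][j] = B[i - 1][j - 1] + s
            D[i][j] = max(D[i][j - 1] + ge, M[i][j - 1] + open_cost, I[i][j - 1] + open_cost)
            ii = max(I[i - 1][j] + ge, M[i - 1][j] + open_cost, D[i - 1][j] + open_cost)
            if i == 1:
                ii = max(ii, B[0][j] + open_cost)
            I[i][j] = ii
            B[i][j] = max(M[i][j], D[i][j], I[i][j])
    best = max(B[m])
    bj = B[m].index(best)
    # traceback mirroring the implementation's preferences
    i, j = m, bj
    if B[i][j] == M[i][j]:
        state = "M"
    elif B[i][j] == D[i][j]:
        state = "D"
    else:
        state = "I"
    matches = columns = 0
    while i > 0:
        if state == "M":
            columns += 1
            if a[i - 1] == b[j - 1] and a[i - 1] != "N":
                matches += 1
            i -= 1
            j -= 1
            if i == 0:
                break
            if B[i][j] == M[i][j]:
                state = "M"
            elif B[i][j] == D[i][j]:
                state = "D"
            else:
                state = "I"
        elif state == "D":
            columns += 1
            val = D[i][j]
            j -= 1
            if val == M[i][j] + open_cost:
                state = "M"
            elif val == I[i][j] + open_cost:
                state = "I"
            else:
                state = "D"
        else:
            columns += 1
            val = I[i][j]
            i -= 1
            if i == 0:
                break
            if j > 0 and val == M[i][j] + open_cost:
                state = "M"
            elif j > 0 and val == D[i][j] + open_cost:
                state = "D"
            else:
                state = "I"
    return matches / columns if columns else 0.0


def kmer_census_oracle(seq: str, k: int) -> dict[str, int]:
    """All k-mer windows by direct enumeration."""
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        counts[seq[i : i + k]] = counts.get(seq[i : i + k], 0) + 1
    return counts


def interval_union_oracle(intervals, length: int) -> int:
    """Union size by position-wise boolean marking."""
    hit = [False] * length
    for start, end in intervals:
        for p in range(start, end):
            hit[p] = True
    return sum(hit)


def shannon_oracle_highprec(abundances) -> float:
    """Shannon index via the Fraction/Decimal-free mpmath-free route:
    sympy exact rationals evaluated to 50 digits."""
    import sympy

    total = sympy.Integer(0)
    vals = [sympy.Rational(x) for x in abundances]
    total = sum(vals)
    H = sympy.Integer(0)
    for v in vals:
        if v > 0:
            p = v / total
            H -= p * sympy.log(p)
    return float(sympy.N(H, 50))


def spearman_oracle(x, y):
    """(rho, exact two-sided permutation p) by full n! enumeration.

    Average ranks computed by hand; rho as the Pearson correlation of the
    rank vectors.
    """

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for t in range(i, j + 1):
                r[order[t]] = avg
            i = j + 1
        return r

    def pearson(a, b):
        n = len(a)
        ma = sum(a) / n
        mb = sum(b) / n
        num = sum((ai - ma) * (bi - mb) for ai, bi in zip(a, b))
        da = math.sqrt(sum((ai - ma) ** 2 for ai in a))
        db = math.sqrt(sum((bi - mb) ** 2 for bi in b))
        if da == 0 or db == 0:
            return float("nan")
        return num / (da * db)

    rx, ry = ranks(list(x)), ranks(list(y))
    rho = pearson(rx, ry)
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(pearson(rx, list(perm))) >= abs(rho) - 1e-12:
            hits += 1
    return rho, hits / total


def k2p_oracle(p_transitions: float, q_transversions: float) -> float:
    """Kimura two-parameter distance, closed form."""
    return -0.5 * math.log(
        (1 - 2 * p_transitions - q_transversions) * math.sqrt(1 - 2 * q_transversions)
    )


def parse_newick_oracle(newick: str):
    """Minimal independent newick parser -> nested (children, support) tuples.

    Returns a node dict {"support": float|None, "children": [...], "name":
    str|None}. Only what the clade-enumeration oracle needs.
    """
    s = newick.strip().rstrip(";")
    pos = 0

    def read_label():
        nonlocal pos
        label = ""
        while pos < len(s) and s[pos] not in ",():;":
            label += s[pos]
            pos += 1
        if pos < len(s) and s[pos] == ":":  # branch length: consume
            pos += 1
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
        return label

    def parse():
        nonlocal pos
        node = {"support": None, "children": [], "name": None}
        if s[pos] == "(":
            pos += 1
            while True:
                node["children"].append(parse())
                if s[pos] == ",":
                    pos += 1
                else:
                    break
            assert s[pos] == ")"
            pos += 1
            label = read_label()
            if label:
                try:
                    node["support"] = float(label)
                except ValueError:
                    node["name"] = label
        else:
            node["name"] = read_label()
        return node

    return parse()


def classify_oracle(newick: str, groups: dict[str, str], tip: str, threshold: float) -> str:
    """Exhaustive clade enumeration: collect every (support, tip set) clade,
    keep those containing ``tip`` with support > threshold and a single
    group, return the label of the smallest such clade ("unclassified" if
    none). Equivalent to walking rootward because ancestor clades are
    nested."""
    root = parse_newick_oracle(newick)
    clades = []

    def tips_below(node):
        if not node["children"]:
            return [node["name"]]
        out = []
        for child in node["children"]:
            out.extend(tips_below(child))
        clades.append((node["support"], tuple(out)))
        return out

    tips_below(root)
    eligible = [
        (len(tipset), tipset)
        for support, tipset in clades
        if support is not None
        and support > threshold
        and tip in tipset
        and len({groups[t] for t in tipset}) == 1
    ]
    if not eligible:
        return "unclassified"
    _, tipset = min(eligible)
    return groups[tipset[0]]
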