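"""Built-in progressive multiple aligner.

Pairwise and profile-profile global alignment with affine gaps (Gotoh),
merged over a p-distance UPGMA guide tree.  Scores: match +1, mismatch -1,
gap open -4, gap extend -1.  Tie-breaking is deterministic: diagonal is
preferred, then the vertical (gap-in-second) move.  This aligner exists so
the pipeline runs without external binaries; an external aligner, when
configured, takes precedence.
"""

from __future__ import annotations

import numpy as np

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -1.0, -4.0, -1.0

_BASES = "ACGT"
_NEG = -1e30


def _profile_freqs(rows: list[str]) -> np.ndarray:
    """(4, L) base frequencies of an alignment; gaps contribute zero weight."""
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    freqs = np.zeros((4, arr.shape[1]))
    for k, b in enumerate(_BASES):
        freqs[k] = (arr == ord(b)).mean(axis=0)
    return freqs


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Affine-gap global alignment of two alignment profiles (Gotoh)."""
    fa, fb = _profile_freqs(rows_a), _profile_freqs(rows_b)
    la, lb = fa.shape[1], fb.shape[1]
    sub = np.asarray(2.0 * fa.T @ fb - np.outer(fa.sum(0), fb.sum(0)))  # sum-of-pairs +1/-1
    M = np.full((la + 1, lb + 1), _NEG)
    X = np.full((la + 1, lb + 1), _NEG)  # gap in B (vertical)
    Y = np.full((la + 1, lb + 1), _NEG)  # gap in A (horizontal)
    # 0 = diag, 1 = up/X, 2 = left/Y; per-matrix traceback
    tb_m = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    tb_x = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    tb_y = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = GAP_OPEN + GAP_EXTEND * (i - 1)
        tb_x[i, 0] = 1
    for j in range(1, lb + 1):
        Y[0, j] = GAP_OPEN + GAP_EXTEND * (j - 1)
        tb_y[0, j] = 2
    for i in range(1, la + 1):
        s_row = sub[i - 1]
        for j in range(1, lb + 1):
            best_prev = M[i - 1, j - 1]
            tb = 0
            if X[i - 1, j - 1] > best_prev:
                best_prev, tb = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] > best_prev:
                best_prev, tb = Y[i - 1, j - 1], 2
            M[i, j] = best_prev + s_row[j - 1]
            tb_m[i, j] = tb
            xo, xe = M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXTEND
            if xo >= xe:
                X[i, j], tb_x[i, j] = xo, 0
            else:
                X[i, j], tb_x[i, j] = xe, 1
            yo, ye = M[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXTEND
            if yo >= ye:
                Y[i, j], tb_y[i, j] = yo, 0
            else:
                Y[i, j], tb_y[i, j] = ye, 2
    i, j = la, lb
    state = 0
    best = M[i, j]
    if X[i, j] > best:
        best, state = X[i, j], 1
    if Y[i, j] > best:
        best, state = Y[i, j], 2
    path = []
    while i > 0 or j > 0:
        if state == 0:
            prev = tb_m[i, j]
            path.append("D")
            i, j = i - 1, j - 1
            state = prev
        elif state == 1:
            prev = tb_x[i, j]
            path.append("U")
            i -= 1
            state = prev
        else:
            prev = tb_y[i, j]
            path.append("L")
            j -= 1
            state = prev
    path.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ai = bi = 0
    buf_a = [[] for _ in rows_a]
    buf_b = [[] for _ in rows_b]
    for step in path:
        if step in ("D", "U"):
            for k, r in enumerate(rows_a):
                buf_a[k].append(r[ai])
            ai += 1
        else:
            for k in range(len(rows_a)):
                buf_a[k].append("-")
        if step in ("D", "L"):
            for k, r in enumerate(rows_b):
                buf_b[k].append(r[bi])
            bi += 1
        else:
            for k in range(len(rows_b)):
                buf_b[k].append("-")
    out_a = ["".join(b) for b in buf_a]
    out_b = ["".join(b) for b in buf_b]
    return out_a, out_b


def pairwise_align(a: str, b: str) -> tuple[str, str]:
    """Global affine-gap alignment of two sequences at the configured scores."""
    ra, rb = _align_profiles([a], [b])
    return ra[0], rb[0]


def _p_distance(a_aln: str, b_aln: str) -> float:
    pairs = [(x, y) for x, y in zip(a_aln, b_aln) if x != "-" and y != "-"]
    if not pairs:
        return 1.0
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def _upgma_order(dist: np.ndarray) -> list[tuple[int, int]]:
    """UPGMA merge list over leaf indices; cluster k of merge m gets index n+m.
    Ties broken by lowest index pair."""
    n = dist.shape[0]
    active = {i: [i] for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    nxt = n
    while len(active) > 1:
        best = min(d, key=lambda ij: (d[ij], ij))
        i, j = best
        merges.append((i, j))
        members = active[i] + active[j]
        sizes = (len(active[i]), len(active[j]))
        del active[i], active[j]
        for k in list(active):
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            d[(k, nxt) if k < nxt else (nxt, k)] = (
                sizes[0] * dik + sizes[1] * djk) / sum(sizes)
        d.pop((i, j))
        active[nxt] = members
        nxt += 1
    return merges


def progressive_align(seqs: dict[str, str]) -> dict[str, str]:
    """Progressive MSA: pairwise p-distance UPGMA guide tree, then profile
    merges in guide order."""
    names = list(seqs)
    n = len(names)
    if n == 1:
        return dict(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ra, rb = pairwise_align(seqs[names[i]], seqs[names[j]])
            dist[i, j] = dist[j, i] = _p_distance(ra, rb)
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([names[i]], [seqs[names[i]]]) for i in range(n)
    }
    nxt = n
    for i, j in _upgma_order(dist):
        na, rows_a = clusters.pop(i)
        nb, rows_b = clusters.pop(j)
        out_a, out_b = _align_profiles(rows_a, rows_b)
        clusters[nxt] = (na + nb, out_a + out_b)
        nxt += 1
    (_, (final_names, final_rows)), = clusters.items()
    return dict(zip(final_names, final_rows))
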