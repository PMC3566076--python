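"""Banded global alignment with free terminal gaps, for percent identity.

Identity here is matched columns / aligned columns, where aligned columns
run from the first to the last aligned residue pair and terminal overhangs
are neither penalized nor counted.  Scoring is match +1, mismatch 0,
internal gap -1; among score-optimal alignments the one with the most
matches is taken, and among those the one with the most aligned columns,
which makes the reported identity a well-defined, symmetric quantity
independent of traceback order.

The DP is banded (|i - j| <= band) and jit-compiled; callers choose the
band from sequence lengths.  For sequences related by substitutions and
short indels the optimal path stays inside the band and the result equals
the unbanded optimum.
"""
from __future__ import annotations

import numpy as np
from numba import njit

_NEG = -(10 ** 12)


@njit(cache=True)
def _better(s1, m1, c1, s2, m2, c2):
    """Lexicographic (score, matches, columns) comparison, all maximized."""
    if s1 != s2:
        return s1 > s2
    if m1 != m2:
        return m1 > m2
    return c1 > c2


@njit(cache=True)
def _identity_core(a, b, band):  # pragma: no cover - exercised via wrapper
    n = a.shape[0]
    m = b.shape[0]
    w = band
    W = 2 * w + 1
    S = np.full((n + 1, W), _NEG, np.int64)
    M = np.zeros((n + 1, W), np.int64)
    C = np.zeros((n + 1, W), np.int64)

    # Row 0: leading gaps in a are free terminal gaps.
    jmax0 = m if m < w else w
    for j in range(jmax0 + 1):
        S[0, j + w] = 0
    for i in range(1, n + 1):
        klo = w - i
        if klo < 0:
            klo = 0
        khi = m - i + w
        if khi > W - 1:
            khi = W - 1
        for k in range(klo, khi + 1):
            j = i + k - w
            if j == 0:
                # Leading gaps in b are free.
                S[i, k] = 0
                M[i, k] = 0
                C[i, k] = 0
                continue
            bs = _NEG
            bm = 0
            bc = 0
            # Diagonal: consume a[i-1] and b[j-1].
            if S[i - 1, k] > _NEG // 2:
                hit = 1 if a[i - 1] == b[j - 1] else 0
                s = S[i - 1, k] + hit
                mm = M[i - 1, k] + hit
                c = C[i - 1, k] + 1
                if _better(s, mm, c, bs, bm, bc):
                    bs, bm, bc = s, mm, c
            # Up: gap in b (consume a[i-1]).
            if k + 1 < W and S[i - 1, k + 1] > _NEG // 2:
                s = S[i - 1, k + 1] - 1
                mm = M[i - 1, k + 1]
                c = C[i - 1, k + 1] + 1
                if _better(s, mm, c, bs, bm, bc):
                    bs, bm, bc = s, mm, c
            # Left: gap in a (consume b[j-1]).
            if k - 1 >= 0 and S[i, k - 1] > _NEG // 2:
                s = S[i, k - 1] - 1
                mm = M[i, k - 1]
                c = C[i, k - 1] + 1
                if _better(s, mm, c, bs, bm, bc):
                    bs, bm, bc = s, mm, c
            S[i, k] = bs
            M[i, k] = bm
            C[i, k] = bc

    # Trailing gaps are free: best cell over last row and last column.
    bs = _NEG
    bm = 0
    bc = 0
    for k in range(W):
        j = n + k - w
        if 0 <= j <= m and S[n, k] > _NEG // 2:
            if _better(S[n, k], M[n, k], C[n, k], bs, bm, bc):
                bs, bm, bc = S[n, k], M[n, k], C[n, k]
    for i in range(n + 1):
        k = m - i + w
        if 0 <= k < W and S[i, k] > _NEG // 2:
            if _better(S[i, k], M[i, k], C[i, k], bs, bm, bc):
                bs, bm, bc = S[i, k], M[i, k], C[i, k]
    return bm, bc


@njit(cache=True)
def _best_offset_core(a, b, w):
    """Ungapped offset o (b[p] vs a[p+o]) maximizing matches, |o| <= w.

    Ties break toward the smallest |o|, then the negative offset.
    """
    best_o = 0
    best_matches = -1
    for abso in range(w + 1):
        for sign in range(2):
            o = -abso if sign else abso
            if abso == 0 and sign == 1:
                continue
            lo = 0 if o >= 0 else -o
            hi = b.shape[0]
            if a.shape[0] - o < hi:
                hi = a.shape[0] - o
            matches = 0
            for p in range(lo, hi):
                if b[p] == a[p + o]:
                    matches += 1
            if matches > best_matches:
                best_matches = matches
                best_o = o
    return best_o


def identity_counts(a_codes: np.ndarray, b_codes: np.ndarray, band: int) -> tuple[int, int]:
    """(matches, aligned columns) of the optimal banded alignment."""
    m, c = _identity_core(
        np.ascontiguousarray(a_codes), np.ascontiguousarray(b_codes), int(band)
    )
    return int(m), int(c)


def best_offset(a_codes: np.ndarray, b_codes: np.ndarray, band: int) -> int:
    return int(
        _best_offset_core(
            np.ascontiguousarray(a_codes), np.ascontiguousarray(b_codes), int(band)
        )
    )
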