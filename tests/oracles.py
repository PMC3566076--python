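"""Independent brute-force oracles used to check the package's optimized
implementations.  These deliberately share no code with src/emrec beyond
the problem definitions themselves."""
from __future__ import annotations

import numpy as np

NEG = float("-inf")


def identity_oracle(a: str, b: str) -> float:
    """Unbanded free-end-gap alignment identity by full dynamic programming.

    Objective: lexicographically maximize (score, matches, aligned columns)
    with match +1, mismatch 0, internal gap -1, terminal gaps free and
    uncounted.  identity = matches / aligned columns.
    """
    n, m = len(a), len(b)
    prev = [(0, 0, 0)] * (m + 1)  # row 0: leading gaps in a are free
    best = prev[m]
    for i in range(1, n + 1):
        cur = [(0, 0, 0)]  # column 0: leading gaps in b are free
        ai = a[i - 1]
        for j in range(1, m + 1):
            hit = 1 if ai == b[j - 1] else 0
            s, mm, c = prev[j - 1]
            cand = (s + hit, mm + hit, c + 1)
            s, mm, c = prev[j]
            up = (s - 1, mm, c + 1)
            if up > cand:
                cand = up
            s, mm, c = cur[j - 1]
            left = (s - 1, mm, c + 1)
            if left > cand:
                cand = left
            cur.append(cand)
        if cur[m] > best:  # trailing gaps in b free
            best = cur[m]
        prev = cur
    for cell in prev:  # last row: trailing gaps in a free
        if cell > best:
            best = cell
    _s, matches, cols = best
    return matches / cols if cols else 0.0


def greedy_cluster_oracle(seqs: list[tuple[str, str]], threshold: float) -> list[str]:
    """Greedy centroid ids in input order, using the unbanded identity."""
    centroids: list[tuple[str, str]] = []
    for sid, seq in seqs:
        if not any(identity_oracle(seq, cs) >= threshold for _cid, cs in centroids):
            centroids.append((sid, seq))
    return [cid for cid, _ in centroids]


def best_window_oracle(seq: str, probe: str, rightmost: bool = False) -> int:
    """Exhaustive minimal-Hamming window scan."""
    dists = [
        sum(x != y for x, y in zip(seq[s : s + len(probe)], probe))
        for s in range(len(seq) - len(probe) + 1)
    ]
    best = min(dists)
    idx = [s for s, d in enumerate(dists) if d == best]
    return idx[-1] if rightmost else idx[0]


def _phred_eps(q: np.ndarray) -> np.ndarray:
    return np.minimum(10.0 ** (-np.asarray(q, float) / 10.0), 0.25)


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _mate_loglik(read: str, qual: np.ndarray, window: str) -> tuple[int, float]:
    eps = _phred_eps(qual)
    ll = 0.0
    mm = 0
    for rb, wb, e in zip(read, window, eps):
        if rb == wb:
            ll += np.log1p(-e)
        else:
            ll += np.log(e / 3.0)
            mm += 1
    return mm, ll


def exhaustive_map_oracle(
    pair, candidates, max_mismatch_rate=0.06, insert_range=(0.0, np.inf)
):
    """All-positions, both-orientations scan; returns, per candidate id, the
    best (log_likelihood, start1, start2, orientation) placement subject to
    the per-mate mismatch cap and the insert range, ties -> leftmost
    fragment start then forward orientation."""
    L1, L2 = len(pair.seq1), len(pair.seq2)
    cap1 = int(np.floor(max_mismatch_rate * L1))
    cap2 = int(np.floor(max_mismatch_rate * L2))
    lo, hi = insert_range
    results = {}
    for cid, cseq in candidates:
        best = None
        # orientation "forward": mate1 as stored upstream, rc(mate2) downstream
        # orientation "reverse": mate2 as stored upstream, rc(mate1) downstream
        for orient, up_read, up_qual, up_len, dn_read, dn_qual, dn_len in (
            ("forward", pair.seq1, pair.qual1, L1,
             _revcomp(pair.seq2), pair.qual2[::-1], L2),
            ("reverse", pair.seq2, pair.qual2, L2,
             _revcomp(pair.seq1), pair.qual1[::-1], L1),
        ):
            up_cap = cap1 if orient == "forward" else cap2
            dn_cap = cap2 if orient == "forward" else cap1
            for sa in range(len(cseq) - up_len + 1):
                mm_a, ll_a = _mate_loglik(up_read, up_qual, cseq[sa : sa + up_len])
                if mm_a > up_cap:
                    continue
                for sb in range(sa, len(cseq) - dn_len + 1):
                    insert = sb + dn_len - sa
                    if not (lo <= insert <= hi):
                        continue
                    mm_b, ll_b = _mate_loglik(
                        dn_read, dn_qual, cseq[sb : sb + dn_len]
                    )
                    if mm_b > dn_cap:
                        continue
                    if orient == "forward":
                        s1, s2 = sa, sb
                    else:
                        s1, s2 = sb, sa
                    rec = (ll_a + ll_b, -sa, orient == "forward", s1, s2, orient)
                    if best is None or rec[:3] > best[:3]:
                        best = rec
        if best is not None:
            results[cid] = (best[0], best[3], best[4], best[5])
    return results


def rarefy_clip_oracle(counts: np.ndarray, depth: int, clip: int,
                       n_reps: int, rng: np.random.Generator) -> float:
    """Mean observed-OTU count after depth-rarefaction (without replacement)
    and clipping, by direct Monte-Carlo."""
    total = 0
    for _ in range(n_reps):
        draw = rng.multivariate_hypergeometric(counts, depth)
        draw[draw <= clip] = 0
        total += int((draw > 0).sum())
    return total / n_reps
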