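"""Read preparation and quality-aware candidate placement.

Reads are trimmed, optionally subsampled, and placed on candidate sequences
by seed-and-extend: 15-base exact seeds sampled at three offsets per mate,
followed by full gapless verification in both orientations.  Each placement
carries a log-likelihood under the standard Phred-Bernoulli substitution
model: log(1 - eps_b) per matching base and log(eps_b / 3) per mismatching
base, where eps_b is the Phred-implied error probability of the read base
(capped at 0.25 so no base is uninformative-negative).  No indels anywhere:
the reconstruction model is substitution-only, so all placements are
gapless.

Coordinates are 0-based half-open on the candidate's forward strand.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from . import _seqs

SEED_LEN = 15
N_SEED_OFFSETS = 3
DEFAULT_Q_THRESHOLD = 20.0
DEFAULT_MIN_LEN = 60
DEFAULT_MAX_MISMATCH_RATE = 0.06
TRIM_WINDOW = 10
EPS_CAP = 0.25

FORWARD = "forward"
REVERSE = "reverse"


@dataclass
class ReadPair:
    """One paired-end record with per-base Phred qualities."""

    id: str
    seq1: str
    seq2: str
    qual1: np.ndarray
    qual2: np.ndarray
    trimmed: bool = False

    def __post_init__(self) -> None:
        self.qual1 = np.asarray(self.qual1, dtype=np.int16)
        self.qual2 = np.asarray(self.qual2, dtype=np.int16)
        if len(self.seq1) != self.qual1.shape[0] or len(self.seq2) != self.qual2.shape[0]:
            raise ValueError(f"quality/sequence length mismatch in pair {self.id!r}")


@dataclass(frozen=True)
class AlignmentHit:
    """One gapless placement of a read pair on a candidate sequence."""

    pair_id: str
    candidate_id: str
    start1: int
    start2: int
    orientation: str
    mismatch_positions: tuple[int, ...]
    log_likelihood: float


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    """Load mate FASTQ files (Sanger Phred+33) into paired records."""
    pairs = []
    it1 = SeqIO.parse(str(r1_path), "fastq")
    it2 = SeqIO.parse(str(r2_path), "fastq")
    for rec1, rec2 in zip(it1, it2, strict=True):
        pid = rec1.id.removesuffix("/1")
        pairs.append(
            ReadPair(
                pid,
                str(rec1.seq).upper(),
                str(rec2.seq).upper(),
                np.array(rec1.letter_annotations["phred_quality"]),
                np.array(rec2.letter_annotations["phred_quality"]),
            )
        )
    return pairs


def _trim_length(qual: np.ndarray, q_threshold: float, window: int) -> int:
    """Length to keep: 3' bases are dropped from the first position where the
    running mean quality over a ``window``-base window falls below threshold;
    the cut lands on the first sub-threshold base inside that window."""
    n = qual.shape[0]
    if n == 0:
        return 0
    if n < window:
        if qual.mean() >= q_threshold:
            return n
        low = np.flatnonzero(qual < q_threshold)
        return int(low[0]) if low.size else n
    means = np.convolve(qual, np.ones(window) / window, mode="valid")
    bad = np.flatnonzero(means < q_threshold)
    if bad.size == 0:
        return n
    first = int(bad[0])
    inside = np.flatnonzero(qual[first : first + window] < q_threshold)
    return first + int(inside[0]) if inside.size else first


def quality_trim(
    pair: ReadPair,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    window: int = TRIM_WINDOW,
) -> ReadPair | None:
    """Quality-trim both mates from the 3' end; return ``None`` (rejection)
    if either mate falls below ``min_len``."""
    n1 = _trim_length(pair.qual1, q_threshold, window)
    n2 = _trim_length(pair.qual2, q_threshold, window)
    if n1 < min_len or n2 < min_len:
        return None
    if n1 == len(pair.seq1) and n2 == len(pair.seq2):
        return ReadPair(pair.id, pair.seq1, pair.seq2, pair.qual1, pair.qual2,
                        trimmed=True)
    return ReadPair(
        pair.id, pair.seq1[:n1], pair.seq2[:n2], pair.qual1[:n1], pair.qual2[:n2],
        trimmed=True,
    )


def trim_pairs(
    pairs: Iterable[ReadPair],
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
) -> tuple[list[ReadPair], int]:
    """Trim a collection; returns (kept pairs, rejection tally)."""
    kept, rejected = [], 0
    for p in pairs:
        t = quality_trim(p, q_threshold, min_len)
        if t is None:
            rejected += 1
        else:
            kept.append(t)
    return kept, rejected


def subsample_reads(
    pairs: Sequence[ReadPair], n: int, seed: int
) -> list[ReadPair]:
    """Uniform sample of ``n`` distinct pairs without replacement."""
    if n > len(pairs):
        raise ValueError(f"cannot sample {n} pairs from {len(pairs)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=n, replace=False)
    return [pairs[int(i)] for i in idx]


def _phred_eps(qual: np.ndarray) -> np.ndarray:
    return np.minimum(10.0 ** (-qual.astype(np.float64) / 10.0), EPS_CAP)


class PackedReads:
    """Array-of-reads representation used by the mapper and the EM.

    For each mate and each strand representation (as stored / reverse
    complement) it holds base codes, per-base mismatch log-likelihood deltas
    (log(eps/3) - log(1-eps)) and per-base correctness probabilities
    (1 - eps), left-aligned and padded to the longest read.
    """

    def __init__(self, pairs: Sequence[ReadPair]):
        if not pairs:
            raise ValueError("no read pairs supplied")
        self.ids = [p.id for p in pairs]
        self.n = len(pairs)
        self.len1 = np.array([len(p.seq1) for p in pairs], dtype=np.int64)
        self.len2 = np.array([len(p.seq2) for p in pairs], dtype=np.int64)
        lmax = int(max(self.len1.max(), self.len2.max()))
        self.lmax = lmax

        def _pack(seqs, quals, lens):
            codes = np.full((self.n, lmax), 4, dtype=np.uint8)
            eps = np.zeros((self.n, lmax), dtype=np.float64)
            for i, (s, q) in enumerate(zip(seqs, quals)):
                codes[i, : lens[i]] = _seqs.encode(s)
                eps[i, : lens[i]] = _phred_eps(q)
            return codes, eps

        c1, e1 = _pack([p.seq1 for p in pairs], [p.qual1 for p in pairs], self.len1)
        c2, e2 = _pack([p.seq2 for p in pairs], [p.qual2 for p in pairs], self.len2)

        def _rc(codes, eps, lens):
            rcodes = np.full_like(codes, 4)
            reps = np.zeros_like(eps)
            # Reverse only the valid prefix of each row, keeping left alignment.
            idx = lens[:, None] - 1 - np.arange(codes.shape[1])[None, :]
            valid = idx >= 0
            take = np.where(valid, idx, 0)
            rev = np.take_along_axis(codes, take, axis=1)
            rcodes[valid] = np.where(rev[valid] < 4, 3 - rev[valid], 4)
            reps[valid] = np.take_along_axis(eps, take, axis=1)[valid]
            return rcodes, reps

        c1r, e1r = _rc(c1, e1, self.len1)
        c2r, e2r = _rc(c2, e2, self.len2)

        def _delta(eps, lens):
            valid = np.arange(lmax)[None, :] < lens[:, None]
            d = np.zeros_like(eps, dtype=np.float32)
            p = np.zeros_like(eps, dtype=np.float32)
            d[valid] = (np.log(eps[valid] / 3.0) - np.log1p(-eps[valid]))
            p[valid] = 1.0 - eps[valid]
            return d, p

        self.codes = {}
        self.delta = {}
        self.pcorr = {}
        for key, (codes, eps, lens) in {
            ("r1", FORWARD): (c1, e1, self.len1),
            ("r1", REVERSE): (c1r, e1r, self.len1),
            ("r2", FORWARD): (c2, e2, self.len2),
            ("r2", REVERSE): (c2r, e2r, self.len2),
        }.items():
            self.codes[key] = codes
            self.delta[key], self.pcorr[key] = _delta(eps, lens)

        valid1 = np.arange(lmax)[None, :] < self.len1[:, None]
        valid2 = np.arange(lmax)[None, :] < self.len2[:, None]
        self.tot1 = np.where(valid1, np.log1p(-e1), 0.0).sum(axis=1)
        self.tot2 = np.where(valid2, np.log1p(-e2), 0.0).sum(axis=1)

        self._seed_kmers = {}
        self._seed_offsets = {}

    def seed_kmers(self, key) -> tuple[np.ndarray, np.ndarray]:
        """Seed k-mer codes at three per-read offsets (0, middle, end) for one
        (mate, strand) representation; -1 marks unusable seeds."""
        if key in self._seed_kmers:
            return self._seed_kmers[key], self._seed_offsets[key]
        codes = self.codes[key]
        lens = self.len1 if key[0] == "r1" else self.len2
        offsets = np.stack(
            [
                np.zeros(self.n, dtype=np.int64),
                np.maximum((lens - SEED_LEN) // 2, 0),
                np.maximum(lens - SEED_LEN, 0),
            ],
            axis=1,
        )
        kmers = np.full((self.n, N_SEED_OFFSETS), -1, dtype=np.int64)
        pow4 = 4 ** np.arange(SEED_LEN - 1, -1, -1, dtype=np.int64)
        for o in range(N_SEED_OFFSETS):
            cols = offsets[:, o][:, None] + np.arange(SEED_LEN)[None, :]
            ok = (offsets[:, o] + SEED_LEN) <= lens
            sub = np.take_along_axis(codes, np.minimum(cols, self.lmax - 1), axis=1)
            clean = ok & (sub < 4).all(axis=1)
            kmers[clean, o] = sub[clean].astype(np.int64) @ pow4
        self._seed_kmers[key] = kmers
        self._seed_offsets[key] = offsets
        return kmers, offsets


class CandidateIndex:
    """Exact 15-mer index over a candidate sequence set."""

    def __init__(self, candidates: Sequence[tuple[str, str]]):
        self.ids = [cid for cid, _ in candidates]
        self.codes = [_seqs.encode(seq) for _, seq in candidates]
        self.lengths = np.array([c.shape[0] for c in self.codes], dtype=np.int64)
        index: dict[int, list[tuple[int, int]]] = {}
        for ci, codes in enumerate(self.codes):
            if codes.shape[0] < SEED_LEN:
                continue
            k = 0
            mask = 4 ** (SEED_LEN - 1)
            valid_run = 0
            for pos in range(codes.shape[0]):
                c = int(codes[pos])
                if c >= 4:
                    valid_run = 0
                    k = 0
                    continue
                k = (k % mask) * 4 + c
                valid_run += 1
                if valid_run >= SEED_LEN:
                    index.setdefault(k, []).append((ci, pos - SEED_LEN + 1))
        self.index = {k: np.array(v, dtype=np.int64) for k, v in index.items()}


@dataclass
class HitTable:
    """Flat arrays of verified pair placements, sorted by (pair, candidate)."""

    pair: np.ndarray      # int64 index into the PackedReads
    cand: np.ndarray      # int64 index into candidate list
    s1: np.ndarray        # mate-1 window start on candidate
    s2: np.ndarray        # mate-2 window start on candidate
    orient: np.ndarray    # 0 = mate1 forward/mate2 revcomp, 1 = the converse
    mm: np.ndarray        # total mismatches across both mates
    ll: np.ndarray        # log-likelihood of the placement
    cand_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.pair.shape[0]

    def take(self, keep: np.ndarray) -> "HitTable":
        return HitTable(
            self.pair[keep], self.cand[keep], self.s1[keep], self.s2[keep],
            self.orient[keep], self.mm[keep], self.ll[keep], self.cand_ids,
        )


def _verify(
    packed: PackedReads, key: tuple[str, str], i: int, cand_codes: np.ndarray, s: int,
    max_mm: int,
) -> tuple[int, float] | None:
    """Gapless verification of one mate placement; (mismatches, loglik) or
    None if out of bounds / above the mismatch cap."""
    L = int((packed.len1 if key[0] == "r1" else packed.len2)[i])
    if s < 0 or s + L > cand_codes.shape[0]:
        return None
    seg = cand_codes[s : s + L]
    row = packed.codes[key][i, :L]
    diff = seg != row
    n_mm = int(diff.sum())
    if n_mm > max_mm:
        return None
    tot = packed.tot1[i] if key[0] == "r1" else packed.tot2[i]
    ll = float(tot + packed.delta[key][i, :L][diff].sum())
    return n_mm, ll


def map_all(
    packed: PackedReads,
    cindex: CandidateIndex,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    insert_range: tuple[float, float] = (0.0, np.inf),
) -> HitTable:
    """Place every pair on every candidate it maps to.

    Both mates must align gaplessly in consistent orientation with per-mate
    mismatches <= max_mismatch_rate * mate length and implied insert inside
    ``insert_range``.  Within one candidate only the best-likelihood
    placement is kept (ties -> leftmost fragment start).
    """
    cap1 = np.floor(max_mismatch_rate * packed.len1).astype(np.int64)
    cap2 = np.floor(max_mismatch_rate * packed.len2).astype(np.int64)
    lo, hi = insert_range

    seed_data = {
        key: packed.seed_kmers(key)
        for key in (("r1", FORWARD), ("r1", REVERSE), ("r2", FORWARD), ("r2", REVERSE))
    }
    index = cindex.index
    ccodes = cindex.codes

    out_pair, out_cand, out_s1, out_s2 = [], [], [], []
    out_orient, out_mm, out_ll = [], [], []

    for i in range(packed.n):
        L1 = int(packed.len1[i])
        L2 = int(packed.len2[i])

        def _mate_placements(key):
            kmers, offsets = seed_data[key]
            found: dict[tuple[int, int], None] = {}
            for o in range(N_SEED_OFFSETS):
                k = int(kmers[i, o])
                if k < 0:
                    continue
                entries = index.get(k)
                if entries is None:
                    continue
                off = int(offsets[i, o])
                for ci, pos in entries:
                    found[(int(ci), int(pos) - off)] = None
            verified: dict[int, list[tuple[int, int, float]]] = {}
            cap = cap1[i] if key[0] == "r1" else cap2[i]
            for ci, s in found:
                res = _verify(packed, key, i, ccodes[ci], s, int(cap))
                if res is not None:
                    verified.setdefault(ci, []).append((s, res[0], res[1]))
            return verified

        best: dict[int, tuple] = {}  # cand -> (ll, frag_start, record)
        for orient, key_a, key_b, b_downstream in (
            (0, ("r1", FORWARD), ("r2", REVERSE), True),
            (1, ("r2", FORWARD), ("r1", REVERSE), True),
        ):
            pa = _mate_placements(key_a)
            if not pa:
                continue
            pb = _mate_placements(key_b)
            La = L1 if key_a[0] == "r1" else L2
            Lb = L1 if key_b[0] == "r1" else L2
            for ci, alist in pa.items():
                blist = pb.get(ci)
                if not blist:
                    continue
                for sa, _mma, lla in alist:
                    for sb, _mmb, llb in blist:
                        if sb < sa:
                            continue
                        insert = sb + Lb - sa
                        if not (lo <= insert <= hi):
                            continue
                        ll = lla + llb
                        if orient == 0:
                            s1, s2 = sa, sb
                        else:
                            s1, s2 = sb, sa
                        frag_start = sa
                        cur = best.get(ci)
                        cand_rec = (ll, -frag_start, -orient, s1, s2, orient,
                                    _mma + _mmb)
                        if cur is None or cand_rec[:3] > cur[:3]:
                            best[ci] = cand_rec
        for ci in sorted(best):
            ll, _nfs, _no, s1, s2, orient, n_mm = best[ci]
            out_pair.append(i)
            out_cand.append(ci)
            out_s1.append(s1)
            out_s2.append(s2)
            out_orient.append(orient)
            out_mm.append(n_mm)
            out_ll.append(ll)

    return HitTable(
        np.array(out_pair, dtype=np.int64),
        np.array(out_cand, dtype=np.int64),
        np.array(out_s1, dtype=np.int64),
        np.array(out_s2, dtype=np.int64),
        np.array(out_orient, dtype=np.uint8),
        np.array(out_mm, dtype=np.int64),
        np.array(out_ll, dtype=np.float64),
        list(cindex.ids),
    )


def _candidate_seq(c) -> tuple[str, str]:
    cid = getattr(c, "id", None)
    seq = getattr(c, "consensus", None) or getattr(c, "sequence", None)
    if cid is None or seq is None:
        cid, seq = c  # (id, sequence) tuple
    return cid, seq


def map_read_pair(
    pair: ReadPair,
    candidates: Sequence,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    insert_range: tuple[float, float] = (0.0, np.inf),
) -> list[AlignmentHit]:
    """Object-level wrapper over :func:`map_all` for a single pair; returns
    one hit per candidate the pair places on (empty list = unmapped)."""
    packed = PackedReads([pair])
    cindex = CandidateIndex([_candidate_seq(c) for c in candidates])
    ht = map_all(packed, cindex, max_mismatch_rate, insert_range)
    hits = []
    for j in range(len(ht)):
        ci = int(ht.cand[j])
        orient = int(ht.orient[j])
        key1 = ("r1", FORWARD if orient == 0 else REVERSE)
        key2 = ("r2", REVERSE if orient == 0 else FORWARD)
        mism: list[int] = []
        for key, s in ((key1, int(ht.s1[j])), (key2, int(ht.s2[j]))):
            L = len(pair.seq1) if key[0] == "r1" else len(pair.seq2)
            seg = cindex.codes[ci][s : s + L]
            diff = np.flatnonzero(seg != packed.codes[key][0, :L])
            mism.extend(int(s + d) for d in diff)
        hits.append(
            AlignmentHit(
                pair.id,
                ht.cand_ids[ci],
                int(ht.s1[j]),
                int(ht.s2[j]),
                FORWARD if orient == 0 else REVERSE,
                tuple(sorted(mism)),
                float(ht.ll[j]),
            )
        )
    return hits


def estimate_insert_size(
    pairs: Sequence[ReadPair],
    references: Sequence,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    min_pairs: int = 100,
) -> tuple[float, float]:
    """Mean and standard deviation of implied insert length over unique-best
    concordant placements from an initial mapping to the reference set."""
    packed = PackedReads(pairs)
    cindex = CandidateIndex([_candidate_seq(r) for r in references])
    ht = map_all(packed, cindex, max_mismatch_rate)
    inserts = _unique_best_inserts(ht, packed)
    if inserts.shape[0] < min_pairs:
        raise ValueError(
            f"only {inserts.shape[0]} unique-best concordant pairs (< {min_pairs}); "
            "specify the insert distribution manually"
        )
    sd = float(inserts.std(ddof=1)) if inserts.shape[0] > 1 else 0.0
    return float(inserts.mean()), sd


def _unique_best_inserts(ht: HitTable, packed: PackedReads) -> np.ndarray:
    if len(ht) == 0:
        return np.empty(0)
    inserts = np.where(
        ht.orient == 0,
        ht.s2 + packed.len2[ht.pair] - ht.s1,
        ht.s1 + packed.len1[ht.pair] - ht.s2,
    )
    order = np.lexsort((ht.cand, ht.pair))
    pair_sorted = ht.pair[order]
    ll_sorted = ht.ll[order]
    boundaries = np.flatnonzero(np.diff(pair_sorted)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [pair_sorted.shape[0]]))
    keep = []
    for s, e in zip(starts, ends):
        grp = ll_sorted[s:e]
        best = grp.argmax()
        if (grp == grp[best]).sum() == 1:
            keep.append(order[s + best])
    return inserts[np.array(keep, dtype=np.int64)] if keep else np.empty(0)


def fragment_intervals(
    ht: HitTable, packed: PackedReads
) -> tuple[np.ndarray, np.ndarray]:
    """(start, end) of the sequenced fragment implied by each hit, 0-based
    half-open on the candidate."""
    e1 = ht.s1 + packed.len1[ht.pair]
    e2 = ht.s2 + packed.len2[ht.pair]
    start = np.minimum(ht.s1, ht.s2)
    end = np.maximum(e1, e2)
    return start, end
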