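"""Iterative expectation-maximization reconstruction of 16S consensus
sequences and relative abundances.

The model is a finite mixture: each mapped read pair i arises from one of J
candidate sequences with mixture weight (relative abundance) pi_j, and
P(pair | candidate) is the gapless Phred-Bernoulli placement likelihood
from :mod:`emrec.mapping`.  The E-step attributes each pair fractionally
across candidates (posterior proportional to pi_j * likelihood); the M-step
re-estimates abundances as mean posterior mass and rebuilds each consensus
base as the argmax of posterior-weighted base counts.  Candidates whose
consensus sequences reach >= 97% identity in any iteration are merged, and
candidates attracting less than a fraction of a read of posterior mass are
pruned so the candidate set can shrink from a database-scale seed.

Abundances are reported as fractions of mapped pairs, from the final
probabilistic accounting of reads.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _align, _seqs
from .mapping import (
    DEFAULT_MAX_MISMATCH_RATE,
    FORWARD,
    REVERSE,
    AlignmentHit,
    CandidateIndex,
    HitTable,
    PackedReads,
    ReadPair,
    estimate_insert_size,
    map_all,
)
from .refdb import ReferenceRecord, _band_width, pairwise_identity

log = logging.getLogger(__name__)

DEFAULT_N_ITERATIONS = 120
DEFAULT_JOIN_THRESHOLD = 0.97
DEFAULT_MIN_ABUNDANCE = 1e-4
DEFAULT_PRUNE_EXPECTED_READS = 0.05


@dataclass
class CandidateModel:
    """An evolving reconstructed sequence: consensus, mixture weight, and
    per-position posterior-weighted base counts (4 x L)."""

    id: str
    consensus: str
    prior_abundance: float = 0.0
    base_weights: np.ndarray | None = None
    expected_reads: float = 0.0

    def weights(self) -> np.ndarray:
        if self.base_weights is None:
            return np.zeros((4, len(self.consensus)))
        return self.base_weights


@dataclass
class ReconstructedSequence:
    id: str
    consensus: str
    abundance: float
    expected_reads: float


@dataclass
class EmirgeResult:
    """Final reconstructions plus per-iteration diagnostics."""

    sequences: list[ReconstructedSequence]
    mapped_fraction: float
    history: pd.DataFrame
    final_hits: HitTable | None = None
    packed: PackedReads | None = None


# ---------------------------------------------------------------------------
# E-step / M-step on explicit hit objects (reference semantics; the run loop
# below uses equivalent vectorized arithmetic on flat arrays).

def e_step(
    hits: Sequence[AlignmentHit], priors: Mapping[str, float]
) -> dict[str, dict[str, float]]:
    """Posterior attribution of each pair across candidates.

    posterior(j | i) = pi_j * exp(ll_ij) / sum_k pi_k * exp(ll_ik), computed
    stably in log space.  Pairs with no hits are simply absent.
    """
    by_pair: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_pair.setdefault(h.pair_id, []).append(h)
    out: dict[str, dict[str, float]] = {}
    for pid, hlist in by_pair.items():
        logw = np.array(
            [np.log(priors[h.candidate_id]) + h.log_likelihood for h in hlist]
        )
        m = logw.max()
        w = np.exp(logw - m)
        z = w.sum()
        assert z > 0, "zero posterior mass for a mapped pair"
        out[pid] = {h.candidate_id: float(x / z) for h, x in zip(hlist, w)}
    return out


def m_step_abundance(
    posteriors: Mapping[str, Mapping[str, float]], n_mapped: int
) -> dict[str, float]:
    """pi'_j = total posterior mass on j / number of mapped pairs."""
    if n_mapped <= 0:
        raise ValueError("no mapped pairs; cannot estimate abundances")
    acc: dict[str, float] = {}
    for post in posteriors.values():
        for cid, p in post.items():
            acc[cid] = acc.get(cid, 0.0) + p
    return {cid: mass / n_mapped for cid, mass in acc.items()}


def m_step_consensus(
    posteriors: Mapping[str, Mapping[str, float]],
    hits: Sequence[AlignmentHit],
    candidate: CandidateModel,
    reads: Mapping[str, ReadPair],
) -> CandidateModel:
    """Rebuild one candidate's base weights and consensus from the reads
    attributed to it.

    weight[b, p] = sum over reads covering p with base b of
    posterior * (1 - eps_base); the consensus base is the argmax per column
    (ties -> current base, then lexicographic) and positions with zero
    coverage keep the prior consensus base.
    """
    L = len(candidate.consensus)
    weights = np.zeros((4, L))
    for h in hits:
        if h.candidate_id != candidate.id:
            continue
        post = posteriors.get(h.pair_id, {}).get(candidate.id, 0.0)
        if post == 0.0:
            continue
        pair = reads[h.pair_id]
        mates = (
            (pair.seq1, pair.qual1, h.start1, h.orientation == REVERSE),
            (pair.seq2, pair.qual2, h.start2, h.orientation == FORWARD),
        )
        for seq, qual, start, rc in mates:
            codes = _seqs.encode(seq)
            eps = np.minimum(10.0 ** (-np.asarray(qual, float) / 10.0), 0.25)
            if rc:
                codes = _seqs.revcomp_codes(codes)
                eps = eps[::-1]
            pos = start + np.arange(codes.shape[0])
            ok = (codes < 4) & (pos >= 0) & (pos < L)
            np.add.at(weights, (codes[ok], pos[ok]), post * (1.0 - eps[ok]))
    consensus = _consensus_from_weights(weights, _seqs.encode(candidate.consensus))
    return replace(candidate, consensus=_seqs.decode(consensus), base_weights=weights)


def _consensus_from_weights(weights: np.ndarray, current: np.ndarray) -> np.ndarray:
    colmax = weights.max(axis=0)
    covered = colmax > 0
    first_max = weights.argmax(axis=0).astype(np.uint8)
    cur_clipped = np.minimum(current, 3)
    cur_is_max = weights[cur_clipped, np.arange(weights.shape[1])] == colmax
    new = np.where(cur_is_max & (current < 4), current, first_max)
    return np.where(covered, new, current).astype(np.uint8)


# ---------------------------------------------------------------------------
# Merging

def merge_candidates(
    candidates: Sequence[CandidateModel],
    join_threshold: float = DEFAULT_JOIN_THRESHOLD,
    _identity_cache: dict | None = None,
) -> list[CandidateModel]:
    """Merge every group of candidates connected by >= join_threshold
    consensus identity (transitive closure within one call).

    The survivor of a group is its highest-abundance member (ties ->
    lexicographic id); it receives the group's summed abundance and the
    positionwise sum of base weights after ungapped offset alignment.
    """
    n = len(candidates)
    if n <= 1:
        return list(candidates)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            a, b = candidates[i].consensus, candidates[j].consensus
            if _identity_cache is not None:
                key = (hash(a), hash(b))
                ident = _identity_cache.get(key)
                if ident is None:
                    ident = pairwise_identity(a, b)
                    _identity_cache[key] = ident
            else:
                ident = pairwise_identity(a, b)
            if ident >= join_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    merged: list[CandidateModel] = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(candidates[members[0]])
            continue
        members = sorted(
            members,
            key=lambda k: (-candidates[k].prior_abundance, candidates[k].id),
        )
        survivor = candidates[members[0]]
        weights = survivor.weights().copy()
        s_codes = _seqs.encode(survivor.consensus)
        total_ab = survivor.prior_abundance
        total_reads = survivor.expected_reads
        for k in members[1:]:
            other = candidates[k]
            total_ab += other.prior_abundance
            total_reads += other.expected_reads
            o_codes = _seqs.encode(other.consensus)
            off = _align.best_offset(
                s_codes, o_codes, _band_width(s_codes.shape[0], o_codes.shape[0])
            )
            ow = other.weights()
            src_lo = max(0, -off)
            src_hi = min(o_codes.shape[0], s_codes.shape[0] - off)
            if src_hi > src_lo:
                weights[:, src_lo + off : src_hi + off] += ow[:, src_lo:src_hi]
        merged.append(
            replace(
                survivor,
                prior_abundance=total_ab,
                expected_reads=total_reads,
                base_weights=weights,
            )
        )
    merged.sort(key=lambda c: c.id)
    return merged


# ---------------------------------------------------------------------------
# Vectorized run loop

def _hit_mate_arrays(ht: HitTable, packed: PackedReads, mate: str):
    """Gathered read codes, per-base mismatch deltas, correctness probs and
    candidate positions for one mate of every hit."""
    if mate == "r1":
        starts = ht.s1
        lens = packed.len1[ht.pair]
        key_f, key_r = ("r1", FORWARD), ("r1", REVERSE)
        rc = ht.orient == 1
        tot = packed.tot1[ht.pair]
    else:
        starts = ht.s2
        lens = packed.len2[ht.pair]
        key_f, key_r = ("r2", FORWARD), ("r2", REVERSE)
        rc = ht.orient == 0
        tot = packed.tot2[ht.pair]
    rows = ht.pair
    codes = np.where(rc[:, None], packed.codes[key_r][rows], packed.codes[key_f][rows])
    delta = np.where(rc[:, None], packed.delta[key_r][rows], packed.delta[key_f][rows])
    pcorr = np.where(rc[:, None], packed.pcorr[key_r][rows], packed.pcorr[key_f][rows])
    valid = np.arange(packed.lmax)[None, :] < lens[:, None]
    pos = starts[:, None] + np.arange(packed.lmax)[None, :]
    return codes, delta, pcorr, pos, valid, tot


class _CandArrays:
    """Concatenated candidate consensus codes with per-candidate offsets."""

    def __init__(self, consensuses: Sequence[str]):
        self.codes_list = [_seqs.encode(s) for s in consensuses]
        self.lengths = np.array([c.shape[0] for c in self.codes_list], dtype=np.int64)
        self.offsets = np.concatenate(([0], np.cumsum(self.lengths)))
        self.flat = (
            np.concatenate(self.codes_list)
            if self.codes_list
            else np.empty(0, dtype=np.uint8)
        )


def _recompute_likelihoods(
    ht: HitTable, packed: PackedReads, cands: _CandArrays, caps1, caps2
):
    """Log-likelihood and mismatch count of every cached placement against
    the current consensus sequences; returns (ll, ok_mask)."""
    ll = np.zeros(len(ht))
    mm_total = np.zeros(len(ht), dtype=np.int64)
    ok = np.ones(len(ht), dtype=bool)
    for mate, caps in (("r1", caps1), ("r2", caps2)):
        codes, delta, _pc, pos, valid, tot = _hit_mate_arrays(ht, packed, mate)
        gpos = cands.offsets[ht.cand][:, None] + pos
        gpos_safe = np.minimum(gpos, max(cands.flat.shape[0] - 1, 0))
        ref = cands.flat[gpos_safe]
        mism = (ref != codes) & valid
        n_mm = mism.sum(axis=1)
        ll += tot + (delta * mism).sum(axis=1)
        mm_total += n_mm
        ok &= n_mm <= caps[ht.pair]
    return ll, mm_total, ok


def _e_step_arrays(ht: HitTable, ll: np.ndarray, log_pi: np.ndarray):
    """Per-hit posteriors and the total data log-likelihood.

    Hits must be sorted by pair; returns (posterior, groups, total_ll) where
    groups are the reduceat start indices of each mapped pair."""
    z = ll + log_pi[ht.cand]
    boundaries = np.flatnonzero(np.diff(ht.pair)) + 1
    starts = np.concatenate(([0], boundaries))
    gmax = np.maximum.reduceat(z, starts)
    counts = np.diff(np.concatenate((starts, [len(ht)])))
    expz = np.exp(z - np.repeat(gmax, counts))
    gsum = np.add.reduceat(expz, starts)
    post = expz / np.repeat(gsum, counts)
    total_ll = float((np.log(gsum) + gmax).sum())
    return post, starts, total_ll


def _m_step_weights(
    ht: HitTable, packed: PackedReads, post: np.ndarray, n_cands: int,
    lengths: np.ndarray,
):
    """Posterior-weighted base counts for every candidate in one pass."""
    w_off = np.concatenate(([0], np.cumsum(4 * lengths)))
    flat = np.zeros(int(w_off[-1]))
    for mate in ("r1", "r2"):
        codes, _d, pcorr, pos, valid, _t = _hit_mate_arrays(ht, packed, mate)
        use = valid & (codes < 4)
        L_c = lengths[ht.cand][:, None]
        use &= (pos >= 0) & (pos < L_c)
        idx = (
            w_off[ht.cand][:, None]
            + codes.astype(np.int64) * L_c
            + pos
        )
        wt = post[:, None] * pcorr
        flat += np.bincount(idx[use], weights=wt[use], minlength=flat.shape[0])
    return [
        flat[w_off[j] : w_off[j + 1]].reshape(4, int(lengths[j]))
        for j in range(n_cands)
    ]


def run_emirge(
    pairs: Sequence[ReadPair],
    reference_db: Sequence[ReferenceRecord],
    n_iterations: int = DEFAULT_N_ITERATIONS,
    join_threshold: float = DEFAULT_JOIN_THRESHOLD,
    min_abundance: float = DEFAULT_MIN_ABUNDANCE,
    *,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    insert_mean: float | None = None,
    insert_sd: float | None = None,
    prune_expected_reads: float = DEFAULT_PRUNE_EXPECTED_READS,
    keep_hits: bool = False,
) -> EmirgeResult:
    """Run the full EM reconstruction.

    Priors start uniform over candidates with at least one mapped pair.
    Each iteration re-evaluates placements against the current consensuses,
    attributes pairs (E), re-estimates abundances and consensuses (M),
    merges candidates that reached ``join_threshold`` identity and prunes
    candidates expecting fewer than ``prune_expected_reads`` reads.  Seed
    placements are recomputed from scratch whenever the candidate set or any
    consensus changed; otherwise the cached placements are reused (gapless
    placements cannot shift under substitution-only consensus updates).

    Returns candidates with final abundance >= ``min_abundance`` sorted by
    decreasing abundance, plus the fraction of input pairs mapping to any
    retained sequence and a per-iteration history.
    """
    if not pairs:
        raise ValueError("no read pairs supplied")
    if not reference_db:
        raise ValueError("empty reference database")
    packed = PackedReads(pairs)
    n_input = packed.n
    caps1 = np.floor(max_mismatch_rate * packed.len1).astype(np.int64)
    caps2 = np.floor(max_mismatch_rate * packed.len2).astype(np.int64)

    if insert_mean is None or insert_sd is None:
        insert_mean, insert_sd = estimate_insert_size(pairs, reference_db)
        log.info("estimated insert size %.1f +/- %.1f", insert_mean, insert_sd)
    # A generous +/- 5 sd window: the placement likelihood already separates
    # candidates, so the window only needs to exclude wildly discordant pairs.
    insert_range = (insert_mean - 5 * insert_sd, insert_mean + 5 * insert_sd)

    models = [CandidateModel(r.id, r.sequence) for r in reference_db]

    def _full_map(models_):
        cindex = CandidateIndex([(m.id, m.consensus) for m in models_])
        ht = map_all(packed, cindex, max_mismatch_rate, insert_range)
        return ht

    ht = _full_map(models)
    if len(ht) == 0:
        raise RuntimeError(
            "no read pair maps to any candidate; check the reference database"
        )
    hit_cands = np.unique(ht.cand)
    keep_map = -np.ones(len(models), dtype=np.int64)
    keep_map[hit_cands] = np.arange(hit_cands.shape[0])
    models = [models[int(i)] for i in hit_cands]
    ht = HitTable(
        ht.pair, keep_map[ht.cand], ht.s1, ht.s2, ht.orient, ht.mm, ht.ll,
        [m.id for m in models],
    )
    pi = np.full(len(models), 1.0 / len(models))
    log.info("initial mapping: %d candidates seeded, %d hits",
             len(models), len(ht))

    identity_cache: dict = {}
    history_rows = []
    need_remap = False

    for it in range(1, n_iterations + 1):
        if need_remap:
            ht = _full_map(models)
            if len(ht) == 0:
                raise RuntimeError("all pairs unmapped after model update")
            need_remap = False

        cands = _CandArrays([m.consensus for m in models])
        ll, _mm, ok = _recompute_likelihoods(ht, packed, cands, caps1, caps2)
        if not ok.all():
            ht = ht.take(ok)
            ll = ll[ok]
        n_mapped = int(np.unique(ht.pair).shape[0])
        post, _starts, total_ll = _e_step_arrays(ht, ll, np.log(pi))

        # M-step: abundances.
        mass = np.bincount(ht.cand, weights=post, minlength=len(models))
        pi = mass / n_mapped
        np.testing.assert_allclose(pi.sum(), 1.0, atol=1e-9)

        # M-step: consensuses.
        weights = _m_step_weights(ht, packed, post, len(models), cands.lengths)
        consensus_changed = False
        new_models = []
        for j, m in enumerate(models):
            cur = _seqs.encode(m.consensus)
            new_codes = _consensus_from_weights(weights[j], cur)
            changed = not np.array_equal(new_codes, cur)
            consensus_changed |= changed
            new_models.append(
                replace(
                    m,
                    consensus=_seqs.decode(new_codes) if changed else m.consensus,
                    base_weights=weights[j],
                    prior_abundance=float(pi[j]),
                    expected_reads=float(mass[j]),
                )
            )
        models = new_models

        # Merge and prune.
        n_before = len(models)
        models = merge_candidates(models, join_threshold, identity_cache)
        merged = len(models) < n_before
        survivors = [m for m in models if m.expected_reads >= prune_expected_reads]
        pruned = len(survivors) < len(models)
        if survivors:
            models = survivors
        pi = np.array([m.prior_abundance for m in models])
        pi = pi / pi.sum()
        for j, m in enumerate(models):
            m.prior_abundance = float(pi[j])

        if merged or pruned or consensus_changed:
            need_remap = True

        history_rows.append(
            {
                "iteration": it,
                "n_candidates": len(models),
                "n_mapped": n_mapped,
                "mapped_fraction": n_mapped / n_input,
                "log_likelihood": total_ll,
                "merged": merged,
                "pruned": pruned,
                "consensus_changed": consensus_changed,
            }
        )
        if it == 1 or it % 10 == 0 or it == n_iterations:
            log.info(
                "iteration %d: %d candidates, %.1f%% mapped, logL=%.1f",
                it, len(models), 100 * n_mapped / n_input, total_ll,
            )

    if need_remap:
        ht = _full_map(models)
        cands = _CandArrays([m.consensus for m in models])
        ll, _mm, ok = _recompute_likelihoods(ht, packed, cands, caps1, caps2)
        ht = ht.take(ok)

    # Final accounting: abundance filter, mapped fraction to retained set.
    order = sorted(
        range(len(models)), key=lambda j: (-models[j].prior_abundance, models[j].id)
    )
    retained = [
        models[j] for j in order if models[j].prior_abundance >= min_abundance
    ]
    retained_idx = {m.id for m in retained}
    keep = np.array([ht.cand_ids[int(c)] in retained_idx for c in ht.cand], bool)
    mapped_to_retained = int(np.unique(ht.pair[keep]).shape[0]) if keep.any() else 0

    sequences = [
        ReconstructedSequence(m.id, m.consensus, m.prior_abundance, m.expected_reads)
        for m in retained
    ]
    result = EmirgeResult(
        sequences,
        mapped_to_retained / n_input,
        pd.DataFrame(history_rows),
    )
    if keep_hits:
        result.final_hits = ht
        result.packed = packed
    return result


def filter_by_abundance(
    results: Sequence[ReconstructedSequence], threshold: float = DEFAULT_MIN_ABUNDANCE
) -> list[ReconstructedSequence]:
    """Keep reconstructions with abundance >= threshold (boundary inclusive);
    retained abundances are NOT renormalized -- they remain shares of the
    full mapped library."""
    return [r for r in results if r.abundance >= threshold]
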