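"""Downstream community-table procedures over reconstructed sequences.

Covers cross-sample OTU construction (greedy 97% centroid clustering in
decreasing-abundance order), the adjusted OTU table of expected read counts,
the replicate high-specificity rule, in-silico V3 hypervariable-region
excision, rarefaction with low-count clipping, and the amplicon end-bias
diagnostics (fragment-start distance histogram, relative coverage curve,
terminal enrichment factor).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _seqs
from .refdb import pairwise_identity

V3_FWD_PRIMER = "CCTACGGGAGGCAGCAG"   # 341F
V3_REV_PRIMER = "ATTACCGCGGCTGCTGG"   # 518R
V3_MIN_LEN = 100
V3_MAX_LEN = 225

DEFAULT_CLIP = 20
DEFAULT_REPLICATES = 10


@dataclass
class OTUTable:
    """OTUs x samples matrix of expected read counts, with representative
    sequences and per-sample mapped-pair totals."""

    counts: pd.DataFrame
    representatives: dict[str, str]
    mapped_totals: dict[str, float]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("OTU table entries must be non-negative")


def pick_otus(
    sequences: Sequence[tuple[str, str, float]],
    identity: float = 0.97,
) -> tuple[dict[str, str], dict[str, str]]:
    """Greedy centroid OTU picking over pooled (id, sequence, abundance)
    records, processed in decreasing-abundance order (ties -> lexicographic
    id).  Returns (assignment of every input id to an OTU id, OTU id ->
    representative sequence); the representative is the centroid.
    """
    order = sorted(sequences, key=lambda t: (-t[2], t[0]))
    centroids: list[tuple[str, str]] = []
    assignment: dict[str, str] = {}
    for sid, seq, _ab in order:
        home = None
        for oid, oseq in centroids:
            if pairwise_identity(seq, oseq) >= identity:
                home = oid
                break
        if home is None:
            centroids.append((sid, seq))
            assignment[sid] = sid
        else:
            assignment[sid] = home
    return assignment, dict(centroids)


def build_adjusted_table(
    sample_results: Mapping[str, Sequence[tuple[str, float]]],
    mapped_totals: Mapping[str, float],
    assignment: Mapping[str, str],
    representatives: Mapping[str, str],
) -> OTUTable:
    """Adjusted OTU table of expected read counts.

    entry(o, s) = mapped_total(s) * sum of abundances of sample-s sequences
    assigned to OTU o.  Every sequence id must have an OTU assignment.
    """
    samples = list(sample_results)
    otus = sorted(set(assignment.values()))
    counts = pd.DataFrame(0.0, index=otus, columns=samples)
    for sample, results in sample_results.items():
        for sid, abundance in results:
            if sid not in assignment:
                raise ValueError(f"sequence {sid!r} has no OTU assignment")
            counts.loc[assignment[sid], sample] += (
                mapped_totals[sample] * abundance
            )
    return OTUTable(counts, dict(representatives), dict(mapped_totals))


def high_specificity_otus(
    presence: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    min_present: int = 12,
    group_size: int = 16,
) -> set[str]:
    """OTUs present in at least ``min_present`` of the ``group_size``
    technical subsamples of one or more biological sample."""
    for sample, cols in groups.items():
        if len(cols) != group_size:
            raise ValueError(
                f"group {sample!r} has {len(cols)} subsamples, expected {group_size}"
            )
    keep: set[str] = set()
    for cols in groups.values():
        tally = presence[list(cols)].astype(bool).sum(axis=1)
        keep.update(tally.index[tally >= min_present])
    return keep


def _hamming_windows(seq_codes: np.ndarray, probe_codes: np.ndarray) -> np.ndarray:
    windows = np.lib.stride_tricks.sliding_window_view(seq_codes, probe_codes.shape[0])
    return (windows != probe_codes).sum(axis=1)


def extract_v3(
    sequence: str,
    fwd: str = V3_FWD_PRIMER,
    rev: str = V3_REV_PRIMER,
    min_len: int = V3_MIN_LEN,
    max_len: int = V3_MAX_LEN,
) -> str | None:
    """Excise the V3 region between the 341F/518R primer sites, inclusive of
    both primer-binding regions.

    Sites are the minimal-Hamming windows with no cap on mismatches (ties ->
    leftmost; the reverse site is searched downstream of the forward site).
    Returns ``None`` (rejection) if no window arrangement exists or the
    region falls outside [min_len, max_len].
    """
    codes = _seqs.encode(sequence.upper())
    f_codes = _seqs.encode(fwd)
    r_codes = _seqs.encode(_seqs.revcomp(rev))
    if codes.shape[0] < f_codes.shape[0] + r_codes.shape[0]:
        return None
    f_start = int(np.argmin(_hamming_windows(codes, f_codes)))
    down = codes[f_start + f_codes.shape[0]:]
    if down.shape[0] < r_codes.shape[0]:
        return None
    r_rel = int(np.argmin(_hamming_windows(down, r_codes)))
    r_start = f_start + f_codes.shape[0] + r_rel
    region = sequence[f_start : r_start + r_codes.shape[0]]
    if not min_len <= len(region) <= max_len:
        return None
    return region


def _largest_remainder_round(col: np.ndarray) -> np.ndarray:
    """Round non-negative reals to integers preserving the (rounded) total."""
    target = int(round(col.sum()))
    floors = np.floor(col).astype(np.int64)
    short = target - int(floors.sum())
    if short <= 0:
        return floors
    frac = col - floors
    order = np.lexsort((np.arange(col.shape[0]), -frac))
    floors[order[:short]] += 1
    return floors


def rarefy_with_clipping(
    table: OTUTable | pd.DataFrame,
    depth: int,
    clip: int = DEFAULT_CLIP,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Rarefy each sample to ``depth`` reads and zero out low counts.

    Expected (fractional) counts are first converted to integers per sample
    by largest-remainder rounding; each replicate then draws ``depth`` reads
    per sample without replacement (multivariate hypergeometric, so a draw
    at full depth returns the sample unchanged) and sets every count <=
    ``clip`` to 0.  Deterministic per seed.
    """
    counts = table.counts if isinstance(table, OTUTable) else table
    mat = counts.to_numpy(dtype=float)
    ints = np.column_stack(
        [_largest_remainder_round(mat[:, j]) for j in range(mat.shape[1])]
    )
    totals = ints.sum(axis=0)
    for j, sample in enumerate(counts.columns):
        if depth > totals[j]:
            raise ValueError(
                f"depth {depth} exceeds total {int(totals[j])} of sample {sample!r}"
            )
    rng = np.random.default_rng(seed)
    out = []
    for _r in range(replicates):
        rep = np.zeros_like(ints)
        for j in range(ints.shape[1]):
            draw = rng.multivariate_hypergeometric(ints[:, j], depth)
            draw[draw <= clip] = 0
            rep[:, j] = draw
        out.append(pd.DataFrame(rep, index=counts.index, columns=counts.columns))
    return out


@dataclass
class BiasProfile:
    """End-bias diagnostics of a mapped library."""

    distance_hist: pd.Series          # fragment fraction per distance-to-end
    per_position_mass: pd.Series      # hist normalized by placements per bin
    coverage_curve: np.ndarray        # mean relative coverage per position bin
    enrichment_factor: float
    n_fragments: int = 0


def end_bias_profile(
    fragments: pd.DataFrame | Iterable[tuple[str, int, int]],
    amplicon_lengths: Mapping[str, int],
    read_len: int | None = None,
    n_bins: int = 100,
) -> BiasProfile:
    """Histogram of fragment start distances to the nearest amplicon end,
    per-position coverage by relative position, and the terminal enrichment
    factor.

    ``fragments`` supplies (reference id, fragment start, fragment end) per
    mapped pair, 0-based half-open.  The distance of a fragment is
    min(start, L - end).  The enrichment factor divides the per-placement
    histogram mass at distance 0 by the mean per-placement mass over
    interior distances, which recovers the generative per-position
    start-weight ratio.  Coverage counts read bases (the first and last
    ``read_len`` bases of each fragment; the whole fragment if None).
    """
    if not isinstance(fragments, pd.DataFrame):
        fragments = pd.DataFrame(fragments, columns=["ref_id", "start", "end"])
    ref_ids = fragments["ref_id"].to_numpy()
    starts = fragments["start"].to_numpy(dtype=np.int64)
    ends = fragments["end"].to_numpy(dtype=np.int64)
    lens = np.array([amplicon_lengths[r] for r in ref_ids], dtype=np.int64)
    if np.any(starts < 0) or np.any(ends > lens):
        raise ValueError("fragment outside amplicon bounds")

    dist = np.minimum(starts, lens - ends)
    hist = np.bincount(dist)
    total = hist.sum()
    distance_hist = pd.Series(hist / total, name="fragment_fraction")
    distance_hist.index.name = "distance_to_nearest_end"

    # Placements available per distance bin: 2 per (fragment length, amplicon)
    # combo except a possible unpaired middle bin.  Estimated per fragment.
    frag_len = ends - starts
    max_d = lens - frag_len  # distance range per fragment is 0..floor(max_d/2)
    half = max_d // 2
    placements = np.zeros(hist.shape[0])
    for d in range(hist.shape[0]):
        two = (half > d) | ((half == d) & (max_d % 2 == 1))
        one = (half == d) & (max_d % 2 == 0)
        placements[d] = (2.0 * two.sum() + 1.0 * one.sum()) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        per_pos = np.where(placements > 0, hist / total / placements, np.nan)
    per_position_mass = pd.Series(per_pos, name="per_position_mass")
    per_position_mass.index.name = "distance_to_nearest_end"

    interior = per_pos[1:]
    interior = interior[np.isfinite(interior) & (interior > 0)]
    if interior.size == 0:
        enrichment = float("inf") if per_pos[0] > 0 else float("nan")
    else:
        enrichment = float(per_pos[0] / interior.mean())

    # Relative-position coverage curve from read bases.
    cov = np.zeros(n_bins)
    for rid in np.unique(ref_ids):
        sel = ref_ids == rid
        L = int(amplicon_lengths[rid])
        depth = np.zeros(L + 1)
        s = starts[sel]
        e = ends[sel]
        if read_len is None:
            np.add.at(depth, s, 1)
            np.add.at(depth, e, -1)
        else:
            rl = min(read_len, int(frag_len[sel].min())) if sel.any() else read_len
            np.add.at(depth, s, 1)
            np.add.at(depth, np.minimum(s + rl, e), -1)
            np.add.at(depth, np.maximum(e - rl, s), 1)
            np.add.at(depth, e, -1)
        depth = np.cumsum(depth[:-1])
        bins = (np.arange(L) * n_bins) // L
        cov += np.bincount(bins, weights=depth, minlength=n_bins) / np.bincount(
            bins, minlength=n_bins
        )
    mean_cov = cov.mean()
    if mean_cov > 0:
        cov = cov / mean_cov

    return BiasProfile(distance_hist, per_position_mass, cov, enrichment, int(total))


def fragments_from_hit_table(ht, packed) -> pd.DataFrame:
    """Adapter: fragment intervals of a mapping, as end_bias_profile input."""
    from .mapping import fragment_intervals

    start, end = fragment_intervals(ht, packed)
    return pd.DataFrame(
        {
            "ref_id": [ht.cand_ids[int(c)] for c in ht.cand],
            "start": start,
            "end": end,
        }
    )
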