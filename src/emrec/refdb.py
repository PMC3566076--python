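"""Candidate reference database preparation.

The EM reconstruction is template-guided: it needs a database of candidate
16S rRNA gene sequences (in practice a length-filtered, 97%-clustered
subset of a curated SSU database).  This module provides the filtering,
ambiguity resolution, percent-identity computation and greedy centroid
clustering used to build that database, plus FASTA I/O.

Coordinates are 0-based half-open throughout.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _align, _seqs

log = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 1200
DEFAULT_MAX_LEN = 1900
DEFAULT_CLUSTER_IDENTITY = 0.97

#: Fraction of the shorter sequence used as the alignment band half-width.
BAND_FRACTION = 0.05
_MIN_BAND = 10


@dataclass(frozen=True)
class ReferenceRecord:
    """One candidate 16S gene sequence used to seed reconstruction."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def load_and_filter_references(
    fasta_path: str | Path,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[ReferenceRecord]:
    """Parse a FASTA file and keep records with min_len <= length <= max_len.

    Input order is preserved and ambiguity codes are left untouched; any
    character outside the IUPAC nucleotide alphabet raises ``ValueError``
    naming the offending record.
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) exceeds max_len ({max_len})")
    kept: list[ReferenceRecord] = []
    total = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        total += 1
        seq = str(rec.seq).upper()
        _seqs.validate_iupac(seq, rec.id)
        if min_len <= len(seq) <= max_len:
            kept.append(ReferenceRecord(rec.id, seq))
    log.info("length filter [%d, %d]: kept %d of %d records", min_len, max_len,
             len(kept), total)
    return kept


def resolve_ambiguities(
    sequence: str,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> str:
    """Replace each IUPAC ambiguity code with a permitted base at random.

    Unambiguous positions are unchanged; the draw is deterministic for a
    fixed seed (or caller-supplied generator, consumed in sequence order).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    for pos, ch in enumerate(sequence.upper()):
        try:
            choices = _seqs.IUPAC_CHOICES[ch]
        except KeyError:
            raise ValueError(
                f"invalid IUPAC character {ch!r} at position {pos}"
            ) from None
        if len(choices) == 1:
            out.append(choices)
        else:
            out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def _band_width(n: int, m: int) -> int:
    return max(int(BAND_FRACTION * min(n, m)), abs(n - m) + 2, _MIN_BAND)


def pairwise_identity(a: str, b: str, band: int | None = None) -> float:
    """Fractional identity of two sequences under banded global alignment
    with free (unpenalized, uncounted) terminal gaps.

    identity = matched columns / aligned columns; symmetric in (a, b).
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires nonempty sequences")
    if band is None:
        band = _band_width(len(a), len(b))
    matches, cols = _align.identity_counts(_seqs.encode(a), _seqs.encode(b), band)
    return matches / cols if cols else 0.0


def cluster_references(
    records: Sequence[ReferenceRecord],
    identity_threshold: float = DEFAULT_CLUSTER_IDENTITY,
    *,
    return_assignments: bool = False,
):
    """Greedy centroid clustering in input order.

    A record becomes a new centroid unless its identity to some existing
    centroid is >= ``identity_threshold``; otherwise it is assigned to the
    first (earliest) such centroid.
    """
    if not records:
        raise ValueError("cluster_references requires at least one record")
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    centroids: list[ReferenceRecord] = []
    assignment: dict[str, str] = {}
    for rec in records:
        home = None
        for cen in centroids:
            if pairwise_identity(rec.sequence, cen.sequence) >= identity_threshold:
                home = cen
                break
        if home is None:
            centroids.append(rec)
            assignment[rec.id] = rec.id
        else:
            assignment[rec.id] = home.id
    log.info("clustering at %.2f identity: %d records -> %d centroids",
             identity_threshold, len(records), len(centroids))
    if return_assignments:
        return centroids, assignment
    return centroids


def write_references(records: Iterable[ReferenceRecord], fasta_path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(fasta_path),
        "fasta",
    )


def build_reference_db(
    fasta_in: str | Path,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    cluster_identity: float = DEFAULT_CLUSTER_IDENTITY,
    seed: int = 0,
) -> list[ReferenceRecord]:
    """Full database preparation: length filter, ambiguity resolution with a
    single seeded RNG consumed in record order, then greedy 97% clustering."""
    records = load_and_filter_references(fasta_in, min_len, max_len)
    if not records:
        return []
    rng = np.random.default_rng(seed)
    resolved = [
        ReferenceRecord(r.id, resolve_ambiguities(r.sequence, rng=rng))
        for r in records
    ]
    return cluster_references(resolved, cluster_identity)
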