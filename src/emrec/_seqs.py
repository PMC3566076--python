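"""Nucleotide encoding helpers shared across the package.

Bases are encoded A=0, C=1, G=2, T=3; anything else (IUPAC ambiguity
codes, N) encodes to 4 and never matches a concrete base.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT?", dtype=np.uint8)

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
for _c in "RYSWKMBDHVNU":
    _ENC[ord(_c)] = 4
    _ENC[ord(_c.lower())] = 4

# IUPAC ambiguity codes and the concrete bases they permit.
IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def encode(seq: str, *, strict: bool = False) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A=0,C=1,G=2,T=3, other=4).

    With ``strict=True`` any character outside {A,C,G,T} raises ``ValueError``
    with its position.
    """
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = _ENC[raw]
    bad = np.flatnonzero(codes == 255)
    if bad.size:
        raise ValueError(
            f"invalid nucleotide character {seq[bad[0]]!r} at position {int(bad[0])}"
        )
    if strict:
        amb = np.flatnonzero(codes == 4)
        if amb.size:
            raise ValueError(
                f"ambiguous base {seq[amb[0]]!r} at position {int(amb[0])}"
            )
    return codes


def decode(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a (possibly ambiguous) nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of an encoded sequence; code 4 stays 4."""
    out = np.where(codes < 4, 3 - codes, codes)
    return out[::-1]


def validate_iupac(seq: str, record_id: str | None = None) -> None:
    """Raise ``ValueError`` naming the record if ``seq`` contains a character
    outside the IUPAC nucleotide alphabet."""
    for pos, ch in enumerate(seq.upper()):
        if ch not in IUPAC_CHOICES:
            where = f" in record {record_id!r}" if record_id else ""
            raise ValueError(
                f"non-IUPAC nucleotide character {ch!r} at position {pos}{where}"
            )
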