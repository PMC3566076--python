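import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from emrec.refdb import ReferenceRecord


def random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Substitute exactly n_subs distinct positions with a different base."""
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[int(rng.integers(3))]
    return "".join(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20130206)


@pytest.fixture
def tiny_refs(rng):
    """Five unrelated ~1.4 kb references with exact primer termini."""
    from emrec.simulate import synthetic_references

    return synthetic_references(5, length=1464, seed=11)


def write_fasta(path: Path, records: list[ReferenceRecord]) -> Path:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.sequence}\n")
    return path
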