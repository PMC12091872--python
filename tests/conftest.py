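import numpy as np
import pytest

from hetenrich.genome_model import ChromSizes
from hetenrich.intervals import IntervalSet


@pytest.fixture
def toy_sizes() -> ChromSizes:
    return ChromSizes({"c1": 10_000, "c2": 8_000})


# ---------------------------------------------------------------------
# Per-base boolean-array oracle: the independent reference for all
# interval arithmetic.  Deliberately naive — O(genome) memory/time.
# ---------------------------------------------------------------------


def mask_from_records(records, sizes) -> dict:
    masks = {c: np.zeros(sizes[c], dtype=bool) for c in sizes}
    for chrom, s, e in records:
        masks[chrom][s:e] = True
    return masks


def mask_from_set(iset: IntervalSet, sizes) -> dict:
    return mask_from_records(iset.records(), sizes)


def mask_bp(masks: dict) -> int:
    return int(sum(m.sum() for m in masks.values()))


def random_records(rng: np.random.Generator, sizes, n: int, max_len: int = 500):
    chroms = list(sizes)
    out = []
    for _ in range(n):
        c = chroms[rng.integers(0, len(chroms))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, sizes[c] - length + 1))
        out.append((c, start, start + length))
    return out
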