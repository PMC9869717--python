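"""Shared fixtures and brute-force reference implementations.

The oracles here are deliberately naive (full DP, exhaustive
enumeration) and independent of the library's code paths; tests freeze
their outputs against the implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

BASES = "ACGT"


def edit_distance(a: str, b: str) -> int:
    """Plain quadratic edit-distance DP."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        ai = a[i - 1]
        for j in range(1, n + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ai != b[j - 1]))
        prev = cur
    return prev[n]


def brute_force_approx_count(query: str, regions: list[str], max_edits: int) -> int:
    """Reference for approximate counting: scan every start position.

    A position matches when some N-free substring starting there is
    within ``max_edits`` edits of the query.
    """
    k = len(query)
    total = 0
    chunks: list[str] = []
    for region in regions:
        chunks.extend(part for part in region.split("N") if part)
    for chunk in chunks:
        for p in range(len(chunk)):
            longest = min(len(chunk) - p, k + max_edits)
            best = min(
                edit_distance(query, chunk[p : p + j]) for j in range(longest + 1)
            )
            if best <= max_edits:
                total += 1
    return total


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, length))


def mutate(seq: str, n_edits: int, rng: np.random.Generator) -> str:
    """Apply a fixed number of random edits to a sequence."""
    seq = list(seq)
    for _ in range(n_edits):
        kind = rng.integers(0, 3)
        pos = int(rng.integers(0, len(seq)))
        if kind == 0:
            seq[pos] = BASES[(BASES.index(seq[pos]) + int(rng.integers(1, 4))) % 4]
        elif kind == 1:
            seq.insert(pos, BASES[int(rng.integers(0, 4))])
        elif len(seq) > 1:
            del seq[pos]
    return "".join(seq)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
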