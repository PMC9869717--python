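"""Approximate k-mer counting over read-extremity regions.

For every k-mer the pipeline needs the number of positions, across all
regions of a sample, where a substring starting at that position aligns
to the k-mer within an edit-distance budget (mismatches, insertions and
deletions). Each (region, start-position) pair is counted at most once,
whatever the distance at which it matches. Substrings containing N are
never counted and k-mers containing N are never enumerated: regions are
split at N into clean stretches before anything is counted.

The candidate universe is the set of k-mers that occur exactly at least
once, so counting costs one approximate query per distinct k-mer rather
than one per possible k-mer. The counting backend is a sorted-array
index over 2-bit-packed windows of length k-1, k and k+1: for an edit
budget of one, a position matches a query if and only if its window of
one of those lengths is the query itself, a single substitution of it,
a single deletion of it, or a single insertion of it, and match sets
from the three window lengths are merged per position so nothing is
double counted. Larger budgets fall back to a per-position scan with
banded edit distance (edlib).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np

from .fastq_io import RegionSample

__all__ = [
    "KmerCountTable",
    "exact_count",
    "approx_count",
    "count_sample",
    "top_kmers",
    "write_count_tsv",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_BASES = "ACGT"


@dataclass
class KmerCountTable:
    """Approximate occurrence counts of k-mers across one region set."""

    k: int
    max_edits: int
    counts: dict[str, int] = field(default_factory=dict)
    n_regions: int = 0

    def __len__(self) -> int:
        return len(self.counts)


def _as_regions(regions: RegionSample | Sequence[str]) -> list[str]:
    if isinstance(regions, RegionSample):
        return regions.regions
    return list(regions)


def _clean_chunks(regions: Iterable[str]) -> list[str]:
    """Split regions at N (or any non-ACGT symbol) into clean stretches."""
    chunks: list[str] = []
    for region in regions:
        if "N" in region:
            chunks.extend(part for part in region.split("N") if part)
        else:
            if region:
                chunks.append(region)
    return chunks


class _WindowIndex:
    """Sorted index of the 2-bit codes of all length-j windows.

    Window codes are collected over every position of every clean
    stretch where j bases remain; positions are global offsets into the
    concatenation of stretches, so indexes for different window lengths
    share a coordinate system and per-position set unions are exact.
    """

    __slots__ = ("j", "sorted_codes", "sorted_pos")

    def __init__(self, arr: np.ndarray, rem: np.ndarray, j: int):
        self.j = j
        n = arr.size - j + 1
        if j < 1 or n <= 0:
            self.sorted_codes = np.empty(0, dtype=np.uint64)
            self.sorted_pos = np.empty(0, dtype=np.int64)
            return
        codes = np.zeros(n, dtype=np.uint64)
        for i in range(j):
            codes = (codes << np.uint64(2)) | arr[i : n + i]
        pos = np.flatnonzero(rem[:n] >= j)
        codes = codes[pos]
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.sorted_pos = pos[order]

    def counts_of(self, codes: np.ndarray) -> np.ndarray:
        lo = np.searchsorted(self.sorted_codes, codes, side="left")
        hi = np.searchsorted(self.sorted_codes, codes, side="right")
        return hi - lo

    def positions_of(self, codes: np.ndarray) -> np.ndarray:
        lo = np.searchsorted(self.sorted_codes, codes, side="left")
        hi = np.searchsorted(self.sorted_codes, codes, side="right")
        keep = hi > lo
        if not keep.any():
            return np.empty(0, dtype=np.int64)
        parts = [self.sorted_pos[l:h] for l, h in zip(lo[keep], hi[keep])]
        return np.concatenate(parts)


class _Corpus:
    """Packed representation of one sample's clean region stretches."""

    def __init__(self, regions: Iterable[str]):
        chunks = _clean_chunks(regions)
        self.max_len = max((len(c) for c in chunks), default=0)
        blob = "".join(chunks).encode("ascii")
        self.arr = _CODE[np.frombuffer(blob, dtype=np.uint8)]
        lens = np.array([len(c) for c in chunks], dtype=np.int64)
        # bases remaining at each position up to the end of its stretch
        if lens.size:
            ends = np.repeat(np.cumsum(lens), lens)
            self.rem = ends - np.arange(self.arr.size, dtype=np.int64)
        else:
            self.rem = np.empty(0, dtype=np.int64)
        self._indexes: dict[int, _WindowIndex] = {}

    def index(self, j: int) -> _WindowIndex:
        if j not in self._indexes:
            self._indexes[j] = _WindowIndex(self.arr, self.rem, j)
        return self._indexes[j]


def _decode(code: int, k: int) -> str:
    return "".join(_BASES[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def _encode(kmer: str) -> int:
    code = 0
    for ch in kmer:
        code = (code << 2) | int(_CODE[ord(ch)])
    return code


def _substitution_codes(qcodes: np.ndarray, k: int) -> np.ndarray:
    """All single-substitution variants, original included, shape (Q, 4k)."""
    out = np.empty((qcodes.size, 4 * k), dtype=np.uint64)
    for i in range(k):
        s = np.uint64(2 * (k - 1 - i))
        cleared = qcodes & ~(np.uint64(3) << s)
        for b in range(4):
            out[:, 4 * i + b] = cleared | (np.uint64(b) << s)
    return out


def _deletion_codes(qcodes: np.ndarray, k: int) -> np.ndarray:
    """All single-deletion variants (length k-1 codes), shape (Q, k)."""
    out = np.empty((qcodes.size, k), dtype=np.uint64)
    for i in range(k):
        s = np.uint64(2 * (k - 1 - i))
        high = (qcodes >> (s + np.uint64(2))) << s
        low = qcodes & ((np.uint64(1) << s) - np.uint64(1))
        out[:, i] = high | low
    return out


def _insertion_codes(qcodes: np.ndarray, k: int) -> np.ndarray:
    """All single-insertion variants (length k+1 codes), shape (Q, 4(k+1))."""
    out = np.empty((qcodes.size, 4 * (k + 1)), dtype=np.uint64)
    for i in range(k + 1):
        s = np.uint64(2 * (k - i))
        high = (qcodes >> s) << (s + np.uint64(2))
        low = qcodes & ((np.uint64(1) << s) - np.uint64(1))
        for b in range(4):
            out[:, 4 * i + b] = high | (np.uint64(b) << s) | low
    return out


def _unique_per_query(variants: np.ndarray, code_bits: int) -> tuple[np.ndarray, np.ndarray]:
    """Deduplicate variant codes within each query row.

    Returns (query_index, code) arrays sorted by query then code.
    """
    q = variants.shape[0]
    qidx = np.repeat(np.arange(q, dtype=np.uint64), variants.shape[1])
    keys = (qidx << np.uint64(code_bits)) | variants.reshape(-1)
    keys = np.unique(keys)
    mask = (np.uint64(1) << np.uint64(code_bits)) - np.uint64(1)
    return (keys >> np.uint64(code_bits)).astype(np.int64), keys & mask


def _bulk_approx_counts(
    corpus: _Corpus, qcodes: np.ndarray, k: int, max_edits: int
) -> np.ndarray:
    """Approximate counts for many queries at edit budget 0 or 1."""
    idx_k = corpus.index(k)
    if max_edits == 0:
        return idx_k.counts_of(qcodes)

    nq = qcodes.size
    code_bits = 2 * (k + 1)
    # substitutions (and the query itself): distinct length-k codes, and
    # each position carries exactly one length-k window, so counts add up
    # without double counting within this class.
    sub_q, sub_codes = _unique_per_query(_substitution_codes(qcodes, k), code_bits)
    ab_counts = np.bincount(
        sub_q, weights=idx_k.counts_of(sub_codes), minlength=nq
    ).astype(np.int64)

    idx_del = corpus.index(k - 1)
    del_q, del_codes = _unique_per_query(_deletion_codes(qcodes, k), code_bits)
    del_counts = np.bincount(
        del_q, weights=idx_del.counts_of(del_codes), minlength=nq
    ).astype(np.int64)

    idx_ins = corpus.index(k + 1)
    ins_q, ins_codes = _unique_per_query(_insertion_codes(qcodes, k), code_bits)
    ins_counts = np.bincount(
        ins_q, weights=idx_ins.counts_of(ins_codes), minlength=nq
    ).astype(np.int64)

    totals = ab_counts.copy()
    # Positions reachable through a deletion or insertion window may also
    # match through the length-k window; merge per-position sets exactly
    # for the (few) queries where those classes are non-empty.
    needs_union = np.flatnonzero((del_counts > 0) | (ins_counts > 0))
    for qi in needs_union:
        # query blocks are contiguous because _unique_per_query sorts by query
        s0, s1 = np.searchsorted(sub_q, [qi, qi + 1])
        seen = idx_k.positions_of(sub_codes[s0:s1])
        extra = 0
        if del_counts[qi]:
            d0, d1 = np.searchsorted(del_q, [qi, qi + 1])
            dpos = idx_del.positions_of(del_codes[d0:d1])
            dnew = np.setdiff1d(dpos, seen)
            extra += dnew.size
            seen = np.concatenate([seen, dnew])
        if ins_counts[qi]:
            i0, i1 = np.searchsorted(ins_q, [qi, qi + 1])
            ipos = idx_ins.positions_of(ins_codes[i0:i1])
            extra += np.setdiff1d(ipos, seen).size
        totals[qi] = ab_counts[qi] + extra
    return totals


def _scan_count(query: str, chunks: Iterable[str], max_edits: int) -> int:
    """Per-position scan: matches are starts p with min_j ed(q, s[p:p+j]) <= d."""
    k = len(query)
    total = 0
    window = k + max_edits
    for chunk in chunks:
        clen = len(chunk)
        for p in range(clen):
            if clen - p < k - max_edits:
                break
            res = edlib.align(query, chunk[p : p + window], mode="SHW", k=max_edits)
            if res["editDistance"] != -1:
                total += 1
    return total


def exact_count(regions: RegionSample | Sequence[str], k: int) -> KmerCountTable:
    """Exact occurrence counts of every k-mer present in the regions."""
    regs = _as_regions(regions)
    if k < 1:
        raise ValueError("k must be >= 1")
    corpus = _Corpus(regs)
    table = KmerCountTable(k=k, max_edits=0, n_regions=len(regs))
    if k > corpus.max_len:
        return table
    idx = corpus.index(k)
    codes, starts = np.unique(idx.sorted_codes, return_index=True)
    counts = np.diff(np.append(starts, idx.sorted_codes.size))
    table.counts = {
        _decode(int(c), k): int(n) for c, n in zip(codes, counts)
    }
    return table


def approx_count(
    query: str, regions: RegionSample | Sequence[str], max_edits: int
) -> int:
    """Number of (region, start-position) pairs matching ``query``.

    A position matches when some N-free substring starting there aligns
    to the query with at most ``max_edits`` edits; it is counted once
    however many alignments or distances realize the match.
    """
    if max_edits < 0:
        raise ValueError("max_edits must be >= 0")
    chunks = _clean_chunks(_as_regions(regions))
    return _scan_count(query, chunks, max_edits)


def count_sample(
    regions: RegionSample | Sequence[str],
    k: int,
    max_edits: int,
    candidate_limit: int | None = None,
) -> KmerCountTable:
    """Approximate counts for the k-mers occurring exactly in the regions.

    With ``candidate_limit`` set, approximate counts are evaluated only
    for that many k-mers pre-ranked by exact count (ties broken
    lexicographically) and the table is restricted to them; frequent
    k-mers rank identically under both orderings, so this bounds work on
    large samples without disturbing downstream k-mer selection.
    """
    regs = _as_regions(regions)
    corpus = _Corpus(regs)
    table = KmerCountTable(k=k, max_edits=max_edits, n_regions=len(regs))
    if k > corpus.max_len:
        return table
    idx = corpus.index(k)
    codes, starts = np.unique(idx.sorted_codes, return_index=True)
    exact = np.diff(np.append(starts, idx.sorted_codes.size))
    if candidate_limit is not None and codes.size > candidate_limit:
        order = np.lexsort((codes, exact.max() - exact))
        keep = np.sort(order[:candidate_limit])
        codes, exact = codes[keep], exact[keep]
    if max_edits == 0:
        table.counts = {_decode(int(c), k): int(n) for c, n in zip(codes, exact)}
        return table
    if max_edits == 1 and k >= 2:
        totals = _bulk_approx_counts(corpus, codes, k, max_edits)
        table.counts = {_decode(int(c), k): int(n) for c, n in zip(codes, totals)}
        return table
    chunks = _clean_chunks(regs)
    table.counts = {
        _decode(int(c), k): _scan_count(_decode(int(c), k), chunks, max_edits)
        for c in codes
    }
    return table


def top_kmers(table: KmerCountTable, limit: int) -> list[tuple[str, int]]:
    """The ``limit`` highest-count k-mers, count descending, ties lexicographic."""
    if limit < 1:
        raise ValueError("limit must be >= 1")
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:limit]


def write_count_tsv(table: KmerCountTable, path) -> None:
    """Dump the table as TSV (kmer, count, rank) in top_kmers order."""
    ranked = top_kmers(table, max(1, len(table.counts))) if table.counts else []
    with open(path, "wt") as out:
        out.write("kmer\tcount\trank\n")
        for rank, (kmer, count) in enumerate(ranked, start=1):
            out.write(f"{kmer}\t{count}\t{rank}\n")
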