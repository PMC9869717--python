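"""Adapter localization and read-end trimming.

Adapters (inferred or user-supplied) are placed inside a window at the
relevant read end with an overlap alignment: end gaps are free on both
sequences, so a partial adapter may overhang the read boundary — the
usual footprint of incompletely sequenced end adapters. Placement is
scored with match/mismatch/gap = +1/-1/-1; identity is then computed
over the aligned columns and a hit is reported when it reaches the
identity threshold and covers a minimum number of adapter bases. The
trimmer removes everything up to the end of a start hit (plus a couple
of extra bases) and everything from the beginning of an end hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align

from .config import TrimConfig
from .consensus import InferenceResult
from .fastq_io import Read, read_fastq, write_fastq

__all__ = [
    "AdapterHit",
    "TrimSummary",
    "locate_adapter",
    "trim_read",
    "trim_dataset",
]


@dataclass
class AdapterHit:
    """Placement of one adapter on one read (half-open read interval)."""

    adapter_id: str
    read_id: str
    end_label: str
    lo: int
    hi: int
    identity: float


@dataclass
class TrimSummary:
    """Counts reported by a trimming run."""

    reads_seen: int = 0
    start_trimmed: int = 0
    end_trimmed: int = 0
    dropped: int = 0
    written: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "reads_seen": self.reads_seen,
            "start_trimmed": self.start_trimmed,
            "end_trimmed": self.end_trimmed,
            "dropped": self.dropped,
            "written": self.written,
        }

    def format_table(self) -> str:
        rows = self.as_dict()
        width = max(len(k) for k in rows)
        return "\n".join(f"{k.ljust(width)}  {v}" for k, v in rows.items())


def _make_overlap_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    # free end gaps on both sequences: overlap alignment
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


_OVERLAP_ALIGNER = _make_overlap_aligner()


def locate_adapter(
    read: Read,
    adapter: str,
    end_label: str,
    search_len: int = 150,
    identity_threshold: float = 0.75,
    min_overlap: int = 18,
    adapter_id: str = "adapter",
) -> AdapterHit | None:
    """Best placement of ``adapter`` in the start or end window of a read.

    Returns the best-scoring overlap-alignment placement if its
    identity over the aligned columns reaches ``identity_threshold``
    and at least ``min_overlap`` adapter bases take part, else None.
    """
    if end_label not in ("start", "end"):
        raise ValueError("end_label must be 'start' or 'end'")
    if not adapter or not read.bases:
        return None
    if end_label == "start":
        window = read.bases[:search_len]
        offset = 0
    else:
        window = read.bases[-search_len:]
        offset = max(0, len(read.bases) - search_len)
    if not window:
        return None

    alignment = _OVERLAP_ALIGNER.align(window, adapter)[0]
    target_blocks, query_blocks = alignment.aligned
    if len(target_blocks) == 0:
        return None
    matches = 0
    aligned_len = 0
    for (t0, t1), (q0, q1) in zip(target_blocks, query_blocks):
        for wc, ac in zip(window[t0:t1], adapter[q0:q1]):
            matches += wc == ac
        aligned_len += t1 - t0
    # internal gap columns between consecutive aligned blocks
    columns = aligned_len
    for (pt, pq), (nt, nq) in zip(
        zip(target_blocks[:-1], query_blocks[:-1]),
        zip(target_blocks[1:], query_blocks[1:]),
    ):
        columns += (nt[0] - pt[1]) + (nq[0] - pq[1])
    query_span = int(query_blocks[-1][1] - query_blocks[0][0])
    if columns == 0 or query_span < min_overlap:
        return None
    identity = matches / columns
    if identity < identity_threshold:
        return None
    return AdapterHit(
        adapter_id=adapter_id,
        read_id=read.id,
        end_label=end_label,
        lo=offset + int(target_blocks[0][0]),
        hi=offset + int(target_blocks[-1][1]),
        identity=identity,
    )


def trim_read(read: Read, hits: Sequence[AdapterHit], extra: int = 2) -> Read:
    """Clip the read according to its adapter hits.

    Removes [0, start_hit.hi + extra) and [end_hit.lo - extra, len);
    cuts are clamped to the read bounds and qualities are trimmed in
    lockstep. Crossing removals leave an empty read (for the caller to
    drop).
    """
    length = len(read.bases)
    cut_lo = 0
    cut_hi = length
    for hit in hits:
        if hit.read_id != read.id:
            raise ValueError(f"hit for read {hit.read_id!r} applied to {read.id!r}")
        if hit.end_label == "start":
            cut_lo = max(cut_lo, min(length, hit.hi + extra))
        else:
            cut_hi = min(cut_hi, max(0, hit.lo - extra))
    if cut_lo >= cut_hi:
        return Read(read.id, "", "" if read.quals is not None else None)
    bases = read.bases[cut_lo:cut_hi]
    quals = read.quals[cut_lo:cut_hi] if read.quals is not None else None
    return Read(read.id, bases, quals)


def _adapter_lists(
    adapters: InferenceResult | tuple[Sequence[str], Sequence[str]],
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    if isinstance(adapters, InferenceResult):
        starts = [
            (f"start_{i + 1}", a.sequence) for i, a in enumerate(adapters.start_adapters)
        ]
        ends = [
            (f"end_{i + 1}", a.sequence) for i, a in enumerate(adapters.end_adapters)
        ]
        return starts, ends
    start_seqs, end_seqs = adapters
    return (
        [(f"start_{i + 1}", s) for i, s in enumerate(start_seqs)],
        [(f"end_{i + 1}", s) for i, s in enumerate(end_seqs)],
    )


def trim_reads(
    reads: Iterable[Read],
    adapters: InferenceResult | tuple[Sequence[str], Sequence[str]],
    config: TrimConfig | None = None,
) -> tuple[list[Read], TrimSummary]:
    """Trim an in-memory read collection; returns kept reads and counts."""
    config = config or TrimConfig()
    starts, ends = _adapter_lists(adapters)
    summary = TrimSummary()
    kept: list[Read] = []
    for read in reads:
        summary.reads_seen += 1
        hits: list[AdapterHit] = []
        best_start = _best_hit(read, starts, "start", config)
        if best_start is not None:
            hits.append(best_start)
            summary.start_trimmed += 1
        best_end = _best_hit(read, ends, "end", config)
        if best_end is not None:
            hits.append(best_end)
            summary.end_trimmed += 1
        trimmed = trim_read(read, hits, config.extra) if hits else read
        if len(trimmed.bases) < config.min_len:
            summary.dropped += 1
            continue
        kept.append(trimmed)
        summary.written += 1
    return kept, summary


def _best_hit(
    read: Read,
    adapters: list[tuple[str, str]],
    end_label: str,
    config: TrimConfig,
) -> AdapterHit | None:
    best: AdapterHit | None = None
    for adapter_id, seq in adapters:
        hit = locate_adapter(
            read,
            seq,
            end_label,
            search_len=config.search_len,
            identity_threshold=config.identity_threshold,
            min_overlap=config.min_overlap,
            adapter_id=adapter_id,
        )
        if hit is None:
            continue
        if best is None or (hit.identity, hit.hi - hit.lo) > (
            best.identity,
            best.hi - best.lo,
        ):
            best = hit
    return best


def trim_dataset(
    in_path: str | Path,
    adapters: InferenceResult | tuple[Sequence[str], Sequence[str]],
    out_path: str | Path,
    config: TrimConfig | None = None,
) -> TrimSummary:
    """Trim a FASTQ file with the given adapters; writes trimmed FASTQ."""
    kept, summary = trim_reads(read_fastq(in_path), adapters, config)
    write_fastq(kept, out_path)
    return summary
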