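"""FASTQ input/output, read sampling and extremity-region extraction.

Reads are streamed from plain or gzip-compressed FASTQ (gzip is detected
from the magic bytes, not the file name). Multi-line FASTA is also
accepted for inference-only use. Bases are uppercased and U is mapped to
T on input. Adapter inference then works on fixed-length regions cut
from the start and end of each read of independently drawn read samples.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Read",
    "RegionSample",
    "read_fastq",
    "write_fastq",
    "sample_reads",
    "extract_regions",
]

_GZIP_MAGIC = b"\x1f\x8b"
_INPUT_TRANS = str.maketrans("acgtunU", "ACGTTNT")


@dataclass
class Read:
    """One sequencing read: identifier, bases and per-base qualities.

    ``quals`` is ``None`` for FASTA input; otherwise it has the same
    length as ``bases``.
    """

    id: str
    bases: str
    quals: str | None = None

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class RegionSample:
    """The start (or end) regions of every read of one sample."""

    end_label: str  # "start" or "end"
    regions: list[str] = field(default_factory=list)
    sample_index: int = 0


class FastqFormatError(ValueError):
    """Raised for structurally malformed FASTQ/FASTA records."""


def _open_maybe_gzip(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == _GZIP_MAGIC:
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _read_fasta(handle: io.TextIOBase) -> Iterator[Read]:
    name: str | None = None
    parts: list[str] = []
    index = 0
    for line in handle:
        line = line.rstrip("\n")
        if line.startswith(">"):
            if name is not None:
                yield Read(name, "".join(parts).translate(_INPUT_TRANS))
            index += 1
            name = line[1:].split()[0] if len(line) > 1 else f"record{index}"
            parts = []
        elif name is None:
            raise FastqFormatError("FASTA record 1: sequence before first header")
        else:
            parts.append(line.strip())
    if name is not None:
        yield Read(name, "".join(parts).translate(_INPUT_TRANS))


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream reads from FASTQ, gzipped FASTQ or FASTA.

    Yields reads in file order with bases uppercased and U mapped to T.
    Malformed records (missing separator line, quality/sequence length
    mismatch, truncated record) raise :class:`FastqFormatError` naming
    the 1-based record index.
    """
    handle = _open_maybe_gzip(path)
    try:
        first = handle.read(1)
        if first == ">":
            buffered = io.StringIO(">" + handle.read())
            yield from _read_fasta(buffered)
            return
        if not first:
            return
        line = first + handle.readline()
        index = 0
        while line:
            index += 1
            header = line.rstrip("\n")
            if not header.startswith("@"):
                raise FastqFormatError(
                    f"FASTQ record {index}: header does not start with '@'"
                )
            seq = handle.readline()
            sep = handle.readline()
            qual = handle.readline()
            if not qual:
                raise FastqFormatError(f"FASTQ record {index}: truncated record")
            seq = seq.rstrip("\n")
            qual = qual.rstrip("\n")
            if not sep.startswith("+"):
                raise FastqFormatError(
                    f"FASTQ record {index}: missing '+' separator line"
                )
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"FASTQ record {index}: sequence and quality lengths differ "
                    f"({len(seq)} vs {len(qual)})"
                )
            name = header[1:].split()[0] if len(header) > 1 else f"record{index}"
            yield Read(name, seq.translate(_INPUT_TRANS), qual)
            line = handle.readline()
    finally:
        handle.close()


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as 4-line FASTQ; returns the number of records written.

    Reads lacking qualities (FASTA input) get a flat 'I' quality string.
    Gzip output is chosen from a ``.gz`` suffix.
    """
    path = Path(path)
    n = 0
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        for read in reads:
            quals = read.quals if read.quals is not None else "I" * len(read.bases)
            out.write(f"@{read.id}\n{read.bases}\n+\n{quals}\n")
            n += 1
    return n


def sample_reads(
    reads: Sequence[Read],
    n_samples: int,
    sample_size: int,
    seed: int,
) -> list[np.ndarray]:
    """Draw ``n_samples`` independent read-index samples.

    Each sample is drawn uniformly at random without replacement within
    the sample; distinct samples are drawn independently and may share
    reads. When the dataset holds at most ``sample_size`` reads every
    sample is the full dataset. Indices are returned sorted ascending;
    the draw is reproducible for a fixed seed.
    """
    if n_samples < 1 or sample_size < 1:
        raise ValueError("n_samples and sample_size must be >= 1")
    n = len(reads)
    if n == 0:
        raise ValueError("cannot sample from an empty read set")
    rng = np.random.default_rng(seed)
    if n <= sample_size:
        return [np.arange(n, dtype=np.int64) for _ in range(n_samples)]
    return [
        np.sort(rng.choice(n, size=sample_size, replace=False)).astype(np.int64)
        for _ in range(n_samples)
    ]


def extract_regions(
    sample: Iterable[Read],
    end_label: str,
    region_len: int = 100,
    sample_index: int = 0,
) -> RegionSample:
    """Cut the first (or last) ``region_len`` bases from every read.

    Reads shorter than ``region_len`` contribute their full sequence;
    nothing is reverse-complemented, since start and end adapters are
    distinct sequences.
    """
    if end_label not in ("start", "end"):
        raise ValueError("end_label must be 'start' or 'end'")
    if region_len < 1:
        raise ValueError("region_len must be >= 1")
    if end_label == "start":
        regions = [read.bases[:region_len] for read in sample]
    else:
        regions = [read.bases[-region_len:] for read in sample]
    return RegionSample(end_label=end_label, regions=regions, sample_index=sample_index)
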