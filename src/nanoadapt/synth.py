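"""ONT-like read simulation with planted adapters and ground truth.

Emulates the library-preparation footprint that the inference pipeline
exploits: most reads begin with a ligated start adapter, and about half
end with a partial end adapter whose retained length averages a small
fraction of the full sequence (the end of the molecule is the part that
goes unsequenced, so the *start* of the end adapter — the part adjacent
to the insert — is what remains, flush with the read end). Edit-type
sequencing noise (mismatches, insertions, deletions in equal parts) is
applied to the whole read after assembly, and true adapter intervals
are tracked through the indels. Inserts are i.i.d. uniform bases by
default or substrings spliced from a user-supplied FASTA.

Negative datasets for specificity checks come from
:func:`shuffle_negative`: either i.i.d. random reads matching the input
length distribution, or input reads with both 100-nt extremity regions
removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .fastq_io import Read, read_fastq

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_reads",
    "write_truth_tsv",
    "shuffle_negative",
    "random_adapter",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class SimConfig:
    """Parameters of one simulated dataset.

    ``error_rate`` is the per-base probability of an edit, split equally
    between mismatch, insertion and deletion. ``end_retained_mean_frac``
    fixes the mean retained end-adapter length as a fraction of the full
    adapter, matched exactly by a truncated-geometric draw.
    """

    n_reads: int
    start_adapter: str
    end_adapter: str = ""
    start_prob: float = 0.9
    end_prob: float = 0.5
    end_retained_mean_frac: float = 0.2
    error_rate: float = 0.05
    insert_len_range: tuple[int, int] = (300, 2000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        for name in ("start_prob", "end_prob", "end_retained_mean_frac", "error_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class TruthRecord:
    """True adapter placement of one read, after noise. -1 marks absence."""

    read_id: str
    start_lo: int = -1
    start_hi: int = -1
    end_lo: int = -1
    end_hi: int = -1
    retained_frac: float = -1.0


def random_adapter(length: int, rng: np.random.Generator) -> str:
    """A uniform random adapter sequence of the given length."""
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def _truncated_geometric_p(length: int, target_mean: float) -> float:
    """p of min(Geometric(p), length) with the requested mean."""

    def mean_minus_target(p: float) -> float:
        return (1.0 - (1.0 - p) ** length) / p - target_mean

    return brentq(mean_minus_target, 1e-9, 1 - 1e-12)


def _retained_lengths(
    n: int, adapter_len: int, mean_frac: float, rng: np.random.Generator
) -> np.ndarray:
    if adapter_len == 0 or n == 0:
        return np.zeros(n, dtype=np.int64)
    target = mean_frac * adapter_len
    if target >= adapter_len:
        return np.full(n, adapter_len, dtype=np.int64)
    if target <= 1.0:
        return np.ones(n, dtype=np.int64)
    p = _truncated_geometric_p(adapter_len, target)
    return np.minimum(rng.geometric(p, n), adapter_len).astype(np.int64)


def simulate_reads(
    config: SimConfig,
    insert_source: str | Path | None = None,
) -> tuple[list[Read], list[TruthRecord]]:
    """Simulate reads and their ground-truth adapter placements.

    Each read is [start adapter] + insert + [retained end-adapter
    prefix], with presence probabilities from the config, then per-base
    edit noise over the whole read. Truth intervals are mapped through
    the indels. Fully deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reads
    start_arr = _CODE[np.frombuffer(config.start_adapter.encode(), dtype=np.uint8)]
    end_arr = _CODE[np.frombuffer(config.end_adapter.encode(), dtype=np.uint8)]

    insert_lens = rng.integers(
        config.insert_len_range[0], config.insert_len_range[1] + 1, n
    )
    has_start = rng.random(n) < config.start_prob
    if start_arr.size == 0:
        has_start[:] = False
    has_end = rng.random(n) < config.end_prob
    if end_arr.size == 0:
        has_end[:] = False
    retained = _retained_lengths(
        n, end_arr.size, config.end_retained_mean_frac, rng
    )
    retained = np.where(has_end, retained, 0)

    start_lens = np.where(has_start, start_arr.size, 0)
    read_lens = start_lens + insert_lens + retained
    offsets = np.concatenate([[0], np.cumsum(read_lens)])
    total = int(offsets[-1])

    if insert_source is not None:
        pool = _insert_pool(insert_source)
        insert_bases = _spliced_inserts(pool, insert_lens, rng)
    else:
        insert_bases = rng.integers(0, 4, int(insert_lens.sum()), dtype=np.uint8)

    clean = np.empty(total, dtype=np.uint8)
    ins_off = np.concatenate([[0], np.cumsum(insert_lens)])
    for i in range(n):
        pos = offsets[i]
        if has_start[i]:
            clean[pos : pos + start_arr.size] = start_arr
            pos += start_arr.size
        pos2 = pos + insert_lens[i]
        clean[pos:pos2] = insert_bases[ins_off[i] : ins_off[i + 1]]
        if retained[i]:
            clean[pos2 : pos2 + retained[i]] = end_arr[: retained[i]]

    noisy, prefix_out = _apply_edit_noise(clean, config.error_rate, rng)

    # map clean coordinates to noisy coordinates through the indels
    def mapped(positions: np.ndarray) -> np.ndarray:
        return prefix_out[positions]

    new_offsets = prefix_out[offsets]
    reads: list[Read] = []
    truths: list[TruthRecord] = []
    width = len(str(max(n - 1, 1)))
    seq_text = _decode_all(noisy)
    for i in range(n):
        lo, hi = int(new_offsets[i]), int(new_offsets[i + 1])
        read_id = f"read{i:0{width}d}"
        bases = seq_text[lo:hi]
        reads.append(Read(read_id, bases, "I" * len(bases)))
        truth = TruthRecord(read_id)
        if has_start[i]:
            truth.start_lo = 0
            truth.start_hi = int(mapped(offsets[i] + start_lens[i])) - lo
        if retained[i]:
            truth.end_lo = int(mapped(offsets[i + 1] - retained[i])) - lo
            truth.end_hi = hi - lo
            truth.retained_frac = retained[i] / end_arr.size
        truths.append(truth)
    return reads, truths


def _apply_edit_noise(
    clean: np.ndarray, error_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Apply per-base mismatch/insertion/deletion noise.

    Returns the noisy base array and, for every clean position p, the
    number of output bases emitted by the first p clean bases
    (``prefix_out``, length len(clean)+1), used to map coordinates.
    """
    total = clean.size
    if error_rate <= 0.0 or total == 0:
        return clean.copy(), np.arange(total + 1, dtype=np.int64)
    # compact dtypes: these arrays span every simulated base
    is_err = rng.random(total, dtype=np.float32) < error_rate
    kind = rng.integers(0, 3, total, dtype=np.int8)  # 0 mismatch, 1 ins, 2 del
    kind[~is_err] = -1
    del is_err
    is_sub = kind == 0
    is_ins = kind == 1

    out_counts = np.ones(total, dtype=np.int8)
    out_counts[kind == 2] = 0
    out_counts[is_ins] = 2  # the base, then one inserted random base
    del kind
    prefix_dtype = np.int32 if 2 * total < 2**31 else np.int64
    prefix_out = np.empty(total + 1, dtype=prefix_dtype)
    prefix_out[0] = 0
    np.cumsum(out_counts, dtype=prefix_dtype, out=prefix_out[1:])

    out = np.repeat(clean, out_counts)
    sub_pos = prefix_out[:-1][is_sub]
    out[sub_pos] = (out[sub_pos] + rng.integers(1, 4, sub_pos.size, dtype=np.uint8)) % 4
    ins_pos = prefix_out[1:][is_ins] - 1
    out[ins_pos] = rng.integers(0, 4, ins_pos.size, dtype=np.uint8)
    return out, prefix_out


def _decode_all(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def _insert_pool(source: str | Path) -> np.ndarray:
    parts = []
    for read in read_fastq(source):
        seq = read.bases.replace("N", "")
        if seq:
            parts.append(_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)])
    if not parts:
        raise ValueError(f"no usable sequence in insert source {source}")
    return np.concatenate(parts)


def _spliced_inserts(
    pool: np.ndarray, lens: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = np.empty(int(lens.sum()), dtype=np.uint8)
    pos = 0
    for length in lens:
        length = int(length)
        if length >= pool.size:
            reps = int(np.ceil(length / pool.size))
            out[pos : pos + length] = np.tile(pool, reps)[:length]
        else:
            start = int(rng.integers(0, pool.size - length + 1))
            out[pos : pos + length] = pool[start : start + length]
        pos += length
    return out


def write_truth_tsv(truths: Sequence[TruthRecord], path: str | Path) -> None:
    """Truth table as TSV; -1 marks an absent adapter."""
    with open(path, "wt") as out:
        out.write("read_id\tstart_lo\tstart_hi\tend_lo\tend_hi\tretained_frac\n")
        for t in truths:
            out.write(
                f"{t.read_id}\t{t.start_lo}\t{t.start_hi}\t{t.end_lo}\t{t.end_hi}\t"
                f"{t.retained_frac:.4f}\n"
            )


def shuffle_negative(
    reads: str | Path | Sequence[Read],
    seed: int = 0,
    mode: str = "random",
    region_len: int = 100,
) -> list[Read]:
    """Build a negative (adapter-free) dataset from an input one.

    mode="random": i.i.d. uniform reads matching the input length
    distribution. mode="strip": input reads with the first and last
    ``region_len`` bases removed; reads of at most ``2 * region_len``
    bases are dropped.
    """
    if isinstance(reads, (str, Path)):
        reads = list(read_fastq(reads))
    if mode == "random":
        rng = np.random.default_rng(seed)
        out = []
        for read in reads:
            bases = _decode_all(rng.integers(0, 4, len(read.bases), dtype=np.uint8))
            out.append(Read(read.id, bases, "I" * len(bases)))
        return out
    if mode == "strip":
        out = []
        for read in reads:
            if len(read.bases) <= 2 * region_len:
                continue
            bases = read.bases[region_len:-region_len]
            quals = read.quals[region_len:-region_len] if read.quals else None
            out.append(Read(read.id, bases, quals))
        return out
    raise ValueError("mode must be 'random' or 'strip'")
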