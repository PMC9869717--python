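"""Cross-sample consensus of per-sample adapter candidates.

The candidates assembled from the independent read samples are merged
by single-linkage clustering under pairwise global-alignment identity.
Each cluster yields one consensus sequence (progressive multiple
alignment, column-wise majority vote) carrying a support score: the
fraction of samples whose candidate joined the cluster. Two filters
decide what is reported: a minimum support, and the no-adapter rule —
a cluster's members must out-weigh, by a configurable factor, the
assembly-path weight measured on dinucleotide-shuffled copies of the
same regions. Adapter-free input (random reads, or reads whose
extremities were already trimmed away) fails that bar, so the result
lists come back empty.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np
from Bio import Align

from .approx_kmer import count_sample
from .assembly import CandidateAdapter, assemble_sample
from .config import InferenceConfig
from .fastq_io import Read, extract_regions, read_fastq, sample_reads

__all__ = [
    "ConsensusAdapter",
    "InferenceResult",
    "alignment_identity",
    "cluster_candidates",
    "consensus_sequence",
    "score_and_filter",
    "estimate_background_weight",
    "dinucleotide_shuffle",
    "infer_adapters",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _make_global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


_GLOBAL_ALIGNER = _make_global_aligner()


@dataclass
class ConsensusAdapter:
    """A reported adapter: consensus sequence plus its sample support."""

    sequence: str
    end_label: str
    support: float
    member_indices: list[int] = field(default_factory=list)
    mean_path_weight: float = 0.0


@dataclass
class InferenceResult:
    """Inferred adapters for both read ends; empty lists mean "no motif"."""

    start_adapters: list[ConsensusAdapter] = field(default_factory=list)
    end_adapters: list[ConsensusAdapter] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.start_adapters and not self.end_adapters

    def format_text(self) -> str:
        lines = []
        for adapter in self.start_adapters + self.end_adapters:
            lines.append(
                f"{adapter.end_label}\t{adapter.sequence}\t{adapter.support * 100:.1f}%"
            )
        return "\n".join(lines) if lines else "no adapter found"

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "wt") as out:
            out.write("end\tsequence\tsupport\tmean_path_weight\n")
            for adapter in self.start_adapters + self.end_adapters:
                out.write(
                    f"{adapter.end_label}\t{adapter.sequence}\t"
                    f"{adapter.support:.3f}\t{adapter.mean_path_weight:.1f}\n"
                )

    def to_porechop_entries(self, prefix: str = "abinitio") -> str:
        """Adapter-database entries in Porechop's adapter.py syntax."""
        n = max(len(self.start_adapters), len(self.end_adapters))
        entries = []
        for i in range(n):
            name = f"{prefix}_{i + 1}"
            start = self.start_adapters[i].sequence if i < len(self.start_adapters) else ""
            end = self.end_adapters[i].sequence if i < len(self.end_adapters) else ""
            entries.append(
                f"Adapter('{name}',\n"
                f"        start_sequence=('{name}_start', '{start}'),\n"
                f"        end_sequence=('{name}_end', '{end}'))"
            )
        return ",\n".join(entries)


def alignment_identity(a: str, b: str) -> float:
    """Global-alignment identity: matched columns / alignment length."""
    if not a or not b:
        return 0.0
    result = edlib.align(a, b, mode="NW", task="path")
    matches = columns = 0
    for num, op in _CIGAR_RE.findall(result["cigar"]):
        num = int(num)
        columns += num
        if op == "=":
            matches += num
    return matches / columns


def cluster_candidates(
    candidates: Sequence[CandidateAdapter],
    cluster_identity: float = 0.75,
) -> list[list[CandidateAdapter]]:
    """Single-linkage clusters under pairwise identity >= cluster_identity.

    Clusters are returned in order of first appearance of their
    earliest member, so the partition is deterministic for fixed input.
    """
    n = len(candidates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if alignment_identity(candidates[i].sequence, candidates[j].sequence) >= cluster_identity:
                parent[find(j)] = find(i)

    groups: dict[int, list[CandidateAdapter]] = {}
    for i, cand in enumerate(candidates):
        groups.setdefault(find(i), []).append(cand)
    return [groups[root] for root in sorted(groups, key=lambda r: min(
        i for i in range(n) if find(i) == r))]


def _majority_base(column: Counter) -> str:
    best = max((c for c in column if c != "-"), key=lambda c: (column[c], -ord(c)),
               default="-")
    return best


def _progressive_rows(seqs: list[str]) -> list[str]:
    """Progressive alignment, longest sequence first as guide."""
    ordered = sorted(seqs, key=lambda s: (-len(s), s))
    rows = [ordered[0]]
    for seq in ordered[1:]:
        profile = "".join(
            _majority_base(Counter(col)) for col in zip(*rows)
        )
        aln = _GLOBAL_ALIGNER.align(profile, seq)[0]
        gapped_profile, gapped_seq = str(aln[0]), str(aln[1])
        new_rows: list[list[str]] = [[] for _ in rows]
        new_row: list[str] = []
        ip = 0
        for cp, cs in zip(gapped_profile, gapped_seq):
            if cp == "-":
                for row_chars in new_rows:
                    row_chars.append("-")
            else:
                for row, row_chars in zip(rows, new_rows):
                    row_chars.append(row[ip])
                ip += 1
            new_row.append(cs)
        rows = ["".join(chars) for chars in new_rows]
        rows.append("".join(new_row))
    return rows


def consensus_sequence(cluster: Sequence[CandidateAdapter | str]) -> str:
    """Column-majority consensus of a cluster of candidate adapters.

    Members are progressively aligned (longest first as guide). Ragged
    end columns carried by fewer than half of the members are trimmed,
    then each remaining column votes: the most frequent base wins (ties
    lexicographic); a column is dropped when gaps outnumber every base.
    """
    seqs = [c if isinstance(c, str) else c.sequence for c in cluster]
    if not seqs:
        raise ValueError("empty cluster")
    if len(seqs) == 1:
        return seqs[0]
    rows = _progressive_rows(seqs)
    n_members = len(rows)
    columns = ["".join(col) for col in zip(*rows)]
    occupancy = [sum(c != "-" for c in col) for col in columns]
    lo, hi = 0, len(columns)
    while lo < hi and occupancy[lo] * 2 < n_members:
        lo += 1
    while hi > lo and occupancy[hi - 1] * 2 < n_members:
        hi -= 1
    out = []
    for col in columns[lo:hi]:
        counts = Counter(col)
        base = _majority_base(counts)
        if base == "-" or counts["-"] > counts[base]:
            continue
        out.append(base)
    return "".join(out)


def score_and_filter(
    start_clusters: Sequence[Sequence[CandidateAdapter]],
    end_clusters: Sequence[Sequence[CandidateAdapter]],
    n_samples: int,
    *,
    min_support: float = 0.3,
    background_factor: float = 10.0,
    start_background: float | None = None,
    end_background: float | None = None,
) -> InferenceResult:
    """Score clusters and apply the support and no-adapter filters.

    Support is the fraction of samples whose candidate joined the
    cluster. Clusters below ``min_support`` are dropped; when a
    background path weight is supplied, clusters whose members' mean
    path weight does not exceed ``background_factor`` times it are
    dropped as indistinguishable from adapter-free input.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")

    def scored(clusters, background, end_label):
        adapters = []
        for cluster in clusters:
            support = len(cluster) / n_samples
            if support < min_support:
                continue
            mean_weight = float(np.mean([c.path_weight for c in cluster]))
            if background is not None and mean_weight <= background_factor * max(background, 1.0):
                continue
            adapters.append(
                ConsensusAdapter(
                    sequence=consensus_sequence(cluster),
                    end_label=end_label,
                    support=support,
                    member_indices=sorted(c.sample_index for c in cluster),
                    mean_path_weight=mean_weight,
                )
            )
        adapters.sort(key=lambda a: (-a.support, a.sequence))
        return adapters

    return InferenceResult(
        start_adapters=scored(start_clusters, start_background, "start"),
        end_adapters=scored(end_clusters, end_background, "end"),
    )


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide composition.

    Random Eulerian walk on the dinucleotide transition graph (edges
    consumed in randomized order, restarted on the rare dead end);
    falls back to a plain shuffle if no walk completes.
    """
    if len(seq) < 3:
        return seq
    n_edges = len(seq) - 1
    for _ in range(10):
        adjacency: dict[str, list[str]] = {}
        for a, b in zip(seq, seq[1:]):
            adjacency.setdefault(a, []).append(b)
        for targets in adjacency.values():
            rng.shuffle(targets)
        cursor = {a: 0 for a in adjacency}
        out = [seq[0]]
        current = seq[0]
        for _ in range(n_edges):
            targets = adjacency.get(current)
            i = cursor.get(current, 0)
            if targets is None or i >= len(targets):
                break
            cursor[current] = i + 1
            current = targets[i]
            out.append(current)
        if len(out) == len(seq):
            return "".join(out)
    chars = list(seq)
    rng.shuffle(chars)
    return "".join(chars)


def estimate_background_weight(
    regions: Sequence[str],
    config: InferenceConfig,
    rng: np.random.Generator,
    end_label: str = "start",
) -> float:
    """Expected heaviest-path weight on adapter-free regions.

    Runs counting and assembly on dinucleotide-preserving shuffles of
    the given regions and averages the resulting path weights.
    """
    weights = []
    for _ in range(config.background_replicates):
        shuffled = [dinucleotide_shuffle(r, rng) for r in regions]
        table = count_sample(
            shuffled, config.k, config.max_edits, config.candidate_limit
        )
        candidate = assemble_sample(table, config.graph_limit, end_label, -1)
        weights.append(candidate.path_weight if candidate is not None else 0.0)
    return float(np.mean(weights)) if weights else 0.0


def infer_adapters(
    reads: str | Path | Sequence[Read],
    config: InferenceConfig | None = None,
) -> InferenceResult:
    """Full ab initio inference: sample, count, assemble, build consensus.

    ``reads`` may be a FASTQ/FASTA path (plain or gzipped) or an
    in-memory read list. Deterministic for a fixed ``config.seed``.
    """
    config = config or InferenceConfig()
    if isinstance(reads, (str, Path)):
        reads = list(read_fastq(reads))
    if not reads:
        raise ValueError("no reads in input")

    index_sets = sample_reads(reads, config.n_samples, config.sample_size, config.seed)
    identical_samples = len(reads) <= config.sample_size
    background_rng = np.random.default_rng([config.seed, 0xB1A5])

    clusters = {}
    backgrounds = {}
    for end_label in ("start", "end"):
        candidates: list[CandidateAdapter] = []
        first_regions: list[str] | None = None
        cached = None
        for si, indices in enumerate(index_sets):
            if identical_samples and cached is not None:
                candidate = CandidateAdapter(
                    sequence=cached.sequence,
                    path_weight=cached.path_weight,
                    end_label=end_label,
                    sample_index=si,
                )
            else:
                sample = extract_regions(
                    (reads[i] for i in indices), end_label, config.region_len, si
                )
                if first_regions is None:
                    first_regions = sample.regions
                table = count_sample(
                    sample, config.k, config.max_edits, config.candidate_limit
                )
                candidate = assemble_sample(table, config.graph_limit, end_label, si)
                if identical_samples:
                    cached = candidate
                    if candidate is None:
                        cached = CandidateAdapter("", 0.0, end_label, si)
            if candidate is not None and candidate.sequence:
                candidates.append(candidate)
        clusters[end_label] = cluster_candidates(candidates, config.cluster_identity)
        backgrounds[end_label] = estimate_background_weight(
            first_regions or [], config, background_rng, end_label
        )

    return score_and_filter(
        clusters["start"],
        clusters["end"],
        config.n_samples,
        min_support=config.min_support,
        background_factor=config.background_factor,
        start_background=backgrounds["start"],
        end_background=backgrounds["end"],
    )
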