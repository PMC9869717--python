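"""Default parameters for adapter inference and trimming.

The inference defaults mirror the published protocol where it states them
(10 samples of 40 000 reads, 100-nt extremity regions) and otherwise fix
reasonable values for ONT data: 16-mers fit inside every known adapter
(adapters run from 16 nt to beyond 30 nt), and one edit per 16-mer (~6%)
sits within typical ONT error rates.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class InferenceConfig:
    """Tunable knobs of the ab initio inference pipeline.

    Attributes
    ----------
    n_samples : int
        Number of independent read samples drawn from the dataset.
    sample_size : int
        Reads per sample (without replacement within a sample).
    region_len : int
        Length of the start/end region taken from each read, in nt.
    k : int
        k-mer size used for counting and assembly.
    max_edits : int
        Edit-distance budget (mismatches, insertions, deletions) when
        counting approximate k-mer occurrences.
    graph_limit : int
        Number of top-count k-mers that seed the assembly graph.
    candidate_limit : int
        Number of k-mers (pre-ranked by exact count) for which the
        approximate count is evaluated. ``None`` evaluates every k-mer
        that occurs exactly at least once; the default keeps large
        samples tractable without touching the ranking of frequent
        k-mers, which dominate both orderings.
    cluster_identity : float
        Minimum pairwise global-alignment identity for two per-sample
        candidates to join the same consensus cluster.
    min_support : float
        Consensus clusters below this support fraction are discarded.
    background_factor : float
        A cluster is reported only if its members' mean assembly-path
        weight exceeds ``background_factor`` times the path weight
        measured on dinucleotide-shuffled regions. This is the
        no-adapter rule: on adapter-free input nothing clears the bar.
    background_replicates : int
        Number of shuffled replicates averaged for the background
        estimate.
    seed : int
        Seed for read sampling and background shuffling.
    """

    n_samples: int = 10
    sample_size: int = 40_000
    region_len: int = 100
    k: int = 16
    max_edits: int = 1
    graph_limit: int = 500
    candidate_limit: int | None = 2000
    cluster_identity: float = 0.75
    min_support: float = 0.3
    background_factor: float = 10.0
    background_replicates: int = 3
    seed: int = 0


@dataclass
class TrimConfig:
    """Trimming parameters (Porechop-compatible where applicable).

    ``identity_threshold`` (75%), ``extra`` (2 nt removed beyond the
    adapter hit) and ``search_len`` (150-nt end windows) follow
    Porechop's public defaults. ``min_overlap`` is the minimum number of
    adapter bases that must align before a hit is accepted; it guards
    against spurious short end-anchored matches when partial adapters
    are allowed to overhang the read boundary.
    """

    search_len: int = 150
    identity_threshold: float = 0.75
    min_overlap: int = 18
    extra: int = 2
    min_len: int = 1
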