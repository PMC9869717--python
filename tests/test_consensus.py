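"""Candidate clustering, consensus building and the no-adapter rule."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from nanoadapt.assembly import CandidateAdapter
from nanoadapt.config import InferenceConfig
from nanoadapt.consensus import (
    InferenceResult,
    alignment_identity,
    cluster_candidates,
    consensus_sequence,
    dinucleotide_shuffle,
    estimate_background_weight,
    infer_adapters,
    score_and_filter,
)

from conftest import mutate, random_dna


def cand(seq: str, index: int = 0, weight: float = 1000.0, end: str = "start") -> CandidateAdapter:
    return CandidateAdapter(sequence=seq, path_weight=weight, end_label=end, sample_index=index)


def reference_single_linkage(seqs: list[str], threshold: float) -> list[set[str]]:
    """Independent clustering oracle: connected components of the
    identity-threshold graph."""
    graph = nx.Graph()
    graph.add_nodes_from(range(len(seqs)))
    for i, j in itertools.combinations(range(len(seqs)), 2):
        if alignment_identity(seqs[i], seqs[j]) >= threshold:
            graph.add_edge(i, j)
    return [
        sorted(seqs[i] for i in comp) for comp in nx.connected_components(graph)
    ]


class TestClustering:
    def test_identical_strings_one_cluster(self):
        candidates = [cand("ACGTACGTAC", i) for i in range(10)]
        clusters = cluster_candidates(candidates)
        assert len(clusters) == 1
        assert len(clusters[0]) == 10

    def test_two_distinct_adapters_split(self, rng):
        a1, a2 = random_dna(30, rng), random_dna(30, rng)
        while alignment_identity(a1, a2) >= 0.5:
            a2 = random_dna(30, rng)
        candidates = [cand(a1, i) for i in range(5)] + [cand(a2, 5 + i) for i in range(5)]
        clusters = cluster_candidates(candidates)
        assert sorted(len(c) for c in clusters) == [5, 5]

    def test_partition_matches_reference_oracle(self, rng):
        base = random_dna(25, rng)
        seqs = [mutate(base, int(rng.integers(0, 9)), rng) for _ in range(12)]
        clusters = cluster_candidates([cand(s, i) for i, s in enumerate(seqs)], 0.75)
        got = sorted(
            [sorted(c.sequence for c in cluster) for cluster in clusters]
        )
        expected = sorted(reference_single_linkage(seqs, 0.75))
        assert got == expected


class TestConsensusSequence:
    def test_unanimity(self):
        assert consensus_sequence(["ACGT", "ACGT", "ACGT"]) == "ACGT"

    def test_majority_at_last_column(self):
        assert consensus_sequence(["ACGT", "ACGA", "ACGT"]) == "ACGT"

    def test_single_member_is_itself(self):
        assert consensus_sequence(["TTAGGC"]) == "TTAGGC"

    def test_noisy_copies_recover_known_sequence(self, rng):
        truth = random_dna(26, rng)
        copies = [mutate(truth, int(rng.integers(0, 2)), rng) for _ in range(10)]
        consensus = consensus_sequence(copies)
        import edlib

        assert edlib.align(consensus, truth, mode="NW")["editDistance"] <= 1

    def test_order_invariance(self, rng):
        truth = random_dna(24, rng)
        copies = [mutate(truth, int(rng.integers(0, 2)), rng) for _ in range(8)]
        shuffled = list(copies)
        np.random.default_rng(5).shuffle(shuffled)
        assert consensus_sequence(copies) == consensus_sequence(shuffled)


class TestScoreAndFilter:
    def test_full_support_single_cluster(self):
        clusters = [[cand("ACGTACGTACGTACGTACGT", i) for i in range(10)]]
        result = score_and_filter(clusters, [], 10)
        assert len(result.start_adapters) == 1
        assert result.start_adapters[0].support == 1.0
        assert result.start_adapters[0].member_indices == list(range(10))

    def test_two_half_clusters(self, rng):
        a1, a2 = random_dna(30, rng), random_dna(30, rng)
        clusters = [
            [cand(a1, i) for i in range(5)],
            [cand(a2, 5 + i) for i in range(5)],
        ]
        result = score_and_filter(clusters, [], 10)
        assert [a.support for a in result.start_adapters] == [0.5, 0.5]

    def test_min_support_drops_singletons(self):
        clusters = [
            [cand("ACGTACGTACGTACGTACGT", i) for i in range(9)],
            [cand("TTTTGGGGCCCCAAAATTTT", 9)],
        ]
        result = score_and_filter(clusters, [], 10)
        assert len(result.start_adapters) == 1

    def test_background_rule_drops_weak_clusters(self):
        weak = [[cand("ACGTACGTACGTACGTACGT", i, weight=30.0) for i in range(10)]]
        kept = score_and_filter(weak, [], 10, start_background=2.0)
        dropped = score_and_filter(weak, [], 10, start_background=5.0)
        assert len(kept.start_adapters) == 1
        assert dropped.is_empty

    def test_supports_sum_to_at_most_one(self, rng):
        seqs = [random_dna(25, rng) for _ in range(4)]
        clusters = [
            [cand(seqs[j], 3 * j + i) for i in range(3)] for j in range(3)
        ]
        result = score_and_filter(clusters, [], 10, min_support=0.1)
        assert sum(a.support for a in result.start_adapters) <= 1.0


class TestBackground:
    def test_dinucleotide_shuffle_preserves_composition(self, rng):
        seq = random_dna(200, rng)
        shuffled = dinucleotide_shuffle(seq, rng)
        def dinucs(s):
            from collections import Counter

            return Counter(s[i : i + 2] for i in range(len(s) - 1))

        assert shuffled != seq
        assert dinucs(shuffled) == dinucs(seq)
        assert sorted(shuffled) == sorted(seq)

    def test_background_weight_far_below_planted_signal(self, rng):
        adapter = random_dna(24, rng)
        regions = [adapter + random_dna(76, rng) for _ in range(300)]
        config = InferenceConfig(candidate_limit=500)
        background = estimate_background_weight(regions, config, rng)
        assert background < 200  # planted signal would be ~24 * 300


class TestInferAdapters:
    def make_reads(self, rng, n=1500, start=None, end=None):
        from nanoadapt.synth import SimConfig, simulate_reads

        config = SimConfig(
            n_reads=n,
            start_adapter=start or "",
            end_adapter=end or "",
            start_prob=0.9 if start else 0.0,
            end_prob=0.5 if end else 0.0,
            error_rate=0.05,
            insert_len_range=(300, 800),
            seed=int(rng.integers(0, 2**31)),
        )
        return simulate_reads(config)[0]

    def test_single_adapter_both_ends_recovered(self, rng):
        start_truth = random_dna(28, rng)
        end_truth = random_dna(22, rng)
        reads = self.make_reads(rng, 4000, start_truth, end_truth)
        config = InferenceConfig(n_samples=4, sample_size=2000, seed=9)
        result = infer_adapters(reads, config)
        assert len(result.start_adapters) == 1
        assert len(result.end_adapters) == 1
        assert result.start_adapters[0].support == 1.0
        assert alignment_identity(result.start_adapters[0].sequence, start_truth) >= 0.85

    def test_permuting_reads_changes_nothing_material(self, rng):
        start_truth = random_dna(28, rng)
        reads = self.make_reads(rng, 2000, start_truth)
        config = InferenceConfig(n_samples=3, sample_size=1000, seed=4)
        res_a = infer_adapters(reads, config)
        res_b = infer_adapters(reads, config)
        assert res_a.start_adapters[0].sequence == res_b.start_adapters[0].sequence

    def test_trimmed_input_reports_no_motif(self, rng):
        from nanoadapt.synth import shuffle_negative

        start_truth = random_dna(28, rng)
        end_truth = random_dna(22, rng)
        reads = self.make_reads(rng, 2500, start_truth, end_truth)
        stripped = shuffle_negative(reads, seed=1, mode="strip")
        config = InferenceConfig(n_samples=4, sample_size=2000, seed=2)
        assert infer_adapters(stripped, config).is_empty


def test_result_serialization(tmp_path, rng):
    result = InferenceResult(
        start_adapters=[
            __import__("nanoadapt").ConsensusAdapter("ACGTACGT", "start", 1.0, [0, 1], 500.0)
        ]
    )
    assert "100.0%" in result.format_text()
    tsv = tmp_path / "adapters.tsv"
    result.to_tsv(tsv)
    assert "ACGTACGT" in tsv.read_text()
    entries = result.to_porechop_entries()
    assert "start_sequence=('abinitio_1_start', 'ACGTACGT')" in entries
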