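"""Per-sample adapter reconstruction through a weighted overlap graph.

The most represented k-mers of a sample form the nodes of a directed
graph whose edges are the (k-1)-overlaps among them; node weights are
the approximate counts. The candidate adapter is spelled from a heavy
simple path found by greedy bidirectional extension from the
heaviest node. Greedy extension (rather than a globally optimal path)
keeps the search deterministic and linear even when homopolymer
self-loops or cycles are present, where a maximum-weight simple path
would be intractable; the simple-path constraint bounds the candidate
length and stops homopolymer loops from spinning. All ties break
lexicographically so results are bit-reproducible.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx

from .approx_kmer import KmerCountTable, top_kmers

__all__ = [
    "CandidateAdapter",
    "build_graph",
    "heaviest_path",
    "path_to_sequence",
    "assemble_sample",
    "graph_to_dot",
]


@dataclass
class CandidateAdapter:
    """One per-sample assembled adapter with its supporting path weight."""

    sequence: str
    path_weight: float
    end_label: str
    sample_index: int


def build_graph(top: list[tuple[str, int]]) -> nx.DiGraph:
    """Overlap graph of k-mers: edge u->v when suffix(u,k-1) == prefix(v,k-1)."""
    if not top:
        raise ValueError("cannot build a graph from an empty k-mer list")
    k = len(top[0][0])
    if any(len(kmer) != k for kmer, _ in top):
        raise ValueError("all k-mers must have the same length")
    graph = nx.DiGraph()
    for kmer, count in top:
        graph.add_node(kmer, weight=count)
    by_prefix: dict[str, list[str]] = {}
    for kmer, _ in top:
        by_prefix.setdefault(kmer[: k - 1], []).append(kmer)
    for kmer, _ in top:
        for succ in by_prefix.get(kmer[1:], ()):
            graph.add_edge(kmer, succ)
    return graph


def _best(graph: nx.DiGraph, nodes) -> str | None:
    """Highest-weight node, ties to the lexicographically smallest."""
    best = None
    for node in nodes:
        if best is None:
            best = node
            continue
        wn, wb = graph.nodes[node]["weight"], graph.nodes[best]["weight"]
        if wn > wb or (wn == wb and node < best):
            best = node
    return best


def heaviest_path(graph: nx.DiGraph) -> list[str]:
    """Greedy bidirectional heaviest simple path.

    Seeds at the maximum-weight node and repeatedly extends the end
    whose best unvisited neighbor is heavier (ties: extend forward,
    neighbor ties lexicographic), never revisiting a node.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot extract a path from an empty graph")
    seed = _best(graph, graph.nodes)
    path: deque[str] = deque([seed])
    used = {seed}
    while True:
        right = _best(graph, (v for v in graph.successors(path[-1]) if v not in used))
        left = _best(graph, (u for u in graph.predecessors(path[0]) if u not in used))
        if right is None and left is None:
            return list(path)
        if left is None or (
            right is not None
            and graph.nodes[right]["weight"] >= graph.nodes[left]["weight"]
        ):
            path.append(right)
            used.add(right)
        else:
            path.appendleft(left)
            used.add(left)


def path_to_sequence(path: list[str]) -> str:
    """Spell a k-mer path: first k-mer plus the last base of each successor."""
    if not path:
        raise ValueError("empty path")
    pieces = [path[0]]
    for prev, cur in zip(path, path[1:]):
        if prev[1:] != cur[:-1]:
            raise ValueError(f"k-mers {prev!r} and {cur!r} do not overlap by k-1")
        pieces.append(cur[-1])
    return "".join(pieces)


def assemble_sample(
    table: KmerCountTable,
    limit: int,
    end_label: str,
    sample_index: int,
) -> CandidateAdapter | None:
    """Candidate adapter of one sample, or None when the table is empty."""
    if not table.counts:
        return None
    top = top_kmers(table, limit)
    graph = build_graph(top)
    path = heaviest_path(graph)
    return CandidateAdapter(
        sequence=path_to_sequence(path),
        path_weight=float(sum(graph.nodes[n]["weight"] for n in path)),
        end_label=end_label,
        sample_index=sample_index,
    )


def graph_to_dot(graph: nx.DiGraph, path) -> None:
    """GraphViz DOT export of an overlap graph with node weights."""
    with open(path, "wt") as out:
        out.write("digraph adapters {\n")
        for node, data in graph.nodes(data=True):
            out.write(f'  "{node}" [label="{node}\\n{data["weight"]}"];\n')
        for u, v in graph.edges:
            out.write(f'  "{u}" -> "{v}";\n')
        out.write("}\n")
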