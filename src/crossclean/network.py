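"""Directed cross-contamination network between samples.

Nodes are samples; a directed edge ``source -> target`` carries the number of
transcripts in the target's assembly that were strictly called
``cross_contamination`` and attributed to the source. Node attributes record
each sample's transcript count, the share of its own transcripts that are
contaminants, and the total number of contamination events it caused.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx

from .seqio import SampleAssembly


@dataclass
class ContaminationGraph:
    graph: nx.DiGraph

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def edge_weight(self, source: str, target: str) -> int:
        return self.graph.edges[source, target]["weight"]

    def in_weight(self, sample: str) -> int:
        return sum(d["weight"] for _, _, d in self.graph.in_edges(sample, data=True))

    def to_tsv(self, path) -> None:
        with open(path, "wt") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['weight']}\n")

    def to_dot(self, path) -> None:
        # hand-rolled emitter: the DOT dialect here is a plain digraph with
        # label/weight attributes, no layout hints
        def q(s):
            return '"' + str(s).replace('"', r"\"") + '"'

        with open(path, "wt") as fh:
            fh.write("digraph contamination {\n")
            for n, d in sorted(self.graph.nodes(data=True)):
                fh.write(
                    f"  {q(n)} [transcript_count={d['transcript_count']}, "
                    f"contaminated_pct={d['contaminated_pct']:.4f}, "
                    f"out_degree_weight={d['out_degree_weight']}];\n"
                )
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(f"  {q(u)} -> {q(v)} [weight={d['weight']}, label={d['weight']}];\n")
            fh.write("}\n")

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_graph(
    calls: Mapping[str, Sequence],
    assemblies: Sequence[SampleAssembly],
) -> ContaminationGraph:
    """Tally strict cross-contamination calls into the directed sample graph."""
    g = nx.DiGraph()
    by_sample = {a.sample_id: a for a in assemblies}
    for sid, asm in by_sample.items():
        g.add_node(sid, transcript_count=len(asm))
    for sid, sample_calls in calls.items():
        n_contam = 0
        for c in sample_calls:
            if c.category != "cross_contamination":
                continue
            n_contam += 1
            src = c.source_sample
            if g.has_edge(src, sid):
                g.edges[src, sid]["weight"] += 1
            else:
                g.add_edge(src, sid, weight=1)
        total = g.nodes[sid]["transcript_count"] if sid in g.nodes else 0
        g.nodes[sid]["contaminated_pct"] = 100.0 * n_contam / total if total else 0.0
    for n in g.nodes:
        g.nodes[n].setdefault("contaminated_pct", 0.0)
        g.nodes[n]["out_degree_weight"] = sum(
            d["weight"] for _, _, d in g.out_edges(n, data=True)
        )
    return ContaminationGraph(g)


def prune_weak_links(graph: ContaminationGraph, frac: float = 0.02) -> ContaminationGraph:
    """Rendering view without edges weaker than ``frac`` x the strongest edge.

    The input graph is never mutated; with no edges (or frac = 0) the copy is
    the identity.
    """
    g = graph.graph.copy()
    if g.number_of_edges() == 0 or frac <= 0:
        return ContaminationGraph(g)
    wmax = max(d["weight"] for _, _, d in g.edges(data=True))
    cutoff = frac * wmax
    drop = [(u, v) for u, v, d in g.edges(data=True) if d["weight"] < cutoff]
    g.remove_edges_from(drop)
    return ContaminationGraph(g)
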