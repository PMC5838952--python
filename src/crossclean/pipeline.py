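"""End-to-end orchestration: suspects -> quantification -> classification -> graph."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .classify import CategoryCall, ClassifierParams, classify_all
from .network import ContaminationGraph, build_graph
from .quant import DEFAULT_K, DEFAULT_MIN_KMER_FRAC, ExpressionMatrix, quantify_all
from .seqio import ReadSet, SampleAssembly, build_metatranscriptome
from .suspects import SuspectTable, find_suspects


@dataclass
class DetectionResult:
    assemblies: list
    suspects: SuspectTable
    matrix: ExpressionMatrix
    calls: dict  # sample_id -> [CategoryCall]
    graph: ContaminationGraph


def run_detection(
    assemblies: Sequence[SampleAssembly],
    readsets: Mapping[str, ReadSet],
    min_identity: float = 95.0,
    min_length: int = 40,
    seed_len: int = 20,
    k: int = DEFAULT_K,
    min_kmer_frac: float = DEFAULT_MIN_KMER_FRAC,
    params: ClassifierParams | None = None,
) -> DetectionResult:
    """Run the full detection pipeline on registered samples and their reads."""
    assemblies = list(assemblies)
    meta = build_metatranscriptome(assemblies)  # validates >= 2 samples and ids
    suspects = find_suspects(
        assemblies, min_identity=min_identity, min_length=min_length, seed_len=seed_len
    )
    matrix = quantify_all(
        assemblies, readsets, suspects, k=k, min_kmer_frac=min_kmer_frac, meta=meta
    )
    calls = classify_all(matrix, suspects, assemblies, params)
    graph = build_graph(calls, assemblies)
    return DetectionResult(assemblies, suspects, matrix, calls, graph)
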