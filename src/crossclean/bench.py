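"""Simulation benchmark: pipeline sensitivity and false-positive rate.

For each (divergence, contamination strength, seed) cell the harness builds a
reference transcriptome and a divergent copy, injects unidirectional
contamination from the divergent sample into the reference, simulates
error-bearing paired-end reads for both samples, runs the full detection
pipeline, and scores strict cross-contamination calls against the injection
truth table. Dubious calls on true contaminants count as misses and are
reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ClassifierParams
from .errors import ConsistencyError
from .pipeline import DetectionResult, run_detection
from .simulate import (
    EffectiveContaminationCurve,
    inject_contamination,
    mutate_transcriptome,
    simulate_reads,
    simulate_reference,
)


@dataclass
class Score:
    sensitivity: float | None
    fpr: float
    tp: int
    fn: int
    fp: int
    tn: int
    dubious_on_contaminants: int
    lowcov_on_contaminants: int
    source_correct: int
    n_effective: int
    n_clean: int


@dataclass
class BenchResult:
    divergence: float
    n_mrnas: int
    seed: int
    score: Score
    detection: DetectionResult | None = field(default=None, repr=False)


def score_calls(calls: Mapping[str, Sequence], truth, all_samples: bool = True) -> Score:
    """Confusion statistics of the calls against one injection truth table.

    Sensitivity is computed over effective (kept) contaminants of the
    contaminated sample; the false-positive rate over every non-injected
    transcript (of all samples when ``all_samples``, else only the
    contaminated one).
    """
    if truth.target_sample not in calls:
        raise ConsistencyError(
            f"no calls for contaminated sample '{truth.target_sample}'"
        )
    effective = truth.effective_ids
    target_calls = {c.transcript_id: c for c in calls[truth.target_sample]}
    missing = effective - set(target_calls)
    if missing:
        raise ConsistencyError(
            f"truth-table transcript(s) absent from calls: {sorted(missing)[:3]}"
        )

    tp = fn = dub = low = src_ok = 0
    for tid in effective:
        c = target_calls[tid]
        if c.category == "cross_contamination":
            tp += 1
            if c.source_sample == truth.source_sample:
                src_ok += 1
        else:
            fn += 1
            if c.category == "dubious":
                dub += 1
            elif c.category == "low_coverage":
                low += 1

    fp = tn = 0
    samples = calls.keys() if all_samples else [truth.target_sample]
    for sid in samples:
        for c in calls[sid]:
            if sid == truth.target_sample and c.transcript_id in effective:
                continue
            if c.category == "cross_contamination":
                fp += 1
            else:
                tn += 1

    n_eff = tp + fn
    n_clean = fp + tn
    return Score(
        sensitivity=(tp / n_eff) if n_eff else None,
        fpr=(fp / n_clean) if n_clean else 0.0,
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
        dubious_on_contaminants=dub,
        lowcov_on_contaminants=low,
        source_correct=src_ok,
        n_effective=n_eff,
        n_clean=n_clean,
    )


def run_single(
    divergence: float,
    n_mrnas: int = 10_000,
    seed: int = 1,
    n_transcripts: int = 500,
    n_reads: int = 200_000,
    error_rate: float = 0.005,
    curve: EffectiveContaminationCurve | None = None,
    params: ClassifierParams | None = None,
    keep_detection: bool = False,
    **detect_kwargs,
) -> BenchResult:
    """One benchmark cell: simulate, contaminate, sequence, detect, score."""
    ss = np.random.SeedSequence(entropy=[int(seed), int(round(divergence * 10_000)), int(n_mrnas)])
    s_ref, s_mut, s_inj, s_r1, s_r2 = ss.spawn(5)

    ref, prof = simulate_reference(n_transcripts, seed=s_ref, sample_id="ref")
    div = mutate_transcriptome(ref, divergence, seed=s_mut, sample_id="div")
    contaminated, cprof, truth = inject_contamination(
        div, prof, ref, prof, n_mrnas=n_mrnas, curve=curve, seed=s_inj
    )
    reads_ref = simulate_reads(contaminated, cprof, n_reads=n_reads,
                               error_rate=error_rate, seed=s_r1)
    reads_div = simulate_reads(div, prof, n_reads=n_reads,
                               error_rate=error_rate, seed=s_r2)
    det = run_detection(
        [contaminated, div],
        {"ref": reads_ref, "div": reads_div},
        params=params,
        **detect_kwargs,
    )
    score = score_calls(det.calls, truth)
    return BenchResult(
        divergence=divergence,
        n_mrnas=n_mrnas,
        seed=seed,
        score=score,
        detection=det if keep_detection else None,
    )


def run_benchmark(
    divergences: Sequence[float] = (0.01, 0.03, 0.05, 0.10),
    n_mrnas_levels: Sequence[int] = (10_000,),
    seeds: Sequence[int] = (1, 2, 3),
    n_transcripts: int = 500,
    n_reads: int = 200_000,
    **kwargs,
) -> list:
    """The full desk-scale benchmark grid; returns a list of BenchResult."""
    results = []
    for div in divergences:
        for nm in n_mrnas_levels:
            for seed in seeds:
                results.append(
                    run_single(
                        div,
                        n_mrnas=nm,
                        seed=seed,
                        n_transcripts=n_transcripts,
                        n_reads=n_reads,
                        **kwargs,
                    )
                )
    return results


def results_to_frame(results: Sequence[BenchResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        s = r.score
        rows.append(
            {
                "divergence": r.divergence,
                "n_mrnas": r.n_mrnas,
                "seed": r.seed,
                "sensitivity": s.sensitivity,
                "fpr": s.fpr,
                "tp": s.tp,
                "fn": s.fn,
                "fp": s.fp,
                "tn": s.tn,
                "dubious_on_contaminants": s.dubious_on_contaminants,
                "lowcov_on_contaminants": s.lowcov_on_contaminants,
                "source_correct": s.source_correct,
                "n_effective": s.n_effective,
                "n_clean": s.n_clean,
            }
        )
    return pd.DataFrame(rows)


def plot_benchmark(results: Sequence[BenchResult], path) -> None:
    """Sensitivity and FPR against divergence, one line per contamination strength."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = results_to_frame(results)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for nm, grp in df.groupby("n_mrnas"):
        agg = grp.groupby("divergence")[["sensitivity", "fpr"]].mean()
        ax1.plot(agg.index * 100, agg["sensitivity"] * 100, "o-", label=f"{nm} mRNAs")
        ax2.plot(agg.index * 100, agg["fpr"] * 100, "o-", label=f"{nm} mRNAs")
    ax1.set_xlabel("divergence (%)")
    ax1.set_ylabel("sensitivity (%)")
    ax2.set_xlabel("divergence (%)")
    ax2.set_ylabel("false positive rate (%)")
    ax1.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
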