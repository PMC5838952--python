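"""Five-category classification of transcripts from their expression profile.

For a focal transcript with expression ``Nf`` in its own sample and ``Na`` the
maximum over alien samples, given a fold threshold X, a high-expression
threshold Y and a low-expression threshold Z (all TPM):

* ``low_coverage``        — expression < Z in every sample (no power to place it)
* ``over_expressed``      — expression > Y in at least ``overexp_min_samples``
  samples (focal included): rRNA-like or external contamination signature
* ``clean``               — Nf > X * Na
* ``cross_contamination`` — Nf < Na / X, attributed to the argmax alien sample
* ``dubious``             — everything in between, including exact boundary ties

The absolute-level categories take precedence over the ratio rules because
they mark transcripts whose focal/alien ratio cannot be trusted. Transcripts
never flagged as suspicious are clean by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ConfigurationError, ConsistencyError
from .quant import ExpressionMatrix
from .seqio import CATEGORIES, MetaTranscriptome, SampleAssembly
from .suspects import SuspectTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierParams:
    fold_x: float = 2.0  # fold-difference threshold X
    overexp_y: float = 300.0  # high-expression threshold Y, TPM
    lowcov_z: float = 0.2  # low-expression threshold Z, TPM
    overexp_min_samples: int = 3

    def __post_init__(self):
        if not self.fold_x > 1:
            raise ConfigurationError(f"fold_x must be > 1, got {self.fold_x}")
        if not self.overexp_y > self.lowcov_z > 0:
            raise ConfigurationError(
                f"need overexp_y > lowcov_z > 0, got Y={self.overexp_y} Z={self.lowcov_z}"
            )


@dataclass(frozen=True)
class CategoryCall:
    sample_id: str
    transcript_id: str
    category: str
    nf: float | None = None
    na: float | None = None
    source_sample: str | None = None
    hit_count: int = 0

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ConsistencyError(f"unknown category '{self.category}'")
        if (self.source_sample is not None) != (self.category == "cross_contamination"):
            raise ConsistencyError(
                "source_sample must be present exactly when category is "
                "cross_contamination"
            )


def classify_transcript(
    nf: float,
    alien_tpms: Mapping[str, float],
    params: ClassifierParams | None = None,
    sample_id: str = "",
    transcript_id: str = "",
    hit_count: int = 0,
) -> CategoryCall:
    """Apply the decision rule to one suspicious transcript."""
    params = params or ClassifierParams()
    if not alien_tpms:
        raise ConfigurationError("classification needs at least one alien sample")
    if nf < 0 or any(v < 0 for v in alien_tpms.values()):
        raise ConsistencyError("negative TPM")

    na = max(alien_tpms.values())
    category, source = None, None
    if nf < params.lowcov_z and all(v < params.lowcov_z for v in alien_tpms.values()):
        category = "low_coverage"
    elif (int(nf > params.overexp_y) + sum(v > params.overexp_y for v in alien_tpms.values())
          ) >= params.overexp_min_samples:
        category = "over_expressed"
    elif nf > params.fold_x * na:
        category = "clean"
    elif nf < na / params.fold_x:
        category = "cross_contamination"
        top = [s for s, v in alien_tpms.items() if v == na]
        source = min(top)
        if len(top) > 1:
            log.warning(
                "transcript '%s': tie between alien samples %s; attributing to '%s'",
                transcript_id, sorted(top), source,
            )
    else:
        category = "dubious"
    return CategoryCall(
        sample_id=sample_id,
        transcript_id=transcript_id,
        category=category,
        nf=nf,
        na=na,
        source_sample=source,
        hit_count=hit_count,
    )


def classify_all(
    matrix: ExpressionMatrix,
    suspects: SuspectTable,
    assemblies: Sequence[SampleAssembly],
    params: ClassifierParams | None = None,
) -> dict:
    """One :class:`CategoryCall` per transcript per sample.

    Suspicious transcripts go through the decision rule; everything else is
    clean with nf/na unset. Returns ``{sample_id: [CategoryCall, ...]}``
    preserving assembly order, so the partition property holds per sample.
    """
    params = params or ClassifierParams()
    assemblies = list(assemblies)
    sample_ids = [a.sample_id for a in assemblies]
    if params.overexp_min_samples > len(sample_ids):
        log.warning(
            "over_expressed needs > Y TPM in %d samples but only %d samples exist; "
            "the category can never fire",
            params.overexp_min_samples, len(sample_ids),
        )
    suspicious = suspects.namespaced_ids()
    missing = suspicious - set(matrix.values.index)
    if missing:
        raise ConsistencyError(
            f"suspicious transcript(s) missing from expression matrix: "
            f"{sorted(missing)[:3]}"
        )
    hit_counts = suspects.hit_counts()
    tpm = {nsid: row for nsid, row in zip(matrix.values.index,
                                          matrix.values.to_numpy())}
    col_of = {s: i for i, s in enumerate(matrix.values.columns)}

    calls: dict = {}
    for asm in assemblies:
        sid = asm.sample_id
        out = []
        for tid, _seq in asm:
            nsid = MetaTranscriptome.namespace(sid, tid)
            if nsid in suspicious:
                row = tpm[nsid]
                aliens = {s: float(row[col_of[s]]) for s in sample_ids if s != sid}
                out.append(
                    classify_transcript(
                        float(row[col_of[sid]]),
                        aliens,
                        params,
                        sample_id=sid,
                        transcript_id=tid,
                        hit_count=hit_counts.get((sid, tid), 0),
                    )
                )
            else:
                out.append(CategoryCall(sample_id=sid, transcript_id=tid, category="clean"))
        calls[sid] = out
    return calls


def calls_to_tsv(calls: Mapping[str, list], path) -> None:
    """Master report: one row per transcript per sample."""
    with open(path, "wt") as fh:
        fh.write("sample\ttranscript\tcategory\tnf\tna\tsource_sample\thit_count\n")
        for sid in sorted(calls):
            for c in calls[sid]:
                nf = "" if c.nf is None else f"{c.nf:.6g}"
                na = "" if c.na is None else f"{c.na:.6g}"
                fh.write(
                    f"{c.sample_id}\t{c.transcript_id}\t{c.category}\t{nf}\t{na}\t"
                    f"{c.source_sample or ''}\t{c.hit_count}\n"
                )
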