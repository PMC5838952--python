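"""Sequence I/O and the sample registry.

Reads per-sample assemblies (FASTA) and read sets (FASTQ, single or paired,
optionally gzipped), concatenates registered assemblies into a quantification
reference ("metatranscriptome") with collision-free namespaced ids, and writes
the five-way category partition of each assembly back out as FASTA.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ConfigurationError, ConsistencyError, DuplicateIdError, ParseError

#: The five output bins every transcript ends up in, in report order.
CATEGORIES = (
    "clean",
    "cross_contamination",
    "dubious",
    "over_expressed",
    "low_coverage",
)

#: Separator joining sample and transcript ids in the metatranscriptome.
NAMESPACE_SEP = "::"

# U (RNA) becomes T; IUPAC ambiguity codes collapse to N.
_SANITIZE = str.maketrans(
    "acgtnuUryswkmbdhvRYSWKMBDHV",
    "ACGTNTT" + "N" * 20,
)
_VALID_CHARS = frozenset("ACGTN")


def _open_text(path):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _clean_sequence(seq: str, record_id: str, path) -> str:
    seq = "".join(seq.split())  # drop internal whitespace from wrapped FASTA
    out = seq.translate(_SANITIZE)
    if not set(out) <= _VALID_CHARS:
        bad = sorted(set(out) - _VALID_CHARS)
        raise ParseError(
            f"{path}: record '{record_id}' contains non-nucleotide characters {bad}"
        )
    return out


@dataclass
class SampleAssembly:
    """One sample's assembled transcriptome: an ordered set of transcripts."""

    sample_id: str
    _ids: list = field(default_factory=list, repr=False)
    _seqs: list = field(default_factory=list, repr=False)
    _pos: dict = field(default_factory=dict, repr=False)

    def add(self, transcript_id: str, sequence: str) -> None:
        if NAMESPACE_SEP in transcript_id:
            raise DuplicateIdError(
                f"transcript id '{transcript_id}' contains the reserved "
                f"namespace separator '{NAMESPACE_SEP}'"
            )
        if transcript_id in self._pos:
            raise DuplicateIdError(
                f"duplicate transcript id '{transcript_id}' in sample "
                f"'{self.sample_id}'"
            )
        if not sequence:
            raise ParseError(
                f"empty sequence for transcript '{transcript_id}' in sample "
                f"'{self.sample_id}'"
            )
        self._pos[transcript_id] = len(self._ids)
        self._ids.append(transcript_id)
        self._seqs.append(sequence)

    @property
    def transcript_ids(self) -> Sequence[str]:
        return tuple(self._ids)

    def sequence(self, transcript_id: str) -> str:
        return self._seqs[self._pos[transcript_id]]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._pos

    def __len__(self) -> int:
        return len(self._ids)

    def __iter__(self) -> Iterator[tuple]:
        return iter(zip(self._ids, self._seqs))

    @classmethod
    def from_records(cls, sample_id: str, records: Iterable) -> "SampleAssembly":
        asm = cls(sample_id)
        for tid, seq in records:
            asm.add(tid, seq)
        return asm


def read_fasta(path, sample_id: str | None = None) -> SampleAssembly:
    """Parse a (possibly gzipped) FASTA file into a :class:`SampleAssembly`.

    Headers are truncated at the first whitespace to form transcript ids;
    sequences are uppercased, with IUPAC ambiguity codes collapsed to N.
    """
    if sample_id is None:
        name = Path(os.fspath(path)).name
        for suf in (".gz", ".fasta", ".fa", ".fna"):
            if name.endswith(suf):
                name = name[: -len(suf)]
        sample_id = name
    asm = SampleAssembly(sample_id)
    with _open_text(path) as fh:
        first = fh.read(1)
        if first == "":
            raise ParseError(f"{path}: no records")
        if first != ">":
            raise ParseError(f"{path}: line 1: expected FASTA header starting with '>'")
        fh.seek(0)
        n = 0
        for title, seq in SimpleFastaParser(fh):
            tid = title.split()[0] if title.split() else ""
            if not tid:
                raise ParseError(f"{path}: record {n + 1} has an empty header")
            asm.add(tid, _clean_sequence(seq, tid, path))
            n += 1
    if n == 0:
        raise ParseError(f"{path}: no records")
    return asm


def write_fasta(records: Iterable, path, width: int = 60) -> int:
    """Write ``(id, sequence)`` records as wrapped FASTA; returns record count."""
    n = 0
    opener = gzip.open if os.fspath(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for tid, seq in records:
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            n += 1
    return n


class ReadSet:
    """A sample's sequencing reads, single- or paired-end.

    File-backed read sets stream lazily and are re-iterable; the simulator
    produces in-memory read sets. :meth:`units` yields one tuple of read
    sequences per sequencing unit — ``(seq,)`` for single-end, ``(seq1, seq2)``
    for a mate pair — which is the granularity the quantifier assigns at.
    """

    def __init__(self, sample_id: str, layout: str, units=None, paths=None):
        if layout not in ("single", "paired"):
            raise ConfigurationError(f"unknown layout '{layout}'")
        self.sample_id = sample_id
        self.layout = layout
        self._units = units
        self._paths = paths

    @classmethod
    def from_fastq(cls, path, mate_path=None, sample_id: str | None = None) -> "ReadSet":
        if sample_id is None:
            sample_id = Path(os.fspath(path)).name.split(".")[0]
        layout = "paired" if mate_path is not None else "single"
        return cls(sample_id, layout, paths=(path, mate_path))

    @classmethod
    def in_memory(cls, sample_id: str, units, layout: str | None = None) -> "ReadSet":
        units = list(units)
        if layout is None:
            layout = "paired" if (units and len(units[0]) == 2) else "single"
        return cls(sample_id, layout, units=units)

    def units(self) -> Iterator[tuple]:
        if self._units is not None:
            yield from self._units
            return
        path, mate = self._paths
        if mate is None:
            with _open_text(path) as fh:
                for _tid, seq, _q in _fastq_records(fh, path):
                    yield (seq.upper(),)
        else:
            with _open_text(path) as fh1, _open_text(mate) as fh2:
                it1 = _fastq_records(fh1, path)
                it2 = _fastq_records(fh2, mate)
                while True:
                    r1 = next(it1, None)
                    r2 = next(it2, None)
                    if r1 is None and r2 is None:
                        return
                    if r1 is None or r2 is None:
                        raise ParseError(
                            f"mate count mismatch between {path} and {mate}"
                        )
                    yield (r1[1].upper(), r2[1].upper())

    def records(self) -> Iterator[tuple]:
        """Yield ``(read_id, sequence, quality)`` triples (mates interleaved)."""
        if self._units is not None:
            for i, unit in enumerate(self._units):
                for m, seq in enumerate(unit, start=1):
                    suffix = f"/{m}" if len(unit) > 1 else ""
                    yield (f"{self.sample_id}_r{i}{suffix}", seq, "I" * len(seq))
            return
        path, mate = self._paths
        if mate is None:
            with _open_text(path) as fh:
                yield from _fastq_records(fh, path)
        else:
            for unit_records in self._paired_records():
                yield from unit_records

    def _paired_records(self):
        path, mate = self._paths
        with _open_text(path) as fh1, _open_text(mate) as fh2:
            it1 = _fastq_records(fh1, path)
            it2 = _fastq_records(fh2, mate)
            while True:
                r1 = next(it1, None)
                r2 = next(it2, None)
                if r1 is None and r2 is None:
                    return
                if r1 is None or r2 is None:
                    raise ParseError(f"mate count mismatch between {path} and {mate}")
                yield (r1, r2)

    def n_units(self) -> int:
        if self._units is not None:
            return len(self._units)
        return sum(1 for _ in self.units())


def _fastq_records(handle, path):
    try:
        for tid, seq, qual in FastqGeneralIterator(handle):
            yield tid, seq, qual
    except ValueError as exc:  # truncated or malformed record
        raise ParseError(f"{path}: {exc}") from exc


def read_fastq(path, mate_path=None, sample_id: str | None = None) -> ReadSet:
    """Open a (pair of) FASTQ file(s) as a streaming :class:`ReadSet`."""
    return ReadSet.from_fastq(path, mate_path, sample_id)


def write_fastq(readset: ReadSet, path, mate_path=None) -> int:
    """Write a read set to FASTQ (gzipped if the suffix says so).

    Paired read sets require ``mate_path``; returns the number of units written.
    """
    if readset.layout == "paired" and mate_path is None:
        raise ConfigurationError("paired read set needs a mate_path")

    def _writer(p):
        return gzip.open(p, "wt") if os.fspath(p).endswith(".gz") else open(p, "wt")

    n = 0
    out2 = None
    with _writer(path) as out1:
        if mate_path is not None:
            out2 = _writer(mate_path)
        try:
            for i, unit in enumerate(readset.units()):
                rid = f"{readset.sample_id}_r{i}"
                out1.write(f"@{rid}/1\n{unit[0]}\n+\n{'I' * len(unit[0])}\n")
                if len(unit) > 1:
                    out2.write(f"@{rid}/2\n{unit[1]}\n+\n{'I' * len(unit[1])}\n")
                n += 1
        finally:
            if out2 is not None:
                out2.close()
    return n


@dataclass
class MetaTranscriptome:
    """Every transcript of every registered sample under a namespaced id."""

    entry_ids: list
    seqs: list
    samples: list  # sample id per entry
    lengths: np.ndarray

    def __post_init__(self):
        self._pos = {e: i for i, e in enumerate(self.entry_ids)}

    def __len__(self) -> int:
        return len(self.entry_ids)

    def index_of(self, entry_id: str) -> int:
        return self._pos[entry_id]

    def __contains__(self, entry_id: str) -> bool:
        return entry_id in self._pos

    @staticmethod
    def namespace(sample_id: str, transcript_id: str) -> str:
        return f"{sample_id}{NAMESPACE_SEP}{transcript_id}"

    @staticmethod
    def split(entry_id: str) -> tuple:
        sample, _, tid = entry_id.partition(NAMESPACE_SEP)
        return sample, tid


def build_metatranscriptome(assemblies: Sequence[SampleAssembly]) -> MetaTranscriptome:
    """Concatenate >= 2 sample assemblies into one quantification reference."""
    assemblies = list(assemblies)
    if len(assemblies) < 2:
        raise ConfigurationError(
            "cross-contamination detection needs at least 2 samples, got "
            f"{len(assemblies)}"
        )
    seen = set()
    entry_ids, seqs, samples, lengths = [], [], [], []
    for asm in assemblies:
        if asm.sample_id in seen:
            raise DuplicateIdError(f"duplicate sample id '{asm.sample_id}'")
        if NAMESPACE_SEP in asm.sample_id:
            raise DuplicateIdError(
                f"sample id '{asm.sample_id}' contains the reserved separator "
                f"'{NAMESPACE_SEP}'"
            )
        seen.add(asm.sample_id)
        for tid, seq in asm:
            entry_ids.append(MetaTranscriptome.namespace(asm.sample_id, tid))
            seqs.append(seq)
            samples.append(asm.sample_id)
            lengths.append(len(seq))
    return MetaTranscriptome(entry_ids, seqs, samples, np.asarray(lengths, dtype=np.int64))


def write_category_fastas(
    assembly: SampleAssembly,
    calls,
    out_dir,
    prefix: str | None = None,
) -> dict:
    """Partition one assembly into the five category FASTA files.

    ``calls`` is either a mapping ``transcript_id -> category`` or an iterable
    of objects with ``transcript_id``/``category`` attributes. Every transcript
    must receive exactly one call; the five files (one per category, possibly
    empty) partition the input byte-for-byte.
    """
    if isinstance(calls, Mapping):
        by_tid = dict(calls)
    else:
        by_tid = {}
        for call in calls:
            if call.transcript_id in by_tid:
                raise ConsistencyError(
                    f"multiple calls for transcript '{call.transcript_id}'"
                )
            by_tid[call.transcript_id] = call.category
    missing = [tid for tid in assembly.transcript_ids if tid not in by_tid]
    if missing:
        raise ConsistencyError(
            f"sample '{assembly.sample_id}': {len(missing)} transcript(s) "
            f"without a category call (first: '{missing[0]}')"
        )
    unknown = set(by_tid.values()) - set(CATEGORIES)
    if unknown:
        raise ConsistencyError(f"unknown categories: {sorted(unknown)}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or assembly.sample_id
    buckets = {cat: [] for cat in CATEGORIES}
    for tid, seq in assembly:
        buckets[by_tid[tid]].append((tid, seq))
    paths = {}
    for cat in CATEGORIES:
        path = out_dir / f"{prefix}.{cat}.fasta"
        write_fasta(buckets[cat], path)
        paths[cat] = path
    return paths
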