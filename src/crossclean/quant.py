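"""Expression quantification of suspicious transcripts by k-mer pseudo-alignment.

Every sample's reads are assigned against the full metatranscriptome: a read
(or a mate pair, whose k-mers are pooled) goes to the entry/entries compatible
with the largest number of its k-mers, provided that number reaches
``min_kmer_frac`` of the read's valid k-mers; ties are split equally. TPM is
computed per sample over the *full* metatranscriptome denominator so that
values are comparable across samples:

    TPM_t = (count_t / length_t) / sum_u (count_u / length_u) * 1e6
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import islice
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._kmers import canonical_kmers, encode, ranges_concat
from .errors import ConfigurationError, ConsistencyError
from .seqio import (
    MetaTranscriptome,
    ReadSet,
    SampleAssembly,
    build_metatranscriptome,
)
from .suspects import SuspectTable

log = logging.getLogger(__name__)

DEFAULT_K = 31
DEFAULT_MIN_KMER_FRAC = 0.7


@dataclass
class KmerIndex:
    """Sorted canonical k-mer table with CSR lists of containing entries."""

    k: int
    kmers: np.ndarray  # int64, sorted unique canonical k-mer values
    offsets: np.ndarray  # int64, len(kmers)+1, CSR into `entries`
    entries: np.ndarray  # int32 entry indices
    n_entries: int
    entry_ids: list

    def entries_of(self, kmer_value: int) -> np.ndarray:
        i = int(np.searchsorted(self.kmers, kmer_value))
        if i >= self.kmers.size or self.kmers[i] != kmer_value:
            return np.zeros(0, dtype=np.int32)
        return self.entries[self.offsets[i] : self.offsets[i + 1]]

    def __len__(self) -> int:
        return int(self.kmers.size)


def build_kmer_index(meta: MetaTranscriptome, k: int = DEFAULT_K) -> KmerIndex:
    """Index every N-free k-window of every entry under its canonical form."""
    if k % 2 == 0:
        raise ConfigurationError(f"k must be odd for unambiguous canonical form, got {k}")
    if not 15 <= k <= 31:
        raise ConfigurationError(f"k must be in [15, 31], got {k}")
    all_k, all_e = [], []
    n_short = 0
    for ei, seq in enumerate(meta.seqs):
        if len(seq) < k:
            n_short += 1
            continue
        canon, valid = canonical_kmers(encode(seq), k)
        vals = np.unique(canon[valid])
        if vals.size:
            all_k.append(vals)
            all_e.append(np.full(vals.size, ei, dtype=np.int32))
    if n_short:
        log.warning("%d transcript(s) shorter than k=%d indexed as zero k-mers", n_short, k)
    if not all_k:
        kk = np.zeros(0, dtype=np.int64)
        return KmerIndex(k, kk, np.zeros(1, dtype=np.int64), np.zeros(0, dtype=np.int32),
                         len(meta), list(meta.entry_ids))
    kk = np.concatenate(all_k)
    ee = np.concatenate(all_e)
    order = np.lexsort((ee, kk))
    kk, ee = kk[order], ee[order]
    uniq, counts = np.unique(kk, return_counts=True)
    offsets = np.concatenate(([0], np.cumsum(counts)))
    return KmerIndex(k, uniq, offsets.astype(np.int64), ee, len(meta), list(meta.entry_ids))


def _batched(iterable, size):
    it = iter(iterable)
    while True:
        chunk = list(islice(it, size))
        if not chunk:
            return
        yield chunk


@dataclass
class AssignmentStats:
    n_units: int = 0
    n_assigned: int = 0
    n_unmapped: int = 0


def assign_reads(
    reads: ReadSet,
    index: KmerIndex,
    min_kmer_frac: float = DEFAULT_MIN_KMER_FRAC,
    chunk_units: int = 20000,
):
    """Fractional per-entry read counts from k-mer compatibility.

    Returns ``(counts, stats)`` where ``counts`` is a float64 array over the
    index's entries. A unit (read or pooled mate pair) is assigned to the
    entries hit by its maximal number of k-mers when that maximum reaches
    ``min_kmer_frac`` x (valid k-mers in the unit); ties split equally.
    """
    k = index.k
    counts = np.zeros(index.n_entries, dtype=np.float64)
    stats = AssignmentStats()
    for chunk in _batched(reads.units(), chunk_units):
        unit_strs = ["N".join(u) for u in chunk]
        joined = "N".join(unit_strs)
        codes = encode(joined)
        n_units = len(unit_strs)
        stats.n_units += n_units

        ulens = np.array([len(s) for s in unit_strs], dtype=np.int64)
        starts = np.concatenate(([0], np.cumsum(ulens[:-1] + 1)))
        n_win = codes.size - k + 1
        if n_win <= 0:
            stats.n_unmapped += n_units
            continue
        # window start position -> owning unit (boundary windows are invalid anyway)
        bounds_ = np.clip(np.concatenate((starts, [codes.size])), 0, n_win)
        spans = np.diff(bounds_)
        win_unit = np.repeat(np.arange(n_units), spans)

        canon, valid = canonical_kmers(codes, k)
        v_unit = win_unit[valid]
        v_kmer = canon[valid]
        valid_per_unit = np.bincount(v_unit, minlength=n_units)

        pos = np.searchsorted(index.kmers, v_kmer)
        ok = pos < index.kmers.size
        ok[ok] &= index.kmers[pos[ok]] == v_kmer[ok]
        h_unit = v_unit[ok]
        h_pos = pos[ok]
        if h_unit.size == 0:
            stats.n_unmapped += n_units
            continue

        lens = index.offsets[h_pos + 1] - index.offsets[h_pos]
        ent = index.entries[ranges_concat(index.offsets[h_pos], lens)]
        unit_rep = np.repeat(h_unit, lens)

        key = unit_rep.astype(np.int64) * index.n_entries + ent
        ukey, kcounts = np.unique(key, return_counts=True)
        u = ukey // index.n_entries
        e = (ukey % index.n_entries).astype(np.int64)

        bounds = np.flatnonzero(np.concatenate(([True], u[1:] != u[:-1])))
        group_sizes = np.diff(np.concatenate((bounds, [u.size])))
        gmax = np.maximum.reduceat(kcounts, bounds)
        g_unit = u[bounds]
        thr = min_kmer_frac * valid_per_unit[g_unit]
        g_ok = gmax >= thr - 1e-9

        row_group = np.repeat(np.arange(bounds.size), group_sizes)
        winner = (kcounts == gmax[row_group]) & g_ok[row_group]
        ties = np.zeros(bounds.size, dtype=np.int64)
        np.add.at(ties, row_group[winner], 1)
        frac = 1.0 / ties[row_group[winner]]
        np.add.at(counts, e[winner], frac)

        n_assigned = int(np.count_nonzero(g_ok))
        stats.n_assigned += n_assigned
        stats.n_unmapped += n_units - n_assigned
    return counts, stats


def compute_tpm(counts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Length-normalised counts scaled to sum to one million per sample."""
    counts = np.asarray(counts, dtype=np.float64)
    lengths = np.asarray(lengths, dtype=np.float64)
    if (counts < 0).any():
        raise ConsistencyError("negative read count")
    if (lengths <= 0).any():
        raise ConsistencyError("non-positive transcript length")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        return np.zeros_like(counts)
    return rates / total * 1e6


@dataclass
class ExpressionMatrix:
    """TPM of every suspicious transcript in every sample's read set.

    ``values``/``raw_counts`` are restricted to suspicious transcripts (rows,
    namespaced ids) by samples (columns); ``full_tpm`` keeps the complete
    per-sample columns whose sums are one million whenever any read mapped.
    """

    values: pd.DataFrame
    raw_counts: pd.DataFrame
    lengths: pd.Series
    full_tpm: pd.DataFrame = None
    stats: dict = field(default_factory=dict)

    def nf(self, sample_id: str, transcript_id: str) -> float:
        nsid = MetaTranscriptome.namespace(sample_id, transcript_id)
        return float(self.values.at[nsid, sample_id])

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="transcript")


def quantify_all(
    assemblies: Sequence[SampleAssembly],
    readsets: Mapping[str, ReadSet],
    suspects: SuspectTable,
    k: int = DEFAULT_K,
    min_kmer_frac: float = DEFAULT_MIN_KMER_FRAC,
    meta: MetaTranscriptome | None = None,
    index: KmerIndex | None = None,
) -> ExpressionMatrix:
    """TPM matrix of all suspicious transcripts across all samples."""
    assemblies = list(assemblies)
    if meta is None:
        meta = build_metatranscriptome(assemblies)
    sample_ids = [a.sample_id for a in assemblies]
    missing = [s for s in sample_ids if s not in readsets]
    if missing:
        raise ConfigurationError(f"no read set for sample(s): {missing}")
    if index is None:
        index = build_kmer_index(meta, k)

    suspicious = sorted(suspects.namespaced_ids())
    absent = [nsid for nsid in suspicious if nsid not in meta]
    if absent:
        raise ConsistencyError(
            f"suspicious transcript(s) missing from metatranscriptome: {absent[:3]}"
        )

    tpm_cols, count_cols, stats = {}, {}, {}
    for sid in sample_ids:
        counts, st = assign_reads(readsets[sid], index, min_kmer_frac)
        if st.n_assigned == 0:
            log.warning("sample '%s': zero assigned reads; TPM column is all zeros", sid)
        tpm_cols[sid] = compute_tpm(counts, meta.lengths)
        count_cols[sid] = counts
        stats[sid] = st

    full_tpm = pd.DataFrame(tpm_cols, index=list(meta.entry_ids))
    full_counts = pd.DataFrame(count_cols, index=list(meta.entry_ids))
    lengths = pd.Series(meta.lengths, index=list(meta.entry_ids), name="length")
    return ExpressionMatrix(
        values=full_tpm.loc[suspicious].copy(),
        raw_counts=full_counts.loc[suspicious].copy(),
        lengths=lengths,
        full_tpm=full_tpm,
        stats=stats,
    )
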