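"""Synthetic multi-sample experiments with full contamination ground truth.

The generator emulates the benchmark conditions of a cross-contamination
study between closely related species: a reference transcriptome with
log-normal lengths and abundances, divergent copies produced by i.i.d.
nucleotide substitution, physical mRNA transfer modelled as a multinomial
draw from a virtual pool of one million molecules, copy-number-dependent
survival through sequencing/assembly, and uniform-error paired-end reads
whose per-transcript counts follow the abundance profile.

Contaminant transcripts are injected verbatim into the recipient assembly
(with TPM equal to the number of transferred copies, pool-to-pool); whether a
transferred species would have survived de novo assembly is emulated by the
effective-contamination probability curve rather than by running an
assembler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._kmers import decode
from .errors import ConfigurationError
from .seqio import ReadSet, SampleAssembly

log = logging.getLogger(__name__)

POOL_SIZE = 1_000_000


@dataclass
class AbundanceProfile:
    """Per-transcript TPM of one sample, summing to the virtual pool size."""

    tpm: np.ndarray
    pool_size: int = POOL_SIZE

    def __post_init__(self):
        self.tpm = np.asarray(self.tpm, dtype=np.float64)
        if (self.tpm < 0).any():
            raise ConfigurationError("negative TPM in abundance profile")

    def normalised(self) -> "AbundanceProfile":
        total = self.tpm.sum()
        if total == 0:
            raise ConfigurationError("all-zero abundance profile")
        return AbundanceProfile(self.tpm / total * self.pool_size, self.pool_size)

    @property
    def fractions(self) -> np.ndarray:
        return self.tpm / self.tpm.sum()


@dataclass
class EffectiveContaminationCurve:
    """Probability that a transferred mRNA species survives into the
    recipient assembly, as a function of transferred copy number.

    Anchored at ``p_single`` for one copy and ``p_many`` beyond
    ``saturation_copies``; log-linear in copy number in between, hence
    non-decreasing. A user table ``{copies: probability}`` overrides the
    parametric form (values above the largest key saturate).
    """

    p_single: float = 0.483
    p_many: float = 0.933
    saturation_copies: int = 10
    table: Mapping[int, float] | None = None

    def __call__(self, copies):
        copies = np.asarray(copies, dtype=np.float64)
        if self.table is not None:
            keys = np.array(sorted(self.table), dtype=np.float64)
            vals = np.array([self.table[int(k)] for k in keys])
            idx = np.clip(np.searchsorted(keys, copies, side="right") - 1, 0, keys.size - 1)
            return vals[idx]
        c = np.clip(copies, 1.0, float(self.saturation_copies))
        frac = np.log(c) / np.log(float(self.saturation_copies))
        return self.p_single + (self.p_many - self.p_single) * frac


@dataclass
class ContaminationTruth:
    """Ground truth of one injection: every sampled species, kept or dropped."""

    source_sample: str
    target_sample: str
    table: pd.DataFrame  # source_transcript, target_transcript, copies, kept, tpm
    n_mrnas: int

    @property
    def effective_ids(self) -> set:
        """Transcript ids present in the contaminated assembly."""
        kept = self.table.loc[self.table["kept"].astype(bool)]
        return set(kept["target_transcript"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


_LEN_DTYPE = np.int64


def simulate_reference(
    n_transcripts: int = 500,
    length_median: float = 1000.0,
    length_sigma: float = 0.45,
    min_length: int = 200,
    tpm_sigma: float = 1.5,
    seed: int | None = None,
    sample_id: str = "ref",
):
    """Random reference transcriptome plus a log-normal abundance profile.

    Lengths are log-normal (median ``length_median`` nt, floor ``min_length``);
    TPM values are log-normal with ``tpm_sigma`` on the natural-log scale,
    normalised to one million. Fully reproducible from ``seed``.
    """
    if n_transcripts < 2:
        raise ConfigurationError("need at least 2 transcripts")
    if length_median <= 0 or length_sigma <= 0 or tpm_sigma <= 0:
        raise ConfigurationError("degenerate length/abundance parameters")
    rng = np.random.default_rng(seed)
    lengths = np.maximum(
        np.round(rng.lognormal(np.log(length_median), length_sigma, n_transcripts)),
        min_length,
    ).astype(_LEN_DTYPE)
    total = int(lengths.sum())
    codes = rng.integers(0, 4, size=total, dtype=np.uint8)
    bounds = np.concatenate(([0], np.cumsum(lengths)))
    asm = SampleAssembly(sample_id)
    width = len(str(n_transcripts))
    for i in range(n_transcripts):
        asm.add(f"t{i:0{width}d}", decode(codes[bounds[i] : bounds[i + 1]]))
    tpm = rng.lognormal(0.0, tpm_sigma, n_transcripts)
    profile = AbundanceProfile(tpm).normalised()
    return asm, profile


def mutate_transcriptome(
    ref: SampleAssembly,
    divergence: float,
    seed: int | None = None,
    sample_id: str | None = None,
) -> SampleAssembly:
    """Divergent copy of a transcriptome: i.i.d. substitutions, no indels.

    Each site mutates with probability ``divergence`` to one of the three
    alternative bases, chosen uniformly. The abundance profile of the copy is
    the reference's, unchanged; lengths and transcript ids are preserved.
    """
    if not 0 <= divergence <= 0.5:
        raise ConfigurationError(f"divergence must be in [0, 0.5], got {divergence}")
    rng = np.random.default_rng(seed)
    out = SampleAssembly(sample_id or f"{ref.sample_id}_div")
    from ._kmers import encode  # local to avoid a cycle at import time

    for tid, seq in ref:
        codes = encode(seq).copy()
        mask = rng.random(codes.size) < divergence
        mask &= codes < 4  # N sites stay N
        n_mut = int(mask.sum())
        if n_mut:
            codes[mask] = (codes[mask] + rng.integers(1, 4, n_mut, dtype=np.uint8)) % 4
        out.add(tid, decode(codes))
    return out


def inject_contamination(
    source: SampleAssembly,
    source_profile: AbundanceProfile,
    target: SampleAssembly,
    target_profile: AbundanceProfile,
    n_mrnas: int = 10_000,
    curve: EffectiveContaminationCurve | None = None,
    seed: int | None = None,
):
    """Transfer ``n_mrnas`` molecules from the source pool into the target.

    Molecules are drawn multinomially from the source abundance profile; each
    sampled species survives independently with probability ``curve(copies)``.
    Survivors are appended verbatim to the target assembly under namespace-free
    ids ``contam|<source>|<tid>`` with contaminant TPM equal to the transferred
    copy count (pool-to-pool); the combined profile is re-normalised to one
    million. Inputs are never mutated. Returns
    ``(contaminated_assembly, contaminated_profile, truth)``.
    """
    if source.sample_id == target.sample_id:
        raise ConfigurationError("source and target samples must differ")
    if n_mrnas >= source_profile.pool_size:
        raise ConfigurationError("n_mrnas must be smaller than the mRNA pool")
    curve = curve or EffectiveContaminationCurve()
    rng = np.random.default_rng(seed)

    src_ids = list(source.transcript_ids)
    probs = source_profile.fractions
    copies = rng.multinomial(n_mrnas, probs)
    sampled = np.flatnonzero(copies)
    keep = rng.random(sampled.size) < curve(copies[sampled])

    contaminated = SampleAssembly.from_records(target.sample_id, iter(target))
    rows = []
    kept_tpm = []
    for j, si in enumerate(sampled):
        tid = src_ids[si]
        new_id = f"contam|{source.sample_id}|{tid}"
        rows.append(
            {
                "source_sample": source.sample_id,
                "source_transcript": tid,
                "target_transcript": new_id,
                "copies": int(copies[si]),
                "kept": bool(keep[j]),
                "tpm": float(copies[si]),
            }
        )
        if keep[j]:
            contaminated.add(new_id, source.sequence(tid))
            kept_tpm.append(float(copies[si]))

    table = pd.DataFrame(
        rows,
        columns=["source_sample", "source_transcript", "target_transcript",
                 "copies", "kept", "tpm"],
    )
    combined = AbundanceProfile(
        np.concatenate((target_profile.tpm, np.asarray(kept_tpm))),
        target_profile.pool_size,
    ).normalised()
    truth = ContaminationTruth(
        source_sample=source.sample_id,
        target_sample=target.sample_id,
        table=table,
        n_mrnas=n_mrnas,
    )
    return contaminated, combined, truth


def simulate_reads(
    assembly: SampleAssembly,
    profile: AbundanceProfile,
    n_reads: int = 200_000,
    read_len: int = 100,
    fragment_mean: float = 250.0,
    fragment_sd: float = 25.0,
    error_rate: float = 0.005,
    seed: int | None = None,
    paired: bool = True,
    chunk: int = 50_000,
) -> ReadSet:
    """Uniform-error (substitution-only) read simulation from an abundance profile.

    ``n_reads`` fragments are allotted to transcripts multinomially on
    TPM / 1e6; fragment lengths are normal(mean, sd) truncated to
    [read_len, transcript length] (transcripts shorter than the fragment are
    covered end to end, logged); every base is substituted with probability
    ``error_rate`` uniformly to one of the three alternatives. Mate 2 is the
    reverse complement of the fragment's 3' end; quality strings are constant.
    """
    if not 0 <= error_rate <= 0.25:
        raise ConfigurationError(f"error_rate must be in [0, 0.25], got {error_rate}")
    lengths = np.array([len(seq) for _tid, seq in assembly], dtype=np.int64)
    if len(lengths) != profile.tpm.size:
        raise ConfigurationError("assembly and abundance profile sizes differ")
    if (lengths < read_len).any():
        raise ConfigurationError(
            f"all transcripts must be at least read_len={read_len} nt long"
        )
    rng = np.random.default_rng(seed)

    from ._kmers import encode

    flat = np.concatenate([encode(seq) for _tid, seq in assembly])
    bounds = np.concatenate(([0], np.cumsum(lengths)))

    per_t = rng.multinomial(n_reads, profile.fractions)
    t_idx = np.repeat(np.arange(lengths.size), per_t)
    tlen = lengths[t_idx]

    frag = np.round(rng.normal(fragment_mean, fragment_sd, t_idx.size)).astype(np.int64)
    frag = np.maximum(frag, read_len)
    n_trunc = int((frag > tlen).sum())
    if n_trunc:
        log.info("%d fragment(s) truncated to transcript length", n_trunc)
    frag = np.minimum(frag, tlen)
    start = np.floor(rng.random(t_idx.size) * (tlen - frag + 1)).astype(np.int64)
    g1 = bounds[t_idx] + start
    g2_end = g1 + frag

    qual = "I" * read_len
    units = []
    offs = np.arange(read_len, dtype=np.int64)
    for lo in range(0, t_idx.size, chunk):
        hi = min(lo + chunk, t_idx.size)
        m1 = flat[g1[lo:hi, None] + offs[None, :]]
        mats = [m1]
        if paired:
            m2 = flat[(g2_end[lo:hi, None] - read_len) + offs[None, :]]
            m2 = 3 - m2[:, ::-1]  # reverse complement (no N in simulated data)
            mats.append(np.ascontiguousarray(m2))
        for mat in mats:
            if error_rate > 0:
                mask = rng.random(mat.shape) < error_rate
                n_err = int(mask.sum())
                if n_err:
                    mat[mask] = (mat[mask] + rng.integers(1, 4, n_err, dtype=np.uint8)) % 4
        dec = [_decode_rows(mat) for mat in mats]
        if paired:
            units.extend(zip(dec[0], dec[1]))
        else:
            units.extend((s,) for s in dec[0])
    rs = ReadSet.in_memory(assembly.sample_id, units,
                           layout="paired" if paired else "single")
    rs.quality = qual
    return rs


_DECODE_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _decode_rows(mat: np.ndarray) -> list:
    raw = _DECODE_LUT[mat].tobytes()
    w = mat.shape[1]
    return [raw[i : i + w].decode("ascii") for i in range(0, len(raw), w)]
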