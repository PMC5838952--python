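"""Cross-sample suspicious-pair detection.

Two transcripts from two different samples are "suspicious" when they share a
local nucleotide match with identity above ``min_identity`` percent over more
than ``min_length`` bases (strict inequalities on both). Candidate pairs are
anchored by shared exact ``seed_len``-mers on either strand; every anchored
diagonal is then scanned exhaustively for a qualifying ungapped window, so a
reported hit always carries a verified identity and length. Like
maximal-scoring segment pairs, qualifying windows must begin and end on
matched columns — an alignment terminating in mismatches would always score
higher trimmed. Within-sample
matches (isoforms, paralogs) are never reported — they are not evidence of
contamination.

``sw_oracle`` is an independent validation oracle: an exhaustive ungapped
window search over *all* diagonals (no seeding) combined with an optimal
gapped local alignment (match +1, mismatch -2, gap -3). It is quadratic and
meant for property tests on short sequences, not for production scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._kmers import encode, kmer_values, revcomp
from .errors import ConfigurationError
from .seqio import MetaTranscriptome, SampleAssembly

_TOL = 1e-9
_NEG = -1e9


@dataclass(frozen=True)
class SuspectHit:
    """A cross-sample pair of transcripts with a qualifying local match."""

    query: tuple  # (sample_id, transcript_id)
    subject: tuple
    identity_pct: float
    match_len: int
    strand: str  # '+' or '-': subject strand relative to query
    query_start: int = 0  # 0-based, half-open, forward coords of query
    query_end: int = 0
    subject_start: int = 0  # forward coords of subject
    subject_end: int = 0


@dataclass
class SuspectTable:
    hits: list = field(default_factory=list)

    @property
    def suspicious_ids(self) -> set:
        ids = set()
        for h in self.hits:
            ids.add(h.query)
            ids.add(h.subject)
        return ids

    def namespaced_ids(self) -> set:
        return {MetaTranscriptome.namespace(s, t) for s, t in self.suspicious_ids}

    def hit_counts(self) -> dict:
        counts: dict = {}
        for h in self.hits:
            for key in (h.query, h.subject):
                counts[key] = counts.get(key, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.hits)

    def to_tsv(self, path) -> None:
        cols = (
            "query_sample query_transcript subject_sample subject_transcript "
            "identity_pct match_len strand query_start query_end "
            "subject_start subject_end"
        ).split()
        with open(path, "wt") as fh:
            fh.write("#" + "\t".join(cols) + "\n")
            for h in sorted(self.hits, key=lambda h: (h.query, h.subject)):
                fh.write(
                    "\t".join(
                        map(
                            str,
                            (
                                h.query[0],
                                h.query[1],
                                h.subject[0],
                                h.subject[1],
                                f"{h.identity_pct:.2f}",
                                h.match_len,
                                h.strand,
                                h.query_start,
                                h.query_end,
                                h.subject_start,
                                h.subject_end,
                            ),
                        )
                    )
                    + "\n"
                )


def _best_window(match: np.ndarray, min_identity: float, min_length: int):
    """Best strict-threshold window in a boolean match vector.

    Maximises the excess score ``100*matches - min_identity*len`` over windows
    longer than ``min_length`` whose first and last columns are matches (a
    local alignment never terminates in a mismatch — trimming it would score
    higher). A positive optimum certifies ``identity > min_identity`` over
    ``len > min_length``. Returns ``(start, end, n_matches)`` or None.
    """
    w = min_length + 1
    n = match.size
    if n < w:
        return None
    score = np.where(match, 100.0 - min_identity, -min_identity)
    pre = np.concatenate(([0.0], np.cumsum(score)))
    head = np.where(match[: n - w + 1], pre[: n - w + 1], np.inf)
    accmin = np.minimum.accumulate(head)
    diff = np.where(match[w - 1 :], pre[w:] - accmin, -np.inf)
    jrel = int(np.argmax(diff))
    if diff[jrel] <= _TOL:
        return None
    j = jrel + w
    i = int(np.argmin(np.where(match[: j - w + 1], pre[: j - w + 1], np.inf)))
    n_match = int(np.count_nonzero(match[i:j]))
    return i, j, n_match


def _scan_diagonal(ca, cb, d, min_identity, min_length):
    """Best qualifying window on diagonal d (a[i] vs b[i-d]); None if absent."""
    s = max(0, d)
    e = min(ca.size, cb.size + d)
    if e - s < min_length + 1:
        return None
    a_sl = ca[s:e]
    b_sl = cb[s - d : e - d]
    match = (a_sl == b_sl) & (a_sl != 4)
    found = _best_window(match, min_identity, min_length)
    if found is None:
        return None
    i, j, n_match = found
    return s + i, s + j, n_match


def _seed_rows(codes_list, seed_len):
    vals, eidx, pos, sbit = [], [], [], []
    for ei, codes in enumerate(codes_list):
        fwd, rc, valid = kmer_values(codes, seed_len)
        if valid.size == 0:
            continue
        keep = np.flatnonzero(valid)
        if keep.size == 0:
            continue
        f, r = fwd[keep], rc[keep]
        vals.append(np.minimum(f, r))
        sbit.append(r < f)  # True when the revcomp spelling is canonical
        eidx.append(np.full(keep.size, ei, dtype=np.int32))
        pos.append(keep.astype(np.int32))
    if not vals:
        z = np.zeros(0, dtype=np.int64)
        return z, z.astype(np.int32), z.astype(np.int32), np.zeros(0, dtype=bool)
    return (
        np.concatenate(vals),
        np.concatenate(eidx),
        np.concatenate(pos),
        np.concatenate(sbit),
    )


def _candidate_diagonals(codes_list, sample_of, lengths, seed_len, max_seed_occ):
    """Map each cross-sample entry pair to its set of seeded (strand, diagonal)s."""
    vals, eidx, pos, sbit = _seed_rows(codes_list, seed_len)
    if vals.size == 0:
        return {}
    order = np.lexsort((pos, eidx, vals))
    vals, eidx, pos, sbit = vals[order], eidx[order], pos[order], sbit[order]

    starts = np.flatnonzero(np.concatenate(([True], vals[1:] != vals[:-1])))
    run_len = np.diff(np.concatenate((starts, [vals.size])))
    multi = (run_len >= 2) & (run_len <= max_seed_occ)

    pair_a, pair_b = [], []
    for L in np.unique(run_len[multi]):
        run_starts = starts[multi & (run_len == L)]
        rows = run_starts[:, None] + np.arange(L)
        ii, jj = np.triu_indices(int(L), 1)
        pair_a.append(rows[:, ii].ravel())
        pair_b.append(rows[:, jj].ravel())
    if not pair_a:
        return {}
    ra = np.concatenate(pair_a)
    rb = np.concatenate(pair_b)

    ea, eb = eidx[ra], eidx[rb]
    cross = sample_of[ea] != sample_of[eb]
    ra, rb, ea, eb = ra[cross], rb[cross], ea[cross], eb[cross]
    if ea.size == 0:
        return {}
    # canonical orientation: query entry index < subject entry index
    swap = ea > eb
    ra[swap], rb[swap] = rb[swap], ra[swap].copy()
    ea[swap], eb[swap] = eb[swap], ea[swap].copy()

    pa, pb = pos[ra].astype(np.int64), pos[rb].astype(np.int64)
    minus = sbit[ra] != sbit[rb]
    diag = np.where(
        minus,
        pa - (lengths[eb] - pb - seed_len),
        pa - pb,
    )
    rec = np.stack([ea.astype(np.int64), eb.astype(np.int64), minus.astype(np.int64), diag], axis=1)
    rec = np.unique(rec, axis=0)

    out: dict = {}
    for e1, e2, m, d in rec:
        out.setdefault((int(e1), int(e2)), []).append((bool(m), int(d)))
    return out


def find_suspects(
    assemblies: Sequence[SampleAssembly],
    min_identity: float = 95.0,
    min_length: int = 40,
    seed_len: int = 20,
    max_seed_occ: int = 64,
) -> SuspectTable:
    """Find all seed-anchored suspicious cross-sample transcript pairs.

    Each unordered pair is reported at most once (best-scoring window), on the
    strand and diagonal where the strongest qualifying match lives. Seeds
    occurring at more than ``max_seed_occ`` positions across the dataset are
    treated as repeats and skipped as anchors.
    """
    assemblies = list(assemblies)
    if len(assemblies) < 2:
        raise ConfigurationError("find_suspects needs at least 2 samples")
    if min_length <= seed_len:
        raise ConfigurationError(
            f"min_length ({min_length}) must exceed seed_len ({seed_len})"
        )

    names, tids, codes_f, codes_r, samples, lengths = [], [], [], [], [], []
    for si, asm in enumerate(assemblies):
        for tid, seq in asm:
            names.append((asm.sample_id, tid))
            tids.append(tid)
            c = encode(seq)
            codes_f.append(c)
            codes_r.append(None)  # lazily revcomp'd
            samples.append(si)
            lengths.append(len(seq))
    sample_of = np.asarray(samples, dtype=np.int32)
    lengths = np.asarray(lengths, dtype=np.int64)

    cands = _candidate_diagonals(codes_f, sample_of, lengths, seed_len, max_seed_occ)

    hits = []
    for (e1, e2), strand_diags in cands.items():
        best = None  # (excess_key, hit fields)
        for minus, d in set(strand_diags):
            if minus:
                if codes_r[e2] is None:
                    rc = codes_f[e2][::-1].copy()
                    m = rc < 4
                    rc[m] = 3 - rc[m]
                    codes_r[e2] = rc
                cb = codes_r[e2]
            else:
                cb = codes_f[e2]
            found = _scan_diagonal(codes_f[e1], cb, d, min_identity, min_length)
            if found is None:
                continue
            i, j, n_match = found
            length = j - i
            identity = 100.0 * n_match / length
            excess = 100.0 * n_match - min_identity * length
            bs, be = i - d, j - d
            if minus:
                bs, be = int(lengths[e2] - (j - d)), int(lengths[e2] - (i - d))
            key = (excess, length)
            if best is None or key > best[0]:
                best = (
                    key,
                    SuspectHit(
                        query=names[e1],
                        subject=names[e2],
                        identity_pct=identity,
                        match_len=length,
                        strand="-" if minus else "+",
                        query_start=i,
                        query_end=j,
                        subject_start=bs,
                        subject_end=be,
                    ),
                )
        if best is not None:
            hits.append(best[1])
    return SuspectTable(hits)


def _ungapped_exists(ca, cb, min_identity, min_length, block=2048):
    """Exhaustive window search over every diagonal of the a x b match matrix."""
    n, m = ca.size, cb.size
    w = min_length + 1
    if min(n, m) < w:
        return False
    a = ca[:, None].astype(np.int16)
    i_col = np.arange(n)[:, None]
    n_diag = n + m - 1
    for c0 in range(0, n_diag, block):
        cw = min(block, n_diag - c0)
        cols = np.arange(c0, c0 + cw)[None, :]
        j = cols - (n - 1) + i_col  # (n, cw)
        inside = (j >= 0) & (j < m)
        bj = cb[np.clip(j, 0, m - 1)]
        match = inside & (a == bj) & (a != 4) & (bj != 4)
        score = np.where(
            inside, np.where(match, 100.0 - min_identity, -min_identity), _NEG
        )
        pre = np.vstack([np.zeros((1, cw)), np.cumsum(score, axis=0)])
        # windows must start and end on matched columns
        head = np.where(match[: n - w + 1], pre[: n - w + 1], np.inf)
        accmin = np.minimum.accumulate(head, axis=0)
        diff = np.where(match[w - 1 :], pre[w:] - accmin, -np.inf)
        if (diff > _TOL).any():
            return True
    return False


def _gapped_exists(seq_a, seq_b, min_identity, min_length):
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=1,
        mismatch_score=-2,
        open_gap_score=-3,
        extend_gap_score=-3,
    )
    if not seq_a or not seq_b:
        return False
    alns = aligner.align(seq_a, seq_b)
    if len(alns) == 0:
        return False
    counts = alns[0].counts()
    length = counts.identities + counts.mismatches + counts.gaps
    if length == 0:
        return False
    return (
        length > min_length and 100.0 * counts.identities > min_identity * length
    )


def sw_oracle(
    seq_a: str,
    seq_b: str,
    min_identity: float = 95.0,
    min_length: int = 40,
    both_strands: bool = True,
    max_len: int = 5000,
) -> bool:
    """True iff a local alignment with identity > min_identity over length
    > min_length exists between the sequences (either strand).

    Combines an exhaustive ungapped window search over all diagonals with an
    optimal gapped local alignment at match +1 / mismatch -2 / gap -3. Gap
    columns count as non-identities. Quadratic; refuses sequences > max_len.
    """
    if len(seq_a) > max_len or len(seq_b) > max_len:
        raise ConfigurationError(
            f"sw_oracle is quadratic; sequences longer than {max_len} nt refused"
        )
    ca = encode(seq_a)
    subjects = [seq_b]
    if both_strands:
        subjects.append(revcomp(seq_b))
    for sb in subjects:
        if _ungapped_exists(ca, encode(sb), min_identity, min_length):
            return True
        if _gapped_exists(seq_a, sb, min_identity, min_length):
            return True
    return False
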