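"""Low-level 2-bit k-mer encoding shared by the suspect search and the quantifier.

Sequences are encoded as uint8 codes (A=0, C=1, G=2, T=3, anything else=4).
k-mer integer values are base-4 polynomials, so k must stay <= 31 to fit in
a signed 64-bit integer. Windows touching a non-ACGT code are flagged invalid
and never enter an index or a seed table.
"""

from __future__ import annotations

import numpy as np

MAX_K = 31

_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODES[_b] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into uint8 codes (non-ACGT -> 4)."""
    return _CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` (code 4 renders as N)."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_RC_TABLE)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    mask = out < 4
    out[mask] = 3 - out[mask]
    return out


def kmer_values(codes: np.ndarray, k: int):
    """Forward-strand and reverse-complement integer values of every k-window.

    Returns ``(fwd, rc, valid)`` arrays of length ``len(codes) - k + 1``;
    ``valid`` is False for windows containing a non-ACGT code (their values
    are meaningless and must be masked by the caller).
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    n = codes.size - k + 1
    if n <= 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z.copy(), np.zeros(0, dtype=bool)
    c = np.minimum(codes, 3).astype(np.int64)  # clamp N; masked via `valid`
    fwd = _window_poly(c, k, descending=True)
    rc = _window_poly(3 - c, k, descending=False)
    bad = np.concatenate(([0], np.cumsum(codes == 4, dtype=np.int64)))
    valid = (bad[k:] - bad[:-k]) == 0
    return fwd, rc, valid


def _window_poly(c: np.ndarray, k: int, descending: bool) -> np.ndarray:
    """Base-4 polynomial of every k-window by binary doubling (O(log k) passes).

    descending: value[i] = sum_j c[i+j] * 4^(k-1-j) (forward-strand reading);
    otherwise ascending powers (the reverse-complement reading of 3-c input).
    """
    total = c.size
    segs = {1: c}
    m = 1
    while m * 2 <= k:
        v = segs[m]
        ns = total - 2 * m + 1
        if descending:
            segs[2 * m] = v[:ns] * (4**m) + v[m : m + ns]
        else:
            segs[2 * m] = v[:ns] + v[m : m + ns] * (4**m)
        m *= 2
    bits = [b for b in (16, 8, 4, 2, 1) if k & b]
    covered = bits[0]
    acc = segs[bits[0]]
    for b in bits[1:]:
        ns = total - covered - b + 1
        if descending:
            acc = acc[:ns] * (4**b) + segs[b][covered : covered + ns]
        else:
            acc = acc[:ns] + segs[b][covered : covered + ns] * (4**covered)
        covered += b
    n = total - k + 1
    return np.ascontiguousarray(acc[:n])


def canonical_kmers(codes: np.ndarray, k: int):
    """Canonical (min of forward/revcomp value) k-mers and their validity mask."""
    fwd, rc, valid = kmer_values(codes, k)
    return np.minimum(fwd, rc), valid


def ranges_concat(starts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Concatenate ``[arange(s, s+l) for s, l in zip(starts, lengths)]`` without a loop."""
    lengths = np.asarray(lengths, dtype=np.int64)
    total = int(lengths.sum())
    if total == 0:
        return np.zeros(0, dtype=np.int64)
    ends = np.cumsum(lengths)
    base = np.repeat(np.asarray(starts, dtype=np.int64) - (ends - lengths), lengths)
    return base + np.arange(total, dtype=np.int64)
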