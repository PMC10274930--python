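"""Vectorised k-mer utilities: 2-bit encoding, canonical k-mers, minimizers.

All heavy per-base work in the package funnels through these numpy kernels.
k is limited to 31 so a k-mer fits in 62 bits of a uint64. Positions holding
an N are marked invalid and never match anything (including another N).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 codes (A=0 C=1 G=2 T=3, anything else 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward k-mer integers and a validity mask (no N in the window)."""
    n = codes.size
    if k > 31:
        raise ValueError("k must be <= 31")
    if n < k:
        return np.empty(0, np.uint64), np.empty(0, bool)
    m = n - k + 1
    vals = np.zeros(m, dtype=np.uint64)
    safe = np.where(codes == 4, 0, codes).astype(np.uint64)
    for i in range(k):
        vals = (vals << np.uint64(2)) | safe[i : m + i]
    bad = np.cumsum(np.concatenate(([0], (codes == 4).astype(np.int64))))
    valid = (bad[k:] - bad[:-k]) == 0
    return vals, valid


def canonical_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical k-mer values, strand flags and validity.

    Returns (canon, strand, valid) where strand is 0 where the forward k-mer
    is the canonical one, 1 where its reverse complement is.
    """
    n = codes.size
    if n < k:
        e = np.empty(0, np.uint64)
        return e, np.empty(0, np.uint8), np.empty(0, bool)
    fwd, valid = kmer_values(codes, k)
    m = n - k + 1
    rc_codes = np.where(codes == 4, np.uint8(0), (3 - codes).astype(np.uint8)).astype(np.uint64)
    rcv = np.zeros(m, dtype=np.uint64)
    for i in range(k):
        rcv |= rc_codes[i : m + i] << np.uint64(2 * i)
    strand = (rcv < fwd).astype(np.uint8)
    canon = np.where(strand == 1, rcv, fwd)
    return canon, strand, valid


def mix64(v: np.ndarray) -> np.ndarray:
    """Invertible 64-bit mix (splitmix64 finaliser), top bit cleared."""
    v = v.astype(np.uint64, copy=True)
    v ^= v >> np.uint64(30)
    v *= np.uint64(0xBF58476D1CE4E5B9)
    v ^= v >> np.uint64(27)
    v *= np.uint64(0x94D049BB133111EB)
    v ^= v >> np.uint64(31)
    # keep 31 bits: scipy's filters go through float64 internally, which
    # represents these exactly; rare ties only broaden selection symmetrically
    return (v >> np.uint64(33)).astype(np.int64)


def minimizer_positions(canon: np.ndarray, valid: np.ndarray, w: int) -> np.ndarray:
    """Classic minimizer selection: the argmin of every window of w
    consecutive k-mer positions is selected.

    Selection inside a window depends only on that window's k-mer content, so
    any two occurrences of the same substring spanning at least w+k-1 bases
    (either strand) share a selected position — the guarantee seed-and-extend
    relies on. w is forced odd for the filter alignment.
    """
    if canon.size == 0:
        return np.empty(0, np.int64)
    w |= 1
    sel = mix64(canon)
    big = np.iinfo(np.int64).max
    small = np.iinfo(np.int64).min
    sel = np.where(valid, sel, big)
    m = sel.size
    if m <= w:
        if not valid.any():
            return np.empty(0, np.int64)
        return np.nonzero((sel == sel.min()) & valid)[0]
    # winmin[j] = min(sel[j : j + w]) for window starts j in [0, m - w]
    winmin = minimum_filter1d(sel, size=w, mode="nearest", origin=-(w // 2))
    wm = np.full(m, small, np.int64)
    wm[: m - w + 1] = winmin[: m - w + 1]
    # wmax[p] = max over window starts j in [p - w + 1, p] of winmin[j]
    wmax = maximum_filter1d(wm, size=w, mode="constant", cval=small,
                            origin=w // 2)
    return np.nonzero((sel == wmax) & valid)[0]


def canonical_kmer_set(seqs, k: int) -> np.ndarray:
    """Sorted unique canonical k-mers over one or many sequences."""
    if isinstance(seqs, str):
        seqs = [seqs]
    parts = []
    for s in seqs:
        canon, _, valid = canonical_kmers(encode(s), k)
        parts.append(canon[valid])
    if not parts:
        return np.empty(0, np.uint64)
    return np.unique(np.concatenate(parts))


def count_in_set(seq: str, kmer_set: np.ndarray, k: int) -> int:
    """Number of k-mer positions of seq whose canonical k-mer is in kmer_set."""
    if len(seq) < k or kmer_set.size == 0:
        return 0
    canon, _, valid = canonical_kmers(encode(seq), k)
    canon = canon[valid]
    if canon.size == 0:
        return 0
    idx = np.searchsorted(kmer_set, canon)
    idx[idx == kmer_set.size] = kmer_set.size - 1
    return int(np.count_nonzero(kmer_set[idx] == canon))
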