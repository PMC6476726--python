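"""Vectorized 2-bit k-mer encoding shared by the aligner and the counter.

Codes are base-4 integers (A=0, C=1, G=2, T=3) assembled by recursive
doubling, so computing all windows of a 20 Mb sequence takes a handful of
whole-array operations.  k up to 31 fits in uint64.
"""

from __future__ import annotations

import numpy as np

_ENC = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i

MAX_K = 31


def encode(seq: str) -> np.ndarray:
    """Bases to small ints; anything but ACGT (notably N) becomes 4."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, valid) for every k-window of ``arr``.

    ``valid`` is False for windows containing an N; their codes are
    meaningless and must be masked by the caller.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must lie in [1, {MAX_K}]")
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    safe = np.where(arr == 4, 0, arr).astype(np.uint8)
    is_n = (arr == 4).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(is_n, dtype=np.int64)])
    valid = (cs[k:] - cs[:-k]) == 0

    # power-of-two building blocks: blocks[w][i] encodes arr[i : i + w];
    # the dtype grows with the bit width (2w bits for width w) to keep the
    # intermediate arrays small
    dtypes = {1: np.uint8, 2: np.uint8, 4: np.uint8, 8: np.uint16, 16: np.uint32}
    blocks: dict[int, np.ndarray] = {1: safe}
    w = 1
    while w * 2 <= k:
        prev = blocks[w]
        dt = dtypes[w * 2]
        blocks[w * 2] = (prev[: prev.size - w].astype(dt) << dt(2 * w)) | prev[w:]
        w *= 2
    # combine the binary decomposition of k, high bits first
    codes = None
    offset = 0
    for w in sorted(blocks, reverse=True):
        if k & w:
            part = blocks[w][offset : offset + n]
            if codes is None:
                codes = part.astype(np.uint64)
            else:
                codes = (codes << np.uint64(2 * w)) | part
            offset += w
    return codes, valid


def revcomp_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Codes of the reverse complement of each window, aligned so that
    index i pairs with the forward window at index i."""
    rc = np.where(arr == 4, 4, 3 - arr)[::-1]
    codes, _ = kmer_codes(rc, k)
    return codes[::-1]
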