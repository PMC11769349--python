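"""Shared test utilities: independent oracles and statistical bounds.

Everything here is deliberately naive/brute-force so it stays independent
of the implementation paths it is used to check.
"""

from __future__ import annotations

import math

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def binom_3sigma(p: float, n: int) -> float:
    """Three-sigma half-width of a binomial proportion estimate."""
    return 3.0 * math.sqrt(p * (1.0 - p) / n)


def naive_window_trim(qual: np.ndarray, q: int = 30, window: int = 4) -> int | None:
    """Brute-force sliding-window scan; returns the cut index or None."""
    n = len(qual)
    for start in range(0, n - window + 1):
        if float(qual[start : start + window].mean()) < q:
            return start
    return None


def best_segment_naive(match: np.ndarray) -> tuple[int, int, int]:
    """O(n^2) maximal-scoring segment of a +1/-1 vector (first-best ties)."""
    v = [1 if m else -1 for m in match]
    n = len(v)
    best = (0, 0, -10**9)
    for j in range(1, n + 1):
        for i in range(j):
            s = sum(v[i:j])
            if s > best[2]:
                best = (i, j, s)
    return best


def exhaustive_align(read: str, ref: str) -> tuple[int, set[tuple[int, int, int]]]:
    """Exhaustive ungapped local alignment over every diagonal and strand.

    Scores +1 match / -1 mismatch on every diagonal of the read against the
    reference (both strands) and returns the best score together with the
    set of ``(strand, ref_start, ref_end)`` loci achieving it.  Vectorised
    maximal-segment (prefix-min) computation per diagonal.
    """
    n = len(read)
    best_score = -10**9
    loci: set[tuple[int, int, int]] = set()
    for strand, s in ((0, read), (1, rc(read))):
        s_arr = np.frombuffer(s.encode(), dtype=np.uint8)
        padded = b"\x00" * n + ref.encode() + b"\x00" * n
        p_arr = np.frombuffer(padded, dtype=np.uint8)
        # diagonal origin d: read offset 0 sits at ref position d (may be <0)
        for d in range(-n + 1, len(ref)):
            w = p_arr[d + n : d + 2 * n]
            v = np.where(w == s_arr, 1, -1).astype(np.int64)
            P = np.concatenate(([0], np.cumsum(v)))
            prem = np.minimum.accumulate(P)
            gains = P[1:] - prem[:-1]
            j = int(np.argmax(gains))
            score = int(gains[j])
            if score < best_score:
                continue
            i = int(np.argmin(P[: j + 1]))
            locus = (strand, d + i, d + j + 1)
            if score > best_score:
                best_score = score
                loci = {locus}
            else:
                loci.add(locus)
    return best_score, loci
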