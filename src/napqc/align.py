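"""Native paired-end short-read aligner (k-mer seed + ungapped extension).

Kilobase-scale construct references make exhaustive-quality alignment cheap:
seeds are exact k-mers hashed over the (doubled, if circular) reference,
candidate loci are scored by ungapped extension with match +1 / mismatch -1,
and terminal regions that score negatively are soft-clipped (CIGAR is
restricted to M and S).  Multi-mapping ties are broken deterministically
(forward before reverse, then lowest coordinate) and flagged with MAPQ 1;
unique best loci get MAPQ 60.

Also provides Q30 sliding-window read trimming equivalent to the
SLIDINGWINDOW-style rule: scan 4-base windows 5'->3', cut at the first
window whose mean quality drops below the threshold, drop reads shorter
than ``min_len`` afterwards.
"""

from __future__ import annotations

import numpy as np

from .formats import (
    FLAG_FIRST,
    FLAG_MATE_REVERSE,
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_PROPER,
    FLAG_REVERSE,
    FLAG_SECOND,
    FLAG_UNMAPPED,
    AlignmentRecord,
    Read,
    SequenceRecord,
    revcomp_bytes,
)

__all__ = [
    "quality_trim",
    "KmerIndex",
    "build_index",
    "align_read",
    "align_pair",
    "pair_is_proper",
]

_PAD = 512  # widest read the padded linear reference supports


def quality_trim(read: Read, q: int = 30, min_len: int = 36, window: int = 4) -> Read | None:
    """Trim a read at the first 4-base window whose mean quality is below ``q``.

    Returns the (possibly shortened) read, or None if fewer than ``min_len``
    bases survive.  Reads shorter than one window are kept untouched if their
    mean quality passes.
    """
    qual = read.qual
    n = len(qual)
    if n == 0:
        return None
    if int(qual.min()) >= q:  # fast path: nothing can fail
        return read
    if n < window:
        return read if float(qual.mean()) >= q else None
    c = np.concatenate(([0], np.cumsum(qual, dtype=np.int64)))
    means = (c[window:] - c[:-window]) / window  # window starts 0..n-window
    bad = np.nonzero(means < q)[0]
    if len(bad) == 0:
        return read
    cut = int(bad[0])
    if cut < min_len:
        return None
    return Read(read.id, read.seq[:cut], qual[:cut].copy(), read.mate)


class KmerIndex:
    """Exact k-mer lookup table over one reference sequence.

    Circular references are indexed on the doubled string with positions
    reduced modulo the length, so origin-crossing seeds and windows work
    without special cases.  Linear references are padded with a sentinel
    byte on both sides so candidate windows never need bounds checks and
    out-of-reference bases always count as mismatches (hence get clipped).
    """

    def __init__(self, ref: SequenceRecord, k: int = 21):
        if k < 1 or k > len(ref.seq):
            raise ValueError(f"k={k} larger than reference {ref.id!r} ({len(ref.seq)} nt)")
        self.k = k
        self.ref = ref
        self.name = ref.id
        self.circular = ref.circular
        seq = ref.seq.encode()
        L = len(seq)
        self.L = L
        if ref.circular:
            reps = 2
            while L * reps < L + _PAD:  # tiny plasmids: repeat further
                reps += 1
            stored = seq * reps
            self._off = 0
            n_starts = L
        else:
            stored = b"\x00" * _PAD + seq + b"\x00" * _PAD
            self._off = _PAD
            n_starts = L - k + 1
        self._bytes = stored
        self._arr = np.frombuffer(stored, dtype=np.uint8)
        tab: dict[bytes, list[int]] = {}
        off = self._off
        for p in range(n_starts):
            tab.setdefault(stored[off + p : off + p + k], []).append(p)
        self.tab = tab

    def window_bytes(self, start: int, length: int) -> bytes:
        if self.circular:
            start %= self.L
            return self._bytes[start : start + length]
        return self._bytes[start + self._off : start + self._off + length]

    def window_arr(self, start: int, length: int) -> np.ndarray:
        if self.circular:
            start %= self.L
            return self._arr[start : start + length]
        return self._arr[start + self._off : start + self._off + length]


def build_index(ref: SequenceRecord, k: int = 21) -> KmerIndex:
    """Build a :class:`KmerIndex`; thin functional wrapper."""
    return KmerIndex(ref, k)


def _best_segment(match: np.ndarray) -> tuple[int, int, int]:
    """Maximal-scoring contiguous segment of a +1/-1 match vector.

    Returns ``(i, j, score)`` for the half-open query interval [i, j);
    ties resolve to the earliest (lowest j, then lowest i) segment.
    """
    v = np.where(match, 1, -1).astype(np.int64)
    P = np.empty(len(v) + 1, dtype=np.int64)
    P[0] = 0
    np.cumsum(v, out=P[1:])
    prem = np.minimum.accumulate(P)
    gains = P[1:] - prem[:-1]
    j = int(np.argmax(gains))  # first maximum
    score = int(gains[j])
    i = int(np.argmin(P[: j + 1]))  # first minimum prefix
    return i, j + 1, score


def _align_seq(
    seq: bytes,
    index: KmerIndex,
    max_mm: float,
    min_aln: int,
    seed_stride: int,
    max_candidates: int,
    max_seed_hits: int,
) -> tuple[int, int, int, int, int, bool] | None:
    """Best ungapped locus of ``seq`` against ``index`` on either strand.

    Returns ``(strand, ref_start_raw, i, j, n_mismatch, tied)`` where
    [i, j) is the aligned query interval in *aligned* orientation and
    ``ref_start_raw`` is the candidate diagonal origin (query offset 0),
    not yet reduced modulo the circular length.  None if nothing passes
    the ``min_aln`` / ``max_mm`` gates.
    """
    n = len(seq)
    k = index.k
    if n < k:
        return None
    offs = list(range(0, n - k, seed_stride))
    offs.append(n - k)
    tab = index.tab
    rc = revcomp_bytes(seq)
    best = None  # (score, strand, st, i, j, mm)
    tied = False
    for strand, s in ((0, seq), (1, rc)):
        # repetitive seeds (homopolymer tails, repeats) flood the candidate
        # list and can evict the true diagonal; skip them unless nothing
        # else seeds the read
        starts: set[int] = set()
        repetitive: list[list[int]] = []
        rep_offs: list[int] = []
        for off in offs:
            hits = tab.get(s[off : off + k])
            if not hits:
                continue
            if len(hits) > max_seed_hits:
                repetitive.append(hits)
                rep_offs.append(off)
                continue
            for p in hits:
                starts.add(p - off)
        if not starts and repetitive:
            for off, hits in zip(rep_offs, repetitive):
                for p in hits:
                    starts.add(p - off)
        if not starts:
            continue
        cand_list = sorted(starts)[:max_candidates]
        s_arr = None
        for st in cand_list:
            if index.window_bytes(st, n) == s:
                cand = (n, strand, st, 0, n, 0)
            else:
                if best is not None and best[0] == n:
                    continue  # only a full-length exact match could tie
                if s_arr is None:
                    s_arr = np.frombuffer(s, dtype=np.uint8)
                match = index.window_arr(st, n) == s_arr
                i, j, score = _best_segment(match)
                m_len = j - i
                mm = (m_len - score) // 2
                if m_len < min_aln or mm > max_mm * m_len:
                    continue
                cand = (score, strand, st, i, j, mm)
            if best is None or cand[0] > best[0]:
                best = cand
                tied = False
            elif cand[0] == best[0] and (cand[1], cand[2]) != (best[1], best[2]):
                tied = True
    if best is None:
        return None
    score, strand, st, i, j, mm = best
    return strand, st, i, j, mm, tied


def align_read(
    read: Read,
    index: KmerIndex,
    max_mm: float = 0.1,
    min_aln: int = 30,
    seed_stride: int = 15,
    max_candidates: int = 64,
    max_seed_hits: int = 16,
) -> AlignmentRecord:
    """Align one read; failure to align is an unmapped record, not an error.

    The returned record carries the paired + first/second-in-pair bits (mate
    and proper-pair bits are the responsibility of :func:`align_pair`).
    Sequence and quality are stored in aligned orientation.
    """
    base_flag = FLAG_PAIRED | (FLAG_FIRST if read.mate == "R1" else FLAG_SECOND)
    qual_str = (read.qual + 33).tobytes().decode()
    res = _align_seq(
        read.seq.encode(), index, max_mm, min_aln, seed_stride, max_candidates,
        max_seed_hits,
    )
    if res is None:
        return AlignmentRecord(
            read_id=read.id,
            flag=base_flag | FLAG_UNMAPPED,
            seq=read.seq,
            qual=qual_str,
        )
    strand, st, i, j, mm, tied = res
    n = len(read.seq)
    if strand:
        seq = revcomp_bytes(read.seq.encode()).decode()
        qual_str = qual_str[::-1]
        flag = base_flag | FLAG_REVERSE
    else:
        seq = read.seq
        flag = base_flag
    start = st + i
    if index.circular:
        start %= index.L
    cigar: list[tuple[str, int]] = []
    if i:
        cigar.append(("S", i))
    cigar.append(("M", j - i))
    if n - j:
        cigar.append(("S", n - j))
    return AlignmentRecord(
        read_id=read.id,
        flag=flag,
        ref_name=index.name,
        start=start,
        ref_end=start + (j - i),
        cigar=cigar,
        mapq=1 if tied else 60,
        n_mismatch=mm,
        seq=seq,
        qual=qual_str,
    )


def pair_is_proper(
    a1: AlignmentRecord,
    a2: AlignmentRecord,
    ref_len: int,
    circular: bool,
    max_insert: int = 2000,
) -> bool:
    """FR-orientation proper-pair rule with a configurable insert ceiling.

    Both mates mapped to the same reference on opposite strands with the
    forward mate upstream and the implied insert no longer than
    ``max_insert``.  On circular references the insert is taken modulo the
    reference length so origin-spanning fragments still qualify.
    """
    if a1.is_unmapped or a2.is_unmapped:
        return False
    if a1.ref_name != a2.ref_name:
        return False
    if a1.is_reverse == a2.is_reverse:
        return False
    fwd, rev = (a1, a2) if not a1.is_reverse else (a2, a1)
    d = rev.ref_end - fwd.start
    if circular:
        d %= ref_len
    return 0 < d <= max_insert


def align_pair(
    r1: Read,
    r2: Read,
    index: KmerIndex,
    max_mm: float = 0.1,
    min_aln: int = 30,
    seed_stride: int = 15,
    max_candidates: int = 64,
    max_seed_hits: int = 16,
    max_insert: int = 2000,
) -> tuple[AlignmentRecord, AlignmentRecord]:
    """Align both mates independently and set pairing bits consistently."""
    if r1.id != r2.id:
        raise ValueError(f"mate id mismatch: {r1.id!r} vs {r2.id!r}")
    if r1.mate != "R1" or r2.mate != "R2":
        raise ValueError("align_pair expects (R1, R2) in that order")
    a1 = align_read(r1, index, max_mm, min_aln, seed_stride, max_candidates, max_seed_hits)
    a2 = align_read(r2, index, max_mm, min_aln, seed_stride, max_candidates, max_seed_hits)
    if a2.is_unmapped:
        a1.flag |= FLAG_MATE_UNMAPPED
    elif a2.is_reverse:
        a1.flag |= FLAG_MATE_REVERSE
    if a1.is_unmapped:
        a2.flag |= FLAG_MATE_UNMAPPED
    elif a1.is_reverse:
        a2.flag |= FLAG_MATE_REVERSE
    if pair_is_proper(a1, a2, index.L, index.circular, max_insert):
        a1.flag |= FLAG_PROPER
        a2.flag |= FLAG_PROPER
    return a1, a2
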