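"""Algorithmic poly-A tail-length estimation from transcript alignments.

Short-read chemistry cannot read through long homopolymers reliably, and a
read that simply *ends* in A's cannot prove the tail ended there.  The
estimator therefore leans on reads that span the 3' junction: their
alignment enters the annotated tail region of the transcript reference and
their 3' soft clip continues past the adenosine run into non-A sequence
(the run-off suffix a linearised IVT template leaves downstream of the
templated tail).  Per-read tail length is

    (aligned bases at/after the annotated tail start)
  + (maximal A-run at the start of the 3' soft clip, tolerating one non-A
     per ten clipped bases).

Reads whose clip continues into at least ``min_nona_after`` non-A bases
after the run have fully spanned the tail and enter the summary; reads that
end inside the run are right-censored lower bounds, counted separately as
``n_lower_bound`` and excluded from median/min/max.  Only sense-strand
records are informative — the tail lives on the sense strand, and
double-stranded or antisense material carries no tail signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import AlignmentRecord
from .references import ReferenceSet
from .triage import StrandClass, classify_strand

__all__ = ["PolyAEstimate", "estimate_polya", "tail_run_length"]


@dataclass
class PolyAEstimate:
    """Summary of per-read tail-length measurements.

    ``median``/``min``/``max``/``iqr`` are None when no read fully spanned
    the tail (``n_support == 0``); that is a defined outcome, not an error.
    """

    per_read_lengths: list[int]
    n_lower_bound: int
    lower_bounds: list[int]

    @property
    def n_support(self) -> int:
        return len(self.per_read_lengths)

    @property
    def median(self) -> float | None:
        return float(np.median(self.per_read_lengths)) if self.per_read_lengths else None

    @property
    def min(self) -> int | None:
        return int(np.min(self.per_read_lengths)) if self.per_read_lengths else None

    @property
    def max(self) -> int | None:
        return int(np.max(self.per_read_lengths)) if self.per_read_lengths else None

    @property
    def iqr(self) -> float | None:
        if not self.per_read_lengths:
            return None
        q1, q3 = np.percentile(self.per_read_lengths, [25, 75])
        return float(q3 - q1)

    def to_dict(self, per_read: bool = False) -> dict:
        d = {
            "n_support": self.n_support,
            "n_lower_bound": self.n_lower_bound,
            "median": self.median,
            "min": self.min,
            "max": self.max,
            "iqr": self.iqr,
        }
        if per_read:
            d["per_read_lengths"] = list(self.per_read_lengths)
        return d


def tail_run_length(seq: str, max_nona_per10: int = 1) -> int:
    """Length of the maximal prefix A-run allowing a small mismatch budget.

    The run may absorb up to ``max_nona_per10`` non-A bases per ten bases of
    run length and must end on an A.  ``"AAAAAGAAAA"`` therefore scores 10;
    ``"CCCC"`` scores 0.
    """
    if not seq:
        raise ValueError("tail_run_length requires a non-empty sequence")
    best = 0
    non_a = 0
    for i, ch in enumerate(seq):
        if ch != "A":
            non_a += 1
            continue
        length = i + 1
        if non_a * 10 <= length * max_nona_per10:
            best = length
    return best


def estimate_polya(
    records: list[AlignmentRecord],
    refs: ReferenceSet,
    w: int = 5,
    max_nona_per10: int = 1,
    min_nona_after: int = 5,
) -> PolyAEstimate:
    """Estimate tail length from primary alignments against the transcript.

    Parameters
    ----------
    records : list of AlignmentRecord
        Alignments against ``refs.ref2`` (e.g. the phase-1 records of the
        mRNA triage, or a parsed external SAM).
    refs : ReferenceSet
        Supplies the transcript id and the annotated tail start.
    w : int
        A read ending up to ``w`` nt upstream of the annotated tail start
        with a 3' soft clip still counts as informative (junction wobble).
    max_nona_per10, min_nona_after : int
        A-run mismatch budget and the non-A evidence required to call a
        tail fully spanned.
    """
    pstart = refs.polya_start
    ref2_len = len(refs.ref2)
    full: list[int] = []
    lower: list[int] = []
    for rec in records:
        if rec.is_unmapped or rec.ref_name != refs.ref2.id:
            continue
        if classify_strand(rec) is not StrandClass.SENSE:
            continue
        # aligned orientation == transcript orientation: 3' is the right end
        ref_end = rec.ref_end
        clip_len = rec.right_clip
        in_tail = max(0, min(ref_end, ref2_len) - max(rec.start, pstart))
        if ref_end <= pstart - w:
            continue
        if ref_end <= pstart and clip_len == 0:
            continue
        clip_seq = rec.seq[len(rec.seq) - clip_len :] if clip_len else ""
        run = tail_run_length(clip_seq, max_nona_per10) if clip_seq else 0
        measured = in_tail + run
        if measured == 0 and clip_len == 0:
            continue
        after = clip_seq[run:]
        n_nona_after = sum(1 for c in after if c != "A")
        if n_nona_after >= min_nona_after:
            full.append(measured)
        else:
            lower.append(measured)
    return PolyAEstimate(per_read_lengths=full, n_lower_bound=len(lower), lower_bounds=lower)
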