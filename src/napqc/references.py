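"""The four-reference decomposition the whole workflow rests on.

* Ref-1 — the complete circular production plasmid;
* Ref-2 — the replicon transcript (sense strand, 5'->3', terminal poly-A);
* Ref-3 — the plasmid backbone, i.e. Ref-1 with the replicon template span
  excised and the circle re-joined across the cut;
* Ref-4 — the host genome (or a host fixture) the plasmid was propagated in.

Internally all coordinates are 0-based half-open in plasmid coordinates;
spans crossing the circular origin are normalised by doubling the plasmid
string, so ``end`` may exceed ``len(ref1)`` by up to one full turn.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats import REF_ALPHABET, FormatError, SequenceRecord

__all__ = ["ReferenceSet", "build_reference_set", "linearize"]


@dataclass(slots=True)
class ReferenceSet:
    """The four references plus the poly-A annotation.

    Attributes
    ----------
    ref1, ref2, ref3, ref4 : SequenceRecord
        Plasmid / replicon transcript / backbone / host.
    replicon_span : tuple[int, int]
        Template span of the replicon on ref1, 0-based half-open after
        circular normalisation (``0 <= start < len(ref1)``,
        ``start < end <= start + len(ref1)``).
    polya_start : int
        Position on ref2 where the annotated tail begins.
    polya_len : int
        Annotated tail length (nt); the tail is terminal on ref2.
    """

    ref1: SequenceRecord
    ref2: SequenceRecord
    ref3: SequenceRecord
    ref4: SequenceRecord
    replicon_span: tuple[int, int]
    polya_start: int
    polya_len: int

    def __post_init__(self) -> None:
        start, end = self.replicon_span
        span_len = end - start
        if not (0 <= start < len(self.ref1) and start < end <= start + len(self.ref1)):
            raise ValueError(f"replicon span {self.replicon_span} outside plasmid")
        if len(self.ref3) != len(self.ref1) - span_len:
            raise ValueError(
                f"backbone length {len(self.ref3)} != plasmid {len(self.ref1)} "
                f"minus span {span_len}"
            )
        if self.polya_start + self.polya_len != len(self.ref2):
            raise ValueError("poly-A tail must be terminal on ref2")
        tail = self.ref2.seq[self.polya_start : self.polya_start + self.polya_len]
        if tail != "A" * self.polya_len:
            raise ValueError("annotated poly-A region of ref2 is not all A")

    def downstream_of_replicon(self, n: int) -> str:
        """Plasmid sequence immediately downstream of the template span.

        This is what run-off transcription appends past the templated tail
        when the template is linearised downstream of the replicon.
        """
        _, end = self.replicon_span
        doubled = self.ref1.seq * 2
        return doubled[end : end + n]


def _validate_reference_sequence(rec: SequenceRecord, what: str) -> None:
    # N is allowed in reads but not in references (keeps the seed table exact).
    bad = set(rec.seq) - REF_ALPHABET
    if bad:
        raise FormatError(f"{what} sequence contains non-ACGT characters: {sorted(bad)}")


def build_reference_set(
    plasmid: SequenceRecord,
    replicon_span: tuple[int, int],
    polya_len: int,
    host: SequenceRecord,
    templated_tail: bool = True,
) -> ReferenceSet:
    """Derive Ref-2 (transcript) and Ref-3 (backbone) from the plasmid.

    Parameters
    ----------
    plasmid : SequenceRecord
        Circular plasmid (Ref-1).
    replicon_span : tuple[int, int]
        0-based half-open template span on the plasmid; may cross the
        circular origin (``end`` up to ``start + len(plasmid)``).
    polya_len : int
        Length of the poly-A tail.  With ``templated_tail=True`` the last
        ``polya_len`` bases of the span must be A on the sense strand; with
        ``templated_tail=False`` the tail is appended to ref2 (enzymatic
        tailing) and ref1/ref3 are untouched.
    host : SequenceRecord
        Host genome or host fixture (Ref-4).

    Returns
    -------
    ReferenceSet
    """
    if not plasmid.circular:
        raise ValueError("plasmid must be circular")
    _validate_reference_sequence(plasmid, "plasmid")
    _validate_reference_sequence(host, "host")
    L = len(plasmid)
    start, end = replicon_span
    if polya_len < 0:
        raise ValueError("polya_len must be >= 0")
    # Circular normalisation: bring start into [0, L).
    shift = start % L - start
    start, end = start + shift, end + shift
    if not (start < end <= start + L):
        raise ValueError(f"replicon span {replicon_span} empty or exceeds plasmid length {L}")
    if end - start >= L:
        raise ValueError("replicon span covers the whole plasmid; no backbone left")

    doubled = plasmid.seq * 2
    span_seq = doubled[start:end]
    if templated_tail:
        if polya_len > len(span_seq):
            raise ValueError("polya_len exceeds replicon span")
        if span_seq[len(span_seq) - polya_len :] != "A" * polya_len:
            raise ValueError(
                "tail annotation disagrees with sequence: last "
                f"{polya_len} bases of the span are not all A"
            )
        ref2_seq = span_seq
    else:
        ref2_seq = span_seq + "A" * polya_len

    ref3_seq = doubled[end : start + L]  # circular order, joined at the cut
    ref2 = SequenceRecord(f"{plasmid.id}|replicon", ref2_seq, circular=False)
    ref3 = SequenceRecord(f"{plasmid.id}|backbone", ref3_seq, circular=False)
    return ReferenceSet(
        ref1=plasmid,
        ref2=ref2,
        ref3=ref3,
        ref4=host,
        replicon_span=(start, end),
        polya_start=len(ref2_seq) - polya_len,
        polya_len=polya_len,
    )


def linearize(plasmid: SequenceRecord, cut: int) -> SequenceRecord:
    """Linearise a circular plasmid at ``cut`` (models template linearisation).

    The result has the same length, begins at ``cut`` and carries a cleared
    circular flag.
    """
    if not plasmid.circular:
        raise ValueError("linearize requires a circular plasmid")
    if not (0 <= cut < len(plasmid)):
        raise ValueError(f"cut {cut} out of range [0, {len(plasmid)})")
    s = plasmid.seq
    return SequenceRecord(plasmid.id, s[cut:] + s[:cut], circular=False)
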