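"""Readers and writers for the standard formats the pipeline touches.

The dialect is deliberately strict: FASTA is multi-line and case-insensitive,
FASTQ is four-line Phred+33, SAM must carry ``@SQ`` header lines for every
reference an alignment names.  Parsing is backed by Biopython (FASTA/FASTQ)
and pysam (SAM); this module adds the validation the pipeline's invariants
require and converts everything to the internal conventions:

* coordinates are 0-based, half-open internally and 1-based in SAM files;
* alignment records store the read in *aligned* orientation (SAM convention),
  with the FLAG preserved bit-exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pysam
from Bio import SeqIO

__all__ = [
    "FormatError",
    "SequenceRecord",
    "Read",
    "AlignmentRecord",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "parse_sam",
    "write_sam",
    "revcomp",
    "FLAG_PAIRED",
    "FLAG_PROPER",
    "FLAG_UNMAPPED",
    "FLAG_MATE_UNMAPPED",
    "FLAG_REVERSE",
    "FLAG_MATE_REVERSE",
    "FLAG_FIRST",
    "FLAG_SECOND",
]

# SAM FLAG bits (SAM spec semantics).
FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80

REF_ALPHABET = frozenset("ACGT")
READ_ALPHABET = frozenset("ACGTN")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_COMP_B = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


class FormatError(ValueError):
    """A file violates the dialect this pipeline reads/writes."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-complements)."""
    return seq.translate(_COMP)[::-1]


def revcomp_bytes(seq: bytes) -> bytes:
    return seq.translate(_COMP_B)[::-1]


@dataclass(slots=True)
class SequenceRecord:
    """A named nucleotide sequence with an explicit topology flag.

    Parameters
    ----------
    id : str
        Identifier without whitespace.
    seq : str
        Sequence over {A, C, G, T, N}; folded to upper case.
    circular : bool
        True for circular molecules (plasmids); affects downstream
        indexing and fragment sampling.
    """

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"sequence id must be non-empty without whitespace: {self.id!r}")
        self.seq = self.seq.upper()
        if not self.seq:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - READ_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains illegal characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(slots=True)
class Read:
    """One sequencing read with per-base Phred qualities.

    ``mate`` is "R1" (forward read of the pair) or "R2" (reverse read).
    """

    id: str
    seq: str
    qual: np.ndarray
    mate: str

    def __post_init__(self) -> None:
        if self.mate not in ("R1", "R2"):
            raise FormatError(f"mate must be R1 or R2, got {self.mate!r}")
        self.qual = np.asarray(self.qual, dtype=np.uint8)
        if len(self.qual) != len(self.seq):
            raise FormatError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )
        if len(self.qual) and int(self.qual.max()) > 60:
            raise FormatError(f"read {self.id!r}: Phred score above 60")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(slots=True)
class AlignmentRecord:
    """One read's placement, with SAM-semantics FLAG bits.

    ``start``/``ref_end`` are 0-based half-open on the reference.  ``cigar``
    is a list of ``(op, length)`` with ops restricted to ``M`` (aligned) and
    ``S`` (soft clip); richer CIGARs from external SAM are folded so that
    query-side bookkeeping stays exact and ``ref_end`` carries the reference
    span.  ``seq``/``qual`` are stored in aligned orientation (SAM
    convention); for unmapped records they are in original orientation.
    """

    read_id: str
    flag: int
    ref_name: str | None = None
    start: int = -1
    ref_end: int = -1
    cigar: list[tuple[str, int]] = field(default_factory=list)
    mapq: int = 0
    n_mismatch: int = 0
    seq: str = ""
    qual: str = ""

    def __post_init__(self) -> None:
        fs = self.flag & (FLAG_FIRST | FLAG_SECOND)
        if fs not in (FLAG_FIRST, FLAG_SECOND):
            raise FormatError(
                f"record {self.read_id!r}: exactly one of first/second-in-pair "
                f"bits must be set (flag={self.flag})"
            )
        if not self.is_unmapped and (self.ref_name is None or self.start < 0):
            raise FormatError(
                f"record {self.read_id!r}: mapped record needs ref_name and "
                f"non-negative position"
            )

    # -- FLAG convenience -------------------------------------------------
    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_first(self) -> bool:
        return bool(self.flag & FLAG_FIRST)

    @property
    def is_second(self) -> bool:
        return bool(self.flag & FLAG_SECOND)

    @property
    def mate(self) -> str:
        return "R1" if self.is_first else "R2"

    # -- CIGAR bookkeeping ------------------------------------------------
    @property
    def aligned_len(self) -> int:
        """Total query bases in M operations."""
        return sum(n for op, n in self.cigar if op == "M")

    @property
    def left_clip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def right_clip(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0

    @property
    def cigar_string(self) -> str:
        if not self.cigar:
            return "*"
        return "".join(f"{n}{op}" for op, n in self.cigar)

    def original_read(self) -> Read:
        """Reconstruct the read in its original (sequencer) orientation."""
        seq, qual = self.seq, self.qual
        q = np.frombuffer(qual.encode(), dtype=np.uint8) - 33
        if self.is_reverse:
            seq = revcomp(seq)
            q = q[::-1]
        return Read(self.read_id, seq, q.copy(), self.mate)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _locate_bad_fasta_line(path: str | os.PathLike, allowed: frozenset) -> tuple[int, str]:
    """Rescan ``path`` to find the first sequence line with an illegal character."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            bad = set(line.upper()) - allowed
            if bad:
                return lineno, sorted(bad)[0]
    return -1, ""


def read_fasta(path: str | os.PathLike, circular: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Multi-line sequences are concatenated and folded to upper case.  Empty
    files, duplicate ids and illegal characters raise :class:`FormatError`
    naming the offense (and the offending line for alphabet violations).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if set(seq) - READ_ALPHABET:
            lineno, char = _locate_bad_fasta_line(path, READ_ALPHABET)
            raise FormatError(
                f"{path}: illegal character {char!r} on line {lineno}"
            )
        try:
            records.append(SequenceRecord(rec.id, seq, circular=circular))
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | os.PathLike, records: list[SequenceRecord], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | os.PathLike, mate: str = "R1") -> list[Read]:
    """Read a Phred+33 FASTQ file; all reads are tagged with ``mate``.

    Truncated trailing records and seq/qual length mismatches raise
    :class:`FormatError`.
    """
    reads: list[Read] = []
    try:
        for rec in SeqIO.parse(os.fspath(path), "fastq"):
            qual = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.uint8)
            reads.append(Read(rec.id, str(rec.seq).upper(), qual, mate))
    except ValueError as exc:  # Biopython's truncation / length errors
        raise FormatError(f"{path}: {exc}") from exc
    return reads


def write_fastq(path: str | os.PathLike, reads: list[Read]) -> None:
    """Write four-line Phred+33 FASTQ (byte-exact round trip with read_fastq)."""
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(int(q) + 33) for q in r.qual)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_QUERY_OPS = {0: "M", 7: "M", 8: "M", 1: "M", 4: "S"}  # I folded into M (query side)


def parse_sam(path: str | os.PathLike) -> list[AlignmentRecord]:
    """Parse a headered SAM file into :class:`AlignmentRecord` objects.

    Positions are converted from the file's 1-based convention to internal
    0-based half-open coordinates (pysam does this conversion).  The FLAG is
    preserved bit-exactly.  ``@SQ`` lines are mandatory; records naming a
    reference absent from the header are rejected by the underlying parser.
    """
    # htslib demotes records naming an unknown reference to unmapped with a
    # warning; the dialect here treats that as a hard error, so RNAME fields
    # are validated against the header up front.
    sq_names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    for f in line.rstrip("\n").split("\t")[1:]:
                        if f.startswith("SN:"):
                            sq_names.add(f[3:])
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise FormatError(f"{path}: line {lineno}: fewer than 11 SAM columns")
            rname = fields[2]
            if rname not in ("*", "=") and rname not in sq_names:
                raise FormatError(
                    f"{path}: line {lineno}: alignment to reference {rname!r} "
                    f"absent from the @SQ header"
                )
    records: list[AlignmentRecord] = []
    try:
        with pysam.AlignmentFile(os.fspath(path), "r", check_sq=True) as af:
            if not af.header.get("SQ"):
                raise FormatError(f"{path}: SAM header lacks @SQ lines")
            for a in af.fetch(until_eof=True):
                if a.is_unmapped:
                    rec = AlignmentRecord(
                        read_id=a.query_name,
                        flag=a.flag,
                        seq=a.query_sequence or "",
                        qual=pysam.qualities_to_qualitystring(a.query_qualities) or "",
                    )
                else:
                    if a.reference_start < 0:
                        raise FormatError(
                            f"{path}: negative position for {a.query_name!r}"
                        )
                    cigar = []
                    for op, n in a.cigartuples or []:
                        sym = _QUERY_OPS.get(op)
                        if sym is None:
                            continue  # D/N/H/P: no query bases
                        if cigar and cigar[-1][0] == sym:
                            cigar[-1] = (sym, cigar[-1][1] + n)
                        else:
                            cigar.append((sym, n))
                    nm = a.get_tag("NM") if a.has_tag("NM") else 0
                    rec = AlignmentRecord(
                        read_id=a.query_name,
                        flag=a.flag,
                        ref_name=a.reference_name,
                        start=a.reference_start,
                        ref_end=a.reference_end,
                        cigar=cigar,
                        mapq=a.mapping_quality,
                        n_mismatch=int(nm),
                        seq=a.query_sequence or "",
                        qual=pysam.qualities_to_qualitystring(a.query_qualities) or "",
                    )
                records.append(rec)
    except FormatError:
        raise
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return records


def write_sam(
    path: str | os.PathLike,
    records: list[AlignmentRecord],
    references: list[SequenceRecord],
) -> None:
    """Write records as headered SAM (1-based positions, mandatory @SQ)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": r.id, "LN": len(r.seq)} for r in references],
    }
    ref_ids = {r.id: i for i, r in enumerate(references)}
    with pysam.AlignmentFile(os.fspath(path), "w", header=header) as af:
        for rec in records:
            a = pysam.AlignedSegment(af.header)
            a.query_name = rec.read_id
            a.flag = rec.flag
            a.query_sequence = rec.seq or None
            if rec.qual:
                a.query_qualities = pysam.qualitystring_to_array(rec.qual)
            if not rec.is_unmapped:
                if rec.ref_name not in ref_ids:
                    raise FormatError(
                        f"record {rec.read_id!r} aligned to unknown reference "
                        f"{rec.ref_name!r}"
                    )
                a.reference_id = ref_ids[rec.ref_name]
                a.reference_start = rec.start
                a.mapping_quality = rec.mapq
                a.cigarstring = rec.cigar_string
                a.set_tag("NM", rec.n_mismatch)
            af.write(a)
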