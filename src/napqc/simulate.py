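"""Stranded paired-end read simulator with a per-pair ground-truth table.

The generator emulates the sample composition the workflow is built to
measure: a TruSeq-stranded paired-end library from an in vitro transcribed
self-amplifying mRNA (~11 kb transcript, 41–47 nt poly-A tail), spiked with
low-percent plasmid-backbone and host genomic DNA, a trace of antisense
(reverse-strand IVT by-product) RNA, and unmappable library artifacts.

Strandedness follows fr-firststrand chemistry (TruSeq Stranded mRNA): R2
reads the strand of the originating transcript, R1 its reverse complement.
The downstream FLAG-based sense/antisense classification assumes exactly
this convention.

Two modeling points matter for tail-length estimation downstream:

* Replicon transcripts carry a short plasmid-derived *run-off* suffix after
  the templated tail (IVT on a linearised template reads through to the
  restriction cut).  Reads spanning tail -> run-off are the only reads that
  can prove a tail ended, so the suffix is what makes tail length measurable
  from short reads at all.
* Replicon fragments reproduce chop-fragmentation statistics: every molecule
  contributes exactly one 3'-terminal fragment, so junction-spanning reads
  occur at a realistic rate (~fragment_length/molecule_length of pairs)
  instead of vanishing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import Read, SequenceRecord, revcomp
from .references import ReferenceSet, build_reference_set

__all__ = [
    "SimulationConfig",
    "simulate_mrna_readset",
    "simulate_pdna_readset",
    "apply_errors",
    "demo_construct",
    "demo_reference_set",
    "write_truth",
]

MRNA_CLASSES = ("replicon_sense", "antisense", "backbone", "host", "artifact")
PDNA_CLASSES = ("plasmid", "host", "artifact")

TRUTH_COLUMNS = ["pair_id", "class", "source", "start", "end", "strand", "tail_len"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# index of each base byte in ACGT order (255 = not a base)
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def _default_mrna_fractions() -> dict[str, float]:
    # Mirrors the composition the workflow was demonstrated on: ~95% on-target
    # pairs, ~0.1% antisense, low-percent DNA carry-over, residual artifacts.
    return {
        "replicon_sense": 0.950,
        "antisense": 0.001,
        "backbone": 0.020,
        "host": 0.010,
        "artifact": 0.019,
    }


def _default_polya_dist() -> dict[int, float]:
    # Tail lengths 41-47 nt, uniform: templated 44-nt tail plus +/-3 nt of
    # polymerase slippage.
    return {n: 1.0 / 7.0 for n in range(41, 48)}


@dataclass
class SimulationConfig:
    """Parameters of one simulated library.

    Attributes
    ----------
    n_pairs : int
        Number of read pairs to emit.
    read_len : int
        Read length in nt (paired-end, both mates equal length).
    frag_len_mean, frag_len_sd : float
        Fragment-length distribution (truncated normal, redrawn until
        >= read_len).
    class_fractions : dict
        Proportion of pairs per class; must sum to 1 (tolerance 1e-9).
    polya_len_dist : dict[int, float]
        Discrete distribution of per-molecule tail lengths.
    error_rate : float
        Per-base substitution probability, in [0, 0.1].
    runoff_len : int
        Length of the plasmid-derived run-off suffix appended after the
        templated tail of replicon transcripts (0 disables).
    strandedness : str
        "fr-firststrand" (default), "fr-secondstrand" or "unstranded".
    tail_lowq_fraction, tail_lowq_len, tail_lowq_q : float, int, int
        Optional low-quality 3' tail injection to exercise quality trimming.
    base_quality : int
        Constant Phred score of simulated bases (errors are independent of
        quality by design).
    seed : int
        Random seed; identical seed => byte-identical output.
    """

    n_pairs: int
    read_len: int = 150
    frag_len_mean: float = 300.0
    frag_len_sd: float = 60.0
    class_fractions: dict[str, float] = field(default_factory=_default_mrna_fractions)
    polya_len_dist: dict[int, float] = field(default_factory=_default_polya_dist)
    error_rate: float = 0.001
    runoff_len: int = 8
    strandedness: str = "fr-firststrand"
    tail_lowq_fraction: float = 0.0
    tail_lowq_len: int = 20
    tail_lowq_q: int = 10
    base_quality: int = 37
    seed: int = 0

    def validate(self, classes: tuple[str, ...] = MRNA_CLASSES) -> None:
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")
        fr = self.class_fractions
        unknown = set(fr) - set(classes)
        if unknown:
            raise ValueError(f"unknown read classes: {sorted(unknown)}")
        if any(v < 0 for v in fr.values()):
            raise ValueError("class fractions must be non-negative")
        if not math.isclose(sum(fr.values()), 1.0, abs_tol=1e-9):
            raise ValueError(f"class fractions sum to {sum(fr.values())}, not 1")
        if not (0.0 <= self.error_rate <= 0.1):
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.read_len > self.frag_len_mean:
            raise ValueError("read_len must not exceed frag_len_mean")
        pd_ = self.polya_len_dist
        if pd_ and (any(k < 0 for k in pd_) or any(v < 0 for v in pd_.values())):
            raise ValueError("polya_len_dist must have non-negative support/weights")
        if self.strandedness not in ("fr-firststrand", "fr-secondstrand", "unstranded"):
            raise ValueError(f"unknown strandedness {self.strandedness!r}")


def apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``rate``.

    A substituted base becomes a uniformly chosen *different* base (N becomes
    a uniformly chosen ACGT base).
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    if rate == 0.0 or not seq:
        return seq
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = np.nonzero(mask)[0]
    # shift by 1..3 in ACGT order: always a different base
    shifts = rng.integers(1, 4, size=len(idx))
    old = _BASE_INDEX[arr[idx]]
    is_n = old == 255
    new = (old.astype(np.int64) + shifts) % 4
    if is_n.any():
        new[is_n] = rng.integers(0, 4, size=int(is_n.sum()))
    arr[idx] = _BASES[new]
    return arr.tobytes().decode()


def _draw_frag_len(rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int) -> int:
    """Truncated-normal fragment length, redrawn until in [lo, hi]."""
    if lo > hi:
        raise ValueError(f"fragment length floor {lo} exceeds source length {hi}")
    for _ in range(1000):
        f = int(round(rng.normal(mean, sd)))
        if lo <= f <= hi:
            return f
    raise ValueError("fragment length distribution incompatible with bounds")


def _pair_from_fragment(
    frag: str,
    read_len: int,
    pair_id: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[Read, Read]:
    """Build the R1/R2 reads of one fragment under the configured chemistry.

    ``frag`` is the originating transcript/template strand 5'->3'.  Under
    fr-firststrand R2 reads that strand and R1 its reverse complement.
    """
    fwd = frag[:read_len]
    rev = revcomp(frag)[:read_len]
    if cfg.strandedness == "fr-firststrand":
        r1_seq, r2_seq = rev, fwd
    elif cfg.strandedness == "fr-secondstrand":
        r1_seq, r2_seq = fwd, rev
    else:  # unstranded: random assignment
        if rng.random() < 0.5:
            r1_seq, r2_seq = rev, fwd
        else:
            r1_seq, r2_seq = fwd, rev
    r1_seq = apply_errors(r1_seq, cfg.error_rate, rng)
    r2_seq = apply_errors(r2_seq, cfg.error_rate, rng)
    q1 = np.full(len(r1_seq), cfg.base_quality, dtype=np.uint8)
    q2 = np.full(len(r2_seq), cfg.base_quality, dtype=np.uint8)
    if cfg.tail_lowq_fraction > 0.0:
        if rng.random() < cfg.tail_lowq_fraction:
            q1[-cfg.tail_lowq_len :] = cfg.tail_lowq_q
        if rng.random() < cfg.tail_lowq_fraction:
            q2[-cfg.tail_lowq_len :] = cfg.tail_lowq_q
    return Read(pair_id, r1_seq, q1, "R1"), Read(pair_id, r2_seq, q2, "R2")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def simulate_mrna_readset(
    config: SimulationConfig, refs: ReferenceSet
) -> tuple[list[Read], list[Read], pd.DataFrame]:
    """Simulate an mRNA drug-substance library with per-pair ground truth.

    Returns ``(r1_reads, r2_reads, truth)`` where ``truth`` has one row per
    pair: pair_id, class, source, start, end, strand, tail_len (replicon
    pairs only; coordinates are on the originating molecule).
    """
    config.validate(MRNA_CLASSES)
    rng = np.random.default_rng(config.seed)
    rl = config.read_len

    labels = [c for c in MRNA_CLASSES if config.class_fractions.get(c, 0.0) > 0.0]
    probs = np.array([config.class_fractions[c] for c in labels])
    probs = probs / probs.sum()
    class_idx = rng.choice(len(labels), size=config.n_pairs, p=probs)

    # replicon transcript molecules: body + A*t + run-off (cached per t)
    body = refs.ref2.seq[: refs.polya_start]
    runoff = refs.downstream_of_replicon(config.runoff_len) if config.runoff_len else ""
    tail_vals = np.array(sorted(config.polya_len_dist), dtype=np.int64)
    tail_probs = np.array([config.polya_len_dist[int(t)] for t in tail_vals], dtype=float)
    tail_probs = tail_probs / tail_probs.sum() if len(tail_probs) else tail_probs
    if len(tail_vals):
        tails_drawn = tail_vals[rng.choice(len(tail_vals), size=config.n_pairs, p=tail_probs)]
    else:
        tails_drawn = np.zeros(config.n_pairs, dtype=np.int64)
    molecule_cache = {int(t): body + "A" * int(t) + runoff for t in tail_vals} or {
        0: body + runoff
    }
    antisense_template = revcomp(refs.ref2.seq)

    r1s: list[Read] = []
    r2s: list[Read] = []
    rows: list[tuple] = []
    for i in range(config.n_pairs):
        pid = f"pair{i:07d}"
        cls = labels[class_idx[i]]
        tail = -1
        if cls == "replicon_sense":
            t = int(tails_drawn[i])
            tail = t
            mol = molecule_cache[t]
            M = len(mol)
            F = _draw_frag_len(rng, config.frag_len_mean, config.frag_len_sd, rl, M)
            # chop-model fragment: terminal with prob F/M, else interior end
            if rng.random() < F / M:
                e = M
            else:
                e = int(rng.integers(F, M))
            s = e - F
            frag, source, strand = mol[s:e], refs.ref2.id, "+"
        elif cls == "antisense":
            mol = antisense_template
            F = _draw_frag_len(rng, config.frag_len_mean, config.frag_len_sd, rl, len(mol))
            s = int(rng.integers(0, len(mol) - F + 1))
            e = s + F
            frag, source, strand = mol[s:e], refs.ref2.id, "-"
        elif cls in ("backbone", "host"):
            src = refs.ref3 if cls == "backbone" else refs.ref4
            F = _draw_frag_len(rng, config.frag_len_mean, config.frag_len_sd, rl, len(src))
            s = int(rng.integers(0, len(src) - F + 1))
            e = s + F
            strand = "+" if rng.random() < 0.5 else "-"
            frag = src.seq[s:e] if strand == "+" else revcomp(src.seq[s:e])
            source = src.id
        else:  # artifact: unmappable random sequence
            F = _draw_frag_len(
                rng, config.frag_len_mean, config.frag_len_sd, rl, 10 * rl
            )
            frag, source, strand = _random_seq(rng, F), "random", "."
            s, e = 0, F
        r1, r2 = _pair_from_fragment(frag, rl, pid, config, rng)
        r1s.append(r1)
        r2s.append(r2)
        rows.append((pid, cls, source, s, e, strand, tail))

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return r1s, r2s, truth


def _default_pdna_fractions() -> dict[str, float]:
    # ~98% plasmid-derived pairs plus host genomic carry-over from the
    # miniprep and a sliver of artifacts.
    return {"plasmid": 0.980, "host": 0.015, "artifact": 0.005}


def simulate_pdna_readset(
    config: SimulationConfig, refs: ReferenceSet
) -> tuple[list[Read], list[Read], pd.DataFrame]:
    """Simulate a pDNA shotgun library (classes: plasmid, host, artifact).

    Plasmid fragments are drawn uniformly around the circle; origin-crossing
    fragments are allowed and ``end`` in the truth table may exceed the
    plasmid length (modular coordinates).
    """
    if set(config.class_fractions) == set(MRNA_CLASSES):
        # caller left the mRNA default in place; swap in the pDNA default
        config = SimulationConfig(**{**config.__dict__, "class_fractions": _default_pdna_fractions()})
    config.validate(PDNA_CLASSES)
    rng = np.random.default_rng(config.seed)
    rl = config.read_len

    labels = [c for c in PDNA_CLASSES if config.class_fractions.get(c, 0.0) > 0.0]
    probs = np.array([config.class_fractions[c] for c in labels])
    probs = probs / probs.sum()
    class_idx = rng.choice(len(labels), size=config.n_pairs, p=probs)
    doubled = refs.ref1.seq * 2
    L = len(refs.ref1)

    r1s: list[Read] = []
    r2s: list[Read] = []
    rows: list[tuple] = []
    for i in range(config.n_pairs):
        pid = f"pair{i:07d}"
        cls = labels[class_idx[i]]
        if cls == "plasmid":
            F = _draw_frag_len(rng, config.frag_len_mean, config.frag_len_sd, rl, L)
            s = int(rng.integers(0, L))
            e = s + F
            strand = "+" if rng.random() < 0.5 else "-"
            frag = doubled[s:e] if strand == "+" else revcomp(doubled[s:e])
            source = refs.ref1.id
        elif cls == "host":
            F = _draw_frag_len(rng, config.frag_len_mean, config.frag_len_sd, rl, len(refs.ref4))
            s = int(rng.integers(0, len(refs.ref4) - F + 1))
            e = s + F
            strand = "+" if rng.random() < 0.5 else "-"
            frag = refs.ref4.seq[s:e] if strand == "+" else revcomp(refs.ref4.seq[s:e])
            source = refs.ref4.id
        else:
            F = _draw_frag_len(rng, config.frag_len_mean, config.frag_len_sd, rl, 10 * rl)
            frag, source, strand = _random_seq(rng, F), "random", "."
            s, e = 0, F
        r1, r2 = _pair_from_fragment(frag, rl, pid, config, rng)
        r1s.append(r1)
        r2s.append(r2)
        rows.append((pid, cls, source, s, e, strand, -1))

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return r1s, r2s, truth


def write_truth(path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Synthetic demonstration construct
# ---------------------------------------------------------------------------

def demo_construct(
    seed: int = 0,
    replicon_body_len: int = 11_148,
    polya_len: int = 44,
    backbone_len: int = 2_800,
    host_len: int = 40_000,
) -> tuple[SequenceRecord, tuple[int, int], int, SequenceRecord]:
    """Synthetic plasmid + host fixture for tests and demonstrations.

    The plasmid is random sequence shaped like the real construct: an
    ~11.2 kb replicon template (body + templated 44-nt poly-A) and a
    ~2.8 kb backbone, with a restriction-site remnant (``CCGCGGTC``)
    immediately downstream of the tail where the template is linearised.
    The host is a synthetic stand-in for a bacterial genome: random
    sequence, unrelated to the plasmid.

    Returns ``(plasmid, replicon_span, polya_len, host)``.
    """
    rng = np.random.default_rng(seed)
    span_len = replicon_body_len + polya_len
    L = span_len + backbone_len
    span_start = backbone_len // 3  # leaves backbone on both sides of the insert
    arr = _BASES[rng.integers(0, 4, size=L)].copy()
    span_end = span_start + span_len
    # templated tail, terminal on the span
    arr[span_end - polya_len : span_end] = ord("A")
    # keep the junction crisp: no accidental A-run bleeding into the tail
    arr[span_end - polya_len - 4 : span_end - polya_len] = np.frombuffer(b"CGTC", dtype=np.uint8)
    # linearisation-site remnant downstream of the tail (run-off suffix)
    arr[span_end : span_end + 8] = np.frombuffer(b"CCGCGGTC", dtype=np.uint8)
    plasmid = SequenceRecord("pDNA-demo", arr.tobytes().decode(), circular=True)
    host = SequenceRecord("host-demo", _random_seq(rng, host_len), circular=False)
    return plasmid, (span_start, span_end), polya_len, host


def demo_reference_set(seed: int = 0, **kwargs) -> ReferenceSet:
    """ReferenceSet built from :func:`demo_construct`."""
    plasmid, span, polya_len, host = demo_construct(seed, **kwargs)
    return build_reference_set(plasmid, span, polya_len, host)
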