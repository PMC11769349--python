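# Methods

This note records the models, conventions and numerical choices behind
`napqc`, and what the simulation-based tests do and do not demonstrate.

## The four-reference decomposition

The workflow rests on four references derived from one circular production
plasmid (Ref-1): the replicon transcript Ref-2 (sense strand, 5'→3',
including the templated poly-A tail, which is terminal by construction),
the backbone Ref-3 (Ref-1 with the replicon template span excised and the
circle re-joined across the cut, preserving circular order starting at the
span end) and the host genome Ref-4.  Internally all coordinates are
0-based half-open; spans crossing the circular origin are normalised by
doubling the plasmid string, so `end` may exceed the plasmid length by up
to one turn.  The invariant `len(ref3) == len(ref1) − span` and the
reconstruction property (Ref-2 + Ref-3 is a rotation of Ref-1) are enforced
and property-tested.

Whether the transcript reference should include the tail is genuinely open
— the tail can be templated (transcribed from the plasmid) or added
enzymatically.  Both are supported; the default is templated/included,
matching constructs that encode the tail in the plasmid.  With
`templated_tail=False` the tail is appended to Ref-2 only and Ref-1/Ref-3
are untouched.

## Read simulator

The simulator is first-class, tested code: it is the ground truth every
downstream stage is validated against.  It emulates a TruSeq-stranded
paired-end library from an IVT mRNA product:

* **Composition** (per pair, multinomial): replicon-sense 0.950, antisense
  0.001, backbone 0.020, host 0.010, artifact 0.019 by default — the
  on-target/off-target balance a well-purified drug substance shows, with
  antisense at the trace level typical of IVT by-product.  All fractions
  are free parameters.
* **Strandedness**: fr-firststrand — R2 reads the strand of the originating
  transcript, R1 its reverse complement.  The FLAG recipes of the triage
  assume exactly this; `fr-secondstrand` and `unstranded` switches exist
  for generality.
* **Fragments**: truncated normal (mean 300 nt, sd 60, redrawn until ≥ the
  150 nt read length).  Insert-size realism beyond this is not modelled.
* **Errors**: independent per-base substitutions at 0.1% by default (0.2%
  in the stress tests); a substituted base is a uniformly chosen different
  base.  Qualities are constant Q37 and independent of errors; an optional
  low-quality-tail injection (Q10 tails) exercises the trimmer separately.
  Indels, PCR duplicates, adapter read-through and coverage bias are out of
  scope.
* **Poly-A tails**: drawn per molecule from a discrete distribution,
  default uniform on 41–47 nt around a 44-nt templated tail (polymerase
  slippage on the homopolymer).  The annotated reference tail stays 44 nt
  regardless of the drawn length.

Two modelling choices matter specifically for tail estimation:

1. **Run-off suffix.**  Replicon molecules are `body + A^t + runoff`, where
   the run-off (default 8 nt) is the plasmid sequence immediately
   downstream of the template span — what run-off transcription on a
   template linearised at a downstream restriction site produces (the demo
   construct places a SacII-style remnant, `CCGCGGTC`, there).  This is not
   a cosmetic detail: the tail is otherwise terminal in every molecule, so
   no read could ever contain evidence that a tail *ended*, and
   junction-based tail measurement would be impossible in principle.
2. **Chop-model fragment ends.**  Enzymatic fragmentation chops each
   molecule into consecutive fragments, so every molecule contributes
   exactly one 3'-terminal fragment.  Sampling one fragment per pair
   reproduces these statistics as a mixture: with probability F/M (fragment
   over molecule length) the fragment is terminal, otherwise its end is
   uniform in the interior.  Uniform-start sampling would make
   tail-spanning reads vanishingly rare (~1/M instead of ~F/M).

The pDNA simulator restricts classes to {plasmid, host, artifact} (default
0.980/0.015/0.005), draws plasmid fragments uniformly around the circle
(origin-crossing fragments allowed, coordinates modular) and assigns
strands uniformly, as an unstranded DNA prep has no strand information.

What passing tests therefore show: the pipeline recovers known composition,
strandedness and tail lengths under substitution noise at Illumina-like
rates.  What they do not show: robustness to indels, adapter contamination,
quality-correlated errors, GC/priming coverage bias, or real secondary
structure — real libraries need the usual upstream QC.

## Quality trimming

Sliding-window Q30 trimming: 4-base windows scanned 5'→3', the read is cut
at the start of the first window whose mean quality drops below the
threshold (default Q30), and reads shorter than 36 nt after cutting are
dropped.  This mirrors the SLIDINGWINDOW:4:30 / MINLEN:36 convention of
common trimmers and is checked against a brute-force window-scan oracle.

## Aligner

A native seed-and-extend aligner is sufficient and exactly analysable at
construct scale (kilobases):

* exact k-mer seeds (k = 21) hashed over the reference; circular references
  are indexed on the doubled string with positions reduced modulo length,
  linear references are sentinel-padded so out-of-reference bases always
  mismatch and end up soft-clipped;
* seeds whose hit lists exceed 16 positions (homopolymers, repeats) are
  skipped unless nothing else seeds the read — repetitive seeds otherwise
  flood the candidate list and can evict the true diagonal;
* candidate diagonals are scored by ungapped extension, match +1 /
  mismatch −1, taking the maximal-scoring contiguous segment (terminal
  negative-scoring regions become soft clips; CIGAR is M/S only);
* a locus is reported if the aligned length is ≥ 30 nt and the mismatch
  fraction over it is ≤ 0.1 (generous enough that Q30-trimmed reads at
  ≤ 1% error essentially never fail their true source); otherwise the read
  is unmapped — a result, not an error;
* ties are broken deterministically (forward strand first, then lowest
  coordinate) and marked MAPQ 1; unique best loci get MAPQ 60.

Ungapped extension is a deliberate scope decision: the workflow quantifies
read *attribution* and clip-based tail lengths, not indel calling, and the
restriction keeps an exhaustive oracle exact — the acceptance suite checks
the reported locus against all-diagonal, both-strand exhaustive local
alignment.  No published parameter set exists for the original mapping
step, so the local/soft-clip behaviour here is this package's own
definition; anyone comparing against an end-to-end mapper should expect
differences on junction-spanning reads.  Pair flags follow SAM semantics;
the proper-pair bit requires FR orientation on one reference within a 2 kb
insert ceiling (circular-aware), chosen comfortably above any simulated
fragment.

## Triage

Phase 1 aligns all pairs to Ref-2 and records the pair-category split and
the overall mapping percentage (mapped reads over all reads).  "Unmapped"
is read-level (FLAG bit 4) throughout — exactly what `samtools view -f 4`
extracts — so the mate of a mapped read keeps its phase-1 attribution.
Phases 2 and 3 re-align the shrinking unmapped set to Ref-3 and Ref-4; the
residue is reported as unattributed rather than forced into a class.
Attribution is first-hit-wins, so the classes partition the reads exactly
(an enforced invariant).

Phase 4 aligns to Ref-1 and classifies primary mapped records with the
four stranded FLAG recipes.  The sense/antisense tally is restricted to
reads the identity phase attributed to the transcript: double-stranded DNA
contaminants (backbone maps to Ref-1 by construction) carry no
strand-of-origin information and would otherwise dilute a ~0.1% antisense
signal by an order of magnitude.  The antisense percentage is reported
with raw counts so alternative denominators can be recomputed, and an
`antisense_ref="ref2"` switch reuses the phase-1 alignments instead (the
two agree exactly on simulated data, since Ref-2 is the sense strand of
its span on Ref-1).

The pDNA triage is the two-phase analogue (Ref-1, then Ref-4).  Host hits
carry BLAST-style per-read metrics — query coverage (aligned length / read
length) and identity (1 − mismatches / aligned length) — with a call
threshold of ≥ 30 aligned nt and ≥ 0.95 identity; no published threshold
exists, so the values are configurable.

The percentage of still-unmapped reads *within* the pairs outside category
(i) is reported as `unmapped_within_secondary_pct`, computed directly from
phase-1 bits; the quantity is ambiguous in the field (it depends on which
re-mapping reference one counts against), so the definition here is stated
rather than assumed.

## Poly-A estimation

Informative reads are sense-strand records whose alignment enters the
annotated tail region, or ends within 5 nt upstream of it with a 3' soft
clip.  Per-read tail length = aligned bases at/after the tail start + the
maximal A-run at the start of the 3' clip, tolerating one non-A per ten
clipped bases (sequencing-error budget; the run must end on an A).  A read
has *fully spanned* the tail only if its clip continues past the run into
at least 5 non-A bases — the run-off suffix — otherwise the read ended
inside the homopolymer and its measurement is a right-censored lower
bound, counted as `n_lower_bound` and excluded from the summary.  The
point estimate is the median over fully-spanning reads (robust to ±1
jitter from error-absorbed runs); min/max/IQR describe the per-molecule
spread.  Zero informative reads produce a defined empty estimate, not an
exception.

Because alignment records store the read in aligned orientation and Ref-2
is the transcript, the 3' end is always the right-hand end; no separate
orientation recovery is needed beyond the reverse bit already encoded in
the record.

Known limitation: with 150 nt reads the estimator is blind to tails longer
than the read minus the minimum anchor (~120 nt), and on real libraries
where no sequence follows the tail (enzymatic tailing, no run-off), every
read is censored and the estimator honestly reports `n_support = 0` with
lower bounds only.

## Reporting

Percentages are kept at full precision internally and rounded only at
render time (2 decimals).  Run metadata (seed, resolved config, version)
is segregated from the comparable payload so re-rendering identical
results is byte-identical.  The EMA limit (330 ng DNA/mg RNA) is compared
inclusively, the FDA limit (10 ng DNA/dose) strictly, following the
wording of the respective guidance ("limit of" vs "less than").
Read-fraction→mass conversion is intentionally absent: it would require
library-prep efficiency and length normalisation that sequencing data
alone does not determine, so the mass limits are evaluated only against
supplied orthogonal measurements and the rendered report says so.

## Problem sizes

The default validation sizes — 50,000 pairs × 10 seeds for composition
recovery, 20,000 pairs for tail-distribution recovery, 1,000 reads for the
aligner/oracle concordance, 3.8 kb and 14 kb synthetic constructs —
were chosen so that 3σ binomial bounds on the smallest class (0.1%
antisense, ~50 pairs expected) are meaningfully tight while the full suite
stays a single-core, few-minute run.  The synthetic host fixture is 40 kb
of random sequence: a stand-in with the only property the triage needs
(seedable, unrelated to the plasmid), not a real genome.
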