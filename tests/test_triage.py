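"""Triage: FLAG recipes, pair categories, hierarchical attribution."""

import numpy as np
import pytest

from napqc.formats import (
    FLAG_FIRST,
    FLAG_SECOND,
    FLAG_UNMAPPED,
    AlignmentRecord,
    Read,
)
from napqc.simulate import SimulationConfig, simulate_mrna_readset, simulate_pdna_readset
from napqc.triage import (
    PairCategory,
    StrandClass,
    category_fractions,
    classify_pair,
    classify_strand,
    extract_unmapped,
    run_mrna_triage,
    run_pdna_triage,
)

from helpers import binom_3sigma, rc


def _rec(flag, rid="q", **kw):
    defaults = dict(ref_name="ref", start=0, ref_end=4, cigar=[("M", 4)],
                    seq="ACGT", qual="IIII")
    if flag & FLAG_UNMAPPED:
        defaults = dict(seq="ACGT", qual="IIII")
    defaults.update(kw)
    return AlignmentRecord(rid, flag, **defaults)


class TestClassifyPair:
    def test_both_mapped(self):
        assert classify_pair(_rec(FLAG_FIRST), _rec(FLAG_SECOND)) is PairCategory.BOTH_MAPPED

    def test_r1_only_mapped(self):
        assert classify_pair(
            _rec(FLAG_FIRST), _rec(FLAG_SECOND | FLAG_UNMAPPED)
        ) is PairCategory.R1_ONLY_MAPPED

    def test_r2_only_mapped(self):
        assert classify_pair(
            _rec(FLAG_FIRST | FLAG_UNMAPPED), _rec(FLAG_SECOND)
        ) is PairCategory.R2_ONLY_MAPPED

    def test_both_unmapped(self):
        assert classify_pair(
            _rec(FLAG_FIRST | FLAG_UNMAPPED), _rec(FLAG_SECOND | FLAG_UNMAPPED)
        ) is PairCategory.BOTH_UNMAPPED

    def test_pairing_precondition_enforced(self):
        with pytest.raises(ValueError):
            classify_pair(_rec(FLAG_SECOND), _rec(FLAG_FIRST))
        with pytest.raises(ValueError):
            classify_pair(_rec(FLAG_FIRST, rid="a"), _rec(FLAG_SECOND, rid="b"))


class TestClassifyStrand:
    """The four filter recipes: -f 128 -F 16 / -f 80 / -f 144 / -f 64 -F 16."""

    @pytest.mark.parametrize("flag,expected", [
        (163, StrandClass.SENSE),       # second-in-pair, forward
        (83, StrandClass.SENSE),        # first-in-pair, reverse
        (147, StrandClass.ANTISENSE),   # second-in-pair, reverse
        (99, StrandClass.ANTISENSE),    # first-in-pair, forward
        (77, StrandClass.UNSTRANDED),   # unmapped
        (141, StrandClass.UNSTRANDED),  # unmapped, second in pair
    ])
    def test_flag_recipes(self, flag, expected):
        kw = {} if not flag & FLAG_UNMAPPED else dict(ref_name=None)
        assert classify_strand(_rec(flag)) is expected

    def test_record_without_pair_bits_rejected(self):
        rec = _rec(FLAG_FIRST)
        rec.flag = 0x1  # paired only; simulate a malformed external record
        with pytest.raises(ValueError):
            classify_strand(rec)


class TestExtractUnmapped:
    def test_all_mapped_yields_empty(self):
        assert extract_unmapped([_rec(FLAG_FIRST), _rec(FLAG_SECOND)]) == []

    def test_returns_exactly_bit4_records(self):
        recs = [
            _rec(FLAG_FIRST, rid="a"),
            _rec(FLAG_SECOND | FLAG_UNMAPPED, rid="b"),
            _rec(FLAG_FIRST | FLAG_UNMAPPED, rid="c"),
            _rec(FLAG_SECOND, rid="d"),
        ]
        out = extract_unmapped(recs)
        assert [(r.id, r.mate) for r in out] == [("b", "R2"), ("c", "R1")]

    def test_reverse_mapped_record_not_returned_but_restorable(self):
        rec = _rec(FLAG_FIRST | 0x10, seq="AACC", qual="IIII")
        assert extract_unmapped([rec]) == []
        assert rec.original_read().seq == rc("AACC")


class TestCategoryFractions:
    def test_published_style_percentages(self):
        counts = {
            PairCategory.BOTH_MAPPED: 9_533,
            PairCategory.R1_ONLY_MAPPED: 467,
            PairCategory.R2_ONLY_MAPPED: 0,
            PairCategory.BOTH_UNMAPPED: 0,
        }
        pcts = category_fractions(counts)
        assert pcts[PairCategory.BOTH_MAPPED] == pytest.approx(95.33)
        assert pcts[PairCategory.R1_ONLY_MAPPED] == pytest.approx(4.67)
        assert sum(pcts.values()) == pytest.approx(100.0, abs=1e-6)

    def test_single_category_is_100(self):
        pcts = category_fractions({PairCategory.BOTH_MAPPED: 7})
        assert pcts[PairCategory.BOTH_MAPPED] == 100.0

    def test_equal_counts_quarter_each(self):
        pcts = category_fractions({c: 5 for c in PairCategory})
        assert all(p == 25.0 for p in pcts.values())

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            category_fractions({c: 0 for c in PairCategory})


def _sim(refs, n, fractions, seed=1, error=0.0):
    cfg = SimulationConfig(n_pairs=n, seed=seed, error_rate=error,
                           class_fractions=fractions)
    return simulate_mrna_readset(cfg, refs)


PURE = {"replicon_sense": 1.0, "antisense": 0.0, "backbone": 0.0,
        "host": 0.0, "artifact": 0.0}


class TestMrnaTriage:
    def test_pure_error_free_input_limits(self, small_refs):
        """100% on-target input: full mapping, no contamination, no antisense."""
        r1s, r2s, _ = _sim(small_refs, 800, PURE)
        res = run_mrna_triage(r1s, r2s, small_refs)
        assert res.overall_mapping_pct == 100.0
        assert res.category_counts[PairCategory.BOTH_MAPPED] == 800
        assert sum(res.category_counts.values()) == 800
        assert res.profile.counts["backbone_pdna"] == 0
        assert res.profile.counts["host_gdna"] == 0
        assert res.profile.counts["unattributed"] == 0
        assert res.antisense_count == 0 and res.antisense_pct == 0.0

    def test_partition_invariants(self, small_refs):
        fr = {"replicon_sense": 0.85, "antisense": 0.02, "backbone": 0.05,
              "host": 0.05, "artifact": 0.03}
        r1s, r2s, _ = _sim(small_refs, 1_500, fr, error=0.002)
        res = run_mrna_triage(r1s, r2s, small_refs)
        assert sum(res.category_counts.values()) == 1_500
        assert sum(res.profile.counts.values()) == 3_000
        assert sum(res.profile.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        # every read appears exactly once in the attribution table
        assert len(res.attribution) == 3_000
        assert res.attribution.duplicated(["pair_id", "read"]).sum() == 0
        # phase monotonicity: attribution phase matches attribution class
        by_class = res.attribution.groupby("class")["phase_attributed"].unique()
        assert set(by_class.get("replicon", [1])) == {1}
        assert set(by_class.get("backbone_pdna", [2])) == {2}
        assert set(by_class.get("host_gdna", [3])) == {3}
        assert set(by_class.get("unattributed", [3])) == {3}

    def test_class_fractions_recovered_against_truth(self, small_refs):
        fr = {"replicon_sense": 0.90, "antisense": 0.01, "backbone": 0.04,
              "host": 0.03, "artifact": 0.02}
        r1s, r2s, truth = _sim(small_refs, 4_000, fr, error=0.002)
        res = run_mrna_triage(r1s, r2s, small_refs)
        f = res.profile.fractions
        n = 4_000
        assert abs(f["replicon"] - 0.91) <= binom_3sigma(0.91, n)  # replicon+antisense
        assert abs(f["backbone_pdna"] - 0.04) <= binom_3sigma(0.04, n)
        assert abs(f["host_gdna"] - 0.03) <= binom_3sigma(0.03, n)
        assert abs(f["unattributed"] - 0.02) <= binom_3sigma(0.02, n)
        # triage attribution agrees with the truth table per pair
        merged = res.attribution.merge(truth, on="pair_id")
        cls_map = {"replicon_sense": "replicon", "antisense": "replicon",
                   "backbone": "backbone_pdna", "host": "host_gdna",
                   "artifact": "unattributed"}
        expected = merged["class_y"].map(cls_map)
        assert (merged["class_x"] == expected).mean() > 0.999

    def test_antisense_fraction_recovered(self, small_refs):
        fr = {"replicon_sense": 0.80, "antisense": 0.20, "backbone": 0.0,
              "host": 0.0, "artifact": 0.0}
        r1s, r2s, _ = _sim(small_refs, 2_000, fr, error=0.002)
        res = run_mrna_triage(r1s, r2s, small_refs)
        est = res.antisense_count / (res.antisense_count + res.sense_count)
        assert abs(est - 0.20) <= binom_3sigma(0.20, 2_000)

    def test_strand_involution_swapped_fractions_swap_counts(self, small_refs):
        fr = {"replicon_sense": 0.7, "antisense": 0.3, "backbone": 0.0,
              "host": 0.0, "artifact": 0.0}
        swapped = {**fr, "replicon_sense": 0.3, "antisense": 0.7}
        r1, r2, _ = _sim(small_refs, 1_500, fr, seed=5)
        res_a = run_mrna_triage(r1, r2, small_refs)
        r1, r2, _ = _sim(small_refs, 1_500, swapped, seed=5)
        res_b = run_mrna_triage(r1, r2, small_refs)
        tol = 3 * np.sqrt(1_500 * 0.3 * 0.7) * 2  # pair-level, both mates
        assert abs(res_a.antisense_count - res_b.sense_count) <= tol
        assert abs(res_a.sense_count - res_b.antisense_count) <= tol

    def test_antisense_ref2_variant_agrees(self, small_refs):
        fr = {"replicon_sense": 0.9, "antisense": 0.1, "backbone": 0.0,
              "host": 0.0, "artifact": 0.0}
        r1s, r2s, _ = _sim(small_refs, 1_000, fr)
        res1 = run_mrna_triage(r1s, r2s, small_refs, antisense_ref="ref1")
        res2 = run_mrna_triage(r1s, r2s, small_refs, antisense_ref="ref2")
        assert res1.antisense_count == res2.antisense_count
        assert res1.sense_count == res2.sense_count

    def test_duplicate_pair_ids_rejected(self, small_refs):
        r1s, r2s, _ = _sim(small_refs, 10, PURE)
        r1s[1] = Read(r1s[0].id, r1s[1].seq, r1s[1].qual, "R1")
        r2s[1] = Read(r2s[0].id, r2s[1].seq, r2s[1].qual, "R2")
        with pytest.raises(ValueError, match="duplicate"):
            run_mrna_triage(r1s, r2s, small_refs)

    def test_empty_read_set_rejected(self, small_refs):
        with pytest.raises(ValueError, match="empty"):
            run_mrna_triage([], [], small_refs)


class TestPdnaTriage:
    def test_pure_plasmid_fully_identified(self, small_refs):
        cfg = SimulationConfig(
            n_pairs=600, seed=2, error_rate=0.0,
            class_fractions={"plasmid": 1.0, "host": 0.0, "artifact": 0.0})
        r1s, r2s, _ = simulate_pdna_readset(cfg, small_refs)
        res = run_pdna_triage(r1s, r2s, small_refs)
        assert res.overall_mapping_pct == 100.0
        assert res.profile.counts["host_gdna"] == 0
        assert len(res.host_hits) == 0

    def test_host_spike_detected_with_full_identity(self, small_refs):
        cfg = SimulationConfig(
            n_pairs=2_000, seed=3, error_rate=0.0,
            class_fractions={"plasmid": 0.98, "host": 0.02, "artifact": 0.0})
        r1s, r2s, truth = simulate_pdna_readset(cfg, small_refs)
        res = run_pdna_triage(r1s, r2s, small_refs)
        n_host_pairs = (truth["class"] == "host").sum()
        assert res.profile.counts["host_gdna"] == 2 * n_host_pairs
        assert (res.host_hits["identity"] == 1.0).all()
        assert (res.host_hits["query_coverage"] == 1.0).all()

    def test_single_substitution_identity_arithmetic(self, small_refs):
        """A host read with one mid-read substitution reports identity 149/150."""
        host = small_refs.ref4.seq
        frag = host[1_000:1_300]
        r2 = frag[:150]
        r2 = r2[:75] + {"A": "C", "C": "G", "G": "T", "T": "A"}[r2[75]] + r2[76:]
        q = np.full(150, 37, dtype=np.uint8)
        r1s = [Read("p0", rc(frag)[:150], q.copy(), "R1")]
        r2s = [Read("p0", r2, q.copy(), "R2")]
        res = run_pdna_triage(r1s, r2s, small_refs)
        row = res.host_hits[res.host_hits["read"] == "R2"].iloc[0]
        assert row["identity"] == pytest.approx(149 / 150)
        assert row["query_coverage"] == 1.0
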