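"""Classification, run context, rate partitioning, repair efficiencies."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluctspec import (
    CATEGORIES,
    MutationRecord,
    MutationSpectrum,
    annotate_run_context,
    classify_isolate,
    classify_mutation,
    fraction_in_runs,
    partition_rates,
    relative_rates,
    repair_efficiency,
    scan_runs,
)
from fluctspec._util import round_sig

REF = "ATGCAAAAGTTTCGATCGGGCATAC"
#      123456789...


class TestScanRuns:
    def test_simple(self):
        assert scan_runs("ATGCAAAAGT") == ((5, 4, "A"),)

    @settings(derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=60))
    def test_tiles_all_maximal_runs(self, seq):
        runs = scan_runs(seq)
        for start, length, base in runs:
            s = start - 1
            assert seq[s : s + length] == base * length
            assert s == 0 or seq[s - 1] != base
            assert s + length == len(seq) or seq[s + length] != base
        # no maximal run of length >= 2 is missed
        covered = set()
        for start, length, _ in runs:
            covered.update(range(start, start + length))
        for i in range(len(seq) - 1):
            if seq[i] == seq[i + 1]:
                assert (i + 1) in covered


class TestClassification:
    def test_substitution(self):
        assert classify_mutation(REF, 10, "T", "C") == "base substitution"

    def test_one_bp_indels(self):
        assert classify_mutation(REF, 5, "A", "") == "1-bp deletion"
        assert classify_mutation(REF, 5, "", "A") == "1-bp insertion"

    def test_multi_bp_events_are_other(self):
        # the published spectra's "other" events: a 2-bp insertion, a 2-bp
        # deletion, a 13-bp duplication
        assert classify_mutation(REF, 10, "TT", "") == "other"
        assert classify_mutation(REF, 10, "", "TT") == "other"
        assert classify_mutation(REF, 1, "", "ATGCAAAAGTTTC") == "other"

    def test_complex_window_boundary(self):
        assert classify_mutation(REF, 10, "T", "C", neighbors=[20]) == "complex"
        assert (
            classify_mutation(REF, 10, "T", "C", neighbors=[21])
            == "base substitution"
        )

    def test_ref_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_mutation(REF, 10, "G", "C")

    def test_isolate_classification_matches_pairing_oracle(self):
        # exhaustive pairwise-window oracle on a toy isolate
        events = [
            MutationRecord("iso1", 3, "G", "A"),
            MutationRecord("iso1", 10, "T", "C"),
            MutationRecord("iso1", 18, "G", "T"),
        ]
        out = classify_isolate(REF, events, complex_window=10)
        positions = [e.position for e in events]
        for rec in out:
            close = any(
                0 < abs(p - rec.position) <= 10 for p in positions
            )
            assert (rec.category == "complex") == close

    def test_order_invariance(self):
        events = [
            MutationRecord("iso1", 3, "G", "A"),
            MutationRecord("iso1", 10, "T", "C"),
        ]
        a = classify_isolate(REF, events)
        b = classify_isolate(REF, list(reversed(events)))
        assert {(r.position, r.category) for r in a} == {
            (r.position, r.category) for r in b
        }


class TestRunContext:
    def test_deletion_in_run_left_normalized(self):
        # REF has AAAA at 5-8: deleting any A reports run 4, position 5
        for pos in range(5, 9):
            rec = MutationRecord("i", pos, "A", "")
            out = annotate_run_context(REF, rec)
            assert out.run_length == 4
            assert out.position == 5

    def test_deletion_outside_run(self):
        rec = annotate_run_context("GCATG", MutationRecord("i", 3, "A", ""))
        assert rec.run_length == 1

    def test_insertion_adjacent_to_run(self):
        # GGG at 18-20: inserting a G at any adjacent placement sees run 3
        for pos in (18, 19, 20, 21):
            rec = annotate_run_context(REF, MutationRecord("i", pos, "", "G"))
            assert rec.run_length == 3

    def test_insertion_no_neighbors(self):
        rec = annotate_run_context(REF, MutationRecord("i", 2, "", "C"))
        assert rec.run_length == 1

    def test_substitution_gets_site_run_length(self):
        rec = annotate_run_context(REF, MutationRecord("i", 6, "A", "G"))
        assert rec.run_length == 4

    @pytest.mark.parametrize("run_len", range(2, 9))
    def test_placement_invariance_exhaustive(self, run_len):
        # every equivalent placement of a 1-bp indel within a run (up to
        # length 8) must report the same run length and normalized position
        ref = "C" + "A" * run_len + "G"
        del_out = {
            (r.run_length, r.position)
            for r in (
                annotate_run_context(ref, MutationRecord("i", p, "A", ""))
                for p in range(2, 2 + run_len)
            )
        }
        assert del_out == {(run_len, 2)}
        ins_out = {
            (r.run_length, r.position)
            for r in (
                annotate_run_context(ref, MutationRecord("i", p, "", "A"))
                for p in range(2, 3 + run_len)
            )
        }
        assert ins_out == {(run_len, 2)}


class TestFractionInRuns:
    def _spectrum_with_deletions(self, run_lengths):
        recs = [
            MutationRecord(
                f"i{k}", 1, "A", "", category="1-bp deletion",
                run_length=rl,
            )
            for k, rl in enumerate(run_lengths)
        ]
        return MutationSpectrum(
            genotype="t",
            counts={"1-bp deletion": len(recs)},
            records=recs,
        )

    def test_all_and_none(self):
        s = self._spectrum_with_deletions([5] * 8)
        assert fraction_in_runs(s, "1-bp deletion", 3) == 1.0
        s = self._spectrum_with_deletions([1, 2, 1])
        assert fraction_in_runs(s, "1-bp deletion", 3) == 0.0

    def test_nineteen_of_twenty(self):
        # mirrors the ~95%-of-deletions-in-runs observation for
        # repair-deficient spectra
        s = self._spectrum_with_deletions([4] * 19 + [1])
        assert fraction_in_runs(s, "1-bp deletion", 3) == 0.95

    def test_empty_category_flagged(self):
        s = self._spectrum_with_deletions([4])
        with pytest.raises(ValueError):
            fraction_in_runs(s, "base substitution", 3)


class TestPartitionRates:
    def test_published_partition(self, published_spectra_by_genotype):
        msh2 = published_spectra_by_genotype["msh2"]
        part = partition_rates(500e-8, msh2)
        r = part.rounded()
        assert r["base substitution"] == 170e-8
        assert r["1-bp deletion"] == 250e-8
        assert r["1-bp insertion"] == 60e-8

    def test_published_wildtype_deletions(self, published_spectra_by_genotype):
        wt = published_spectra_by_genotype["wild type"]
        part = partition_rates(60e-8, wt)
        assert part.rounded()["1-bp deletion"] == 8.4e-8

    def test_zero_count_upper_bound(self):
        from fluctspec.datasets import rtt109_spectra

        (double,) = rtt109_spectra()
        part = partition_rates(1100e-8, double)
        assert part.bound_flags["complex"]
        assert part.rounded()["complex"] == 23e-8

    def test_total_conserved_exactly(self, simple_spectrum):
        part = partition_rates(3.7e-7, simple_spectrum)
        non_bound = sum(
            r for c, r in part.rates.items() if not part.bound_flags[c]
        )
        assert non_bound == pytest.approx(3.7e-7, rel=1e-12)

    def test_empty_spectrum_rejected(self):
        s = MutationSpectrum(genotype="x", counts={c: 0 for c in CATEGORIES})
        with pytest.raises(ValueError):
            partition_rates(1e-7, s)


class TestRelativeRates:
    def test_published_ratios(self, published_spectra_by_genotype):
        wt = partition_rates(60e-8, published_spectra_by_genotype["wild type"])
        msh2 = partition_rates(500e-8, published_spectra_by_genotype["msh2"])
        rel = relative_rates(msh2, wt)
        assert round_sig(rel["total"]) == 8.3
        assert round_sig(rel["1-bp deletion"]) == 30
        assert round_sig(rel["base substitution"]) == 3.5
        assert round_sig(rel["1-bp insertion"]) == 50

    def test_self_relative_is_one(self, published_spectra_by_genotype):
        wt = partition_rates(60e-8, published_spectra_by_genotype["wild type"])
        rel = relative_rates(wt, wt)
        assert all(v == pytest.approx(1.0) for v in rel.values())


class TestRepairEfficiency:
    def test_published_efficiencies(self, published_spectra_by_genotype,
                                    published_totals):
        wt_total, _ = published_totals["wild type"]
        m_total, _ = published_totals["msh2"]
        wt = partition_rates(wt_total, published_spectra_by_genotype["wild type"])
        m = partition_rates(m_total, published_spectra_by_genotype["msh2"])
        bb = repair_efficiency(
            wt.rates["base substitution"], m.rates["base substitution"]
        )
        dl = repair_efficiency(wt.rates["1-bp deletion"], m.rates["1-bp deletion"])
        il = repair_efficiency(wt.rates["1-bp insertion"], m.rates["1-bp insertion"])
        total = repair_efficiency(wt_total, m_total)
        assert round(bb) == 72
        assert round(dl) == 97
        assert round(il) == 98
        assert round(total) == 88

    def test_degenerate_values(self):
        assert repair_efficiency(1e-7, 1e-7) == 0.0
        assert repair_efficiency(0.0, 1e-7) == 100.0

    def test_monotonicity(self):
        # antitone in the proficient rate, isotone in the deficient rate
        lo = repair_efficiency(1e-8, 1e-7)
        hi = repair_efficiency(5e-8, 1e-7)
        assert hi < lo
        assert repair_efficiency(1e-8, 2e-7) > repair_efficiency(1e-8, 1e-7)

    def test_inverted_rates_warn(self):
        with pytest.warns(UserWarning):
            repair_efficiency(2e-7, 1e-7)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            repair_efficiency(1e-8, 0.0)
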