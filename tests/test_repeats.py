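"""Tandem-repeat detection, CR decomposition, haplotype statistics, folding."""

import numpy as np
import pytest

from larkmt.datasets import MONGOLICA_COMBINED_UNIT, REPEAT_UNIT_TABLE
from larkmt.repeats import (
    build_consensus,
    build_repeat_unit_set,
    decompose_cr,
    detect_subunit_fusion,
    detect_tandem_repeats,
    flag_divergent_initial_unit,
    fold_score,
    unit_similarity_stats,
)
from larkmt.simulate import CR2Spec, simulate_cr2

from conftest import random_dna


class TestDetection:
    def test_planted_array_recovered_exactly(self):
        """4 x 37 bp units between a 60 bp 5NR and a 40 bp 3NR."""
        spec = CR2Spec(
            five_nr_len=60, period=37, copies=4.0,
            per_unit_substitution_rate=0.0, three_nr_len=40,
        )
        cr2, truth = simulate_cr2(spec, seed=2)
        calls = detect_tandem_repeats(cr2)
        assert len(calls) == 1
        c = calls[0]
        assert (c.start, c.end, c.period, c.copies) == (
            truth["tr_start"], truth["tr_end"], 37, 4.0,
        )

    def test_random_sequence_yields_no_calls(self):
        rng = np.random.default_rng(9)
        seq = random_dna(rng, 200)
        assert detect_tandem_repeats(seq, min_period=10, min_copies=1.9,
                                     min_identity=80.0) == []
        # oracle: no period tiles >= 1.9 copies at >= 80% identity anywhere
        n = len(seq)
        for p in range(10, n // 2 + 1):
            for s in range(0, n - 2 * p + 1):
                span = min(n - s, int(1.9 * p) + p)
                m = sum(seq[i] == seq[i + p] for i in range(s, s + span - p))
                assert m / (span - p) < 0.95  # no near-perfect tiling exists

    def test_fused_period_reports_subperiod_alternative(self, table_haplotypes):
        h = table_haplotypes["Melanocorypha mongolica"]
        rng = np.random.default_rng(21)
        cr2 = random_dna(rng, 50) + (h["H_1"] + h["H_2"]) * 3 + random_dna(rng, 50)
        calls = detect_tandem_repeats(cr2)
        assert len(calls) == 1
        assert calls[0].period == 64
        assert 32 in calls[0].alt_periods

    def test_parameter_recovery_across_simulations(self):
        """Period exact and copies within one partial unit in >= 45/50."""
        ok = 0
        for i in range(50):
            rng = np.random.default_rng(100 + i)
            spec = CR2Spec(
                five_nr_len=int(rng.integers(30, 90)),
                period=int(rng.integers(20, 71)),
                copies=float(rng.integers(2, 9)),
                per_unit_substitution_rate=float(rng.uniform(0, 0.02)),
                three_nr_len=int(rng.integers(30, 90)),
            )
            cr2, truth = simulate_cr2(spec, seed=1000 + i)
            calls = detect_tandem_repeats(cr2)
            if len(calls) != 1:
                continue
            c = calls[0]
            if c.period == spec.period and abs(c.copies - truth["copies"]) <= 1.0:
                ok += 1
        assert ok >= 45


class TestDecomposition:
    def test_concatenation_invariant_on_simulations(self):
        for i in range(50):
            rng = np.random.default_rng(200 + i)
            spec = CR2Spec(
                five_nr_len=int(rng.integers(20, 80)),
                period=int(rng.integers(15, 60)),
                copies=float(rng.uniform(2, 6)),
                per_unit_substitution_rate=float(rng.uniform(0, 0.02)),
                three_nr_len=int(rng.integers(20, 80)),
            )
            cr2, _ = simulate_cr2(spec, seed=2000 + i)
            for call in detect_tandem_repeats(cr2):
                assert decompose_cr(cr2, call).sequence == cr2

    def test_planted_decomposition_matches_truth(self):
        spec = CR2Spec(per_unit_substitution_rate=0.0)
        cr2, truth = simulate_cr2(spec, seed=2)
        call = detect_tandem_repeats(cr2)[0]
        d = decompose_cr(cr2, call)
        assert d.five_nr == truth["five_nr"]
        assert list(d.units) == truth["units"]
        assert d.three_nr == truth["three_nr"]

    def test_call_covering_whole_region(self):
        cr = "ACGTTGCATG" * 4
        call = detect_tandem_repeats(cr)[0]
        d = decompose_cr(cr, call)
        assert d.five_nr == "" and d.three_nr == ""

    def test_truncated_final_unit_kept(self):
        rng = np.random.default_rng(8)
        unit = random_dna(rng, 37)
        cr = random_dna(rng, 30) + unit * 3 + unit[:26] + random_dna(rng, 30)
        call = detect_tandem_repeats(cr)[0]
        d = decompose_cr(cr, call)
        # the truncated unit stays in the array (a chance flank match may
        # lengthen it by a base or two, but it remains a partial unit)
        assert len(d.units[-1]) < call.period
        assert abs(len(d.units[-1]) - 26) <= 2
        assert d.sequence == cr


class TestConsensus:
    def test_published_units_rebuild_their_consensus(self, table_haplotypes):
        h = table_haplotypes["Eremophila alpestris"]
        cons = build_consensus([h["A_1"], h["A_2"], h["A_3"]])
        assert cons == REPEAT_UNIT_TABLE["Eremophila alpestris"].reference

    def test_identical_units(self):
        assert build_consensus(["ACGT", "ACGT"]) == "ACGT"

    def test_matches_column_tally_oracle(self):
        rng = np.random.default_rng(4)
        master = random_dna(rng, 30)
        units = []
        for _ in range(5):
            u = list(master)
            for pos in rng.choice(30, size=3, replace=False):
                u[pos] = "ACGT"[rng.integers(0, 4)]
            units.append("".join(u))
        cons = build_consensus(units)
        for col in range(30):
            counts = {}
            for u in units:
                counts[u[col]] = counts.get(u[col], 0) + 1
            assert counts[cons[col]] == max(counts.values())


class TestSimilarity:
    def test_alpestris_range(self, table_haplotypes):
        us = build_repeat_unit_set(
            list(table_haplotypes["Eremophila alpestris"].values()),
            names=list(table_haplotypes["Eremophila alpestris"]),
        )
        stats = unit_similarity_stats(us)
        assert round(stats.min_sim, 1) == 98.0
        assert round(stats.max_sim, 1) == 100.0

    def test_heinei_identity(self, table_haplotypes):
        us = build_repeat_unit_set(
            list(table_haplotypes["Alaudala heinei"].values()),
            names=list(table_haplotypes["Alaudala heinei"]),
        )
        stats = unit_similarity_stats(us)
        assert (stats.min_sim, stats.max_sim) == (100.0, 100.0)

    def test_cheleensis_exclusions_and_minimum(self, table_haplotypes):
        """B_6 (internal deletion) excluded; min among the rest is 94.1%."""
        haps = table_haplotypes["Alaudala cheleensis"]
        us = build_repeat_unit_set(list(haps.values()), names=list(haps))
        assert us.excluded == frozenset({"B_6"})
        stats = unit_similarity_stats(us)
        assert round(stats.min_sim, 1) == 94.1
        assert round(stats.max_sim, 1) == 100.0

    def test_cinerea_internal_deletion_excluded(self, table_haplotypes):
        """G_1 (divergent initial) and G_3 (internal deletion inside the
        TA repeat) are excluded; the remaining units are identical."""
        haps = table_haplotypes["Calandrella cinerea"]
        us = build_repeat_unit_set(list(haps.values()), names=list(haps))
        assert us.excluded == frozenset({"G_1", "G_3"})
        stats = unit_similarity_stats(us)
        assert (stats.min_sim, stats.max_sim) == (100.0, 100.0)

    def test_single_haplotype_gives_null_stats(self):
        us = build_repeat_unit_set(["ACGTACGTACGT"])
        stats = unit_similarity_stats(us)
        assert stats.min_sim is None and stats.max_sim is None

    def test_multiplicities_sum_to_unit_count(self):
        units = ["ACGTA", "ACGTA", "ACGTT", "ACGTA"]
        us = build_repeat_unit_set(units)
        assert sum(h.multiplicity for h in us.haplotypes) == len(units)


class TestDivergentInitial:
    def test_arvensis_first_unit_flagged(self, table_haplotypes):
        h = table_haplotypes["Alauda arvensis"]
        assert flag_divergent_initial_unit([h["D_1"], h["D_2"]], threshold=90)

    def test_alpestris_first_unit_not_flagged(self, table_haplotypes):
        h = table_haplotypes["Eremophila alpestris"]
        assert not flag_divergent_initial_unit([h["A_1"], h["A_2"], h["A_3"]], 90)

    def test_identical_units_not_flagged(self):
        assert not flag_divergent_initial_unit(["ACGTACGTAC"] * 3, 90)

    def test_simulated_divergent_unit_detected(self):
        spec = CR2Spec(divergent_first_unit=True, per_unit_substitution_rate=0.0)
        _, truth = simulate_cr2(spec, seed=12)
        assert flag_divergent_initial_unit(truth["units"], threshold=90)


class TestFusion:
    def test_mongolica_combined_unit(self):
        rec = detect_subunit_fusion(MONGOLICA_COMBINED_UNIT, max_diff_frac=0.35)
        assert rec is not None and rec.hamming == 9

    def test_perfect_duplication(self):
        rec = detect_subunit_fusion("ACGTACGT")
        assert rec is not None and rec.hamming == 0

    def test_odd_length_is_null(self):
        assert detect_subunit_fusion(
            REPEAT_UNIT_TABLE["Eremophila alpestris"].reference
        ) is None

    def test_simulated_fusion_matches_planted_divergence(self):
        spec = CR2Spec(period=64, fused_halves=True, per_unit_substitution_rate=0.0)
        _, truth = simulate_cr2(spec, seed=6)
        rec = detect_subunit_fusion(truth["master_unit"], max_diff_frac=0.35)
        assert rec is not None and rec.hamming == truth["fused_hamming"]


def _enumerate_fold(seq, min_loop=3):
    """Exhaustive enumeration of nested structures (independent oracle)."""
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}

    def rec(lo, hi):
        if hi - lo <= min_loop:
            return 0
        best = rec(lo + 1, hi)
        for k in range(lo + min_loop + 1, hi):
            if (seq[lo], seq[k]) in pairs:
                best = max(best, 1 + rec(lo + 1, k) + rec(k + 1, hi))
        return best

    return rec(0, len(seq))


class TestFold:
    def test_unpairable_sequence(self):
        assert fold_score("AAAAAA").pairs == 0

    def test_simple_hairpin(self):
        fs = fold_score("GGGAAACCC", min_loop=3)
        assert fs.pairs == 3
        assert fs.structure == "(((...)))"

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            seq = random_dna(rng, 40)[:18]
            assert fold_score(seq).pairs == _enumerate_fold(seq)

    def test_structure_is_balanced_and_counts_pairs(self):
        rng = np.random.default_rng(16)
        for _ in range(10):
            seq = random_dna(rng, 30)
            fs = fold_score(seq)
            assert fs.structure.count("(") == fs.structure.count(")") == fs.pairs

    def test_substructure_embeds_in_superstring(self):
        rng = np.random.default_rng(26)
        for _ in range(10):
            a, b = random_dna(rng, 12), random_dna(rng, 15)
            assert fold_score(a + b).pairs >= fold_score(b).pairs
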