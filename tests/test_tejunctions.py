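"""Virus-host chimeric junctions, TE tables, hit resolution, end test."""

from __future__ import annotations

import math
import random

import numpy as np
import pytest

from svmeta.models import ReadAlignment
from svmeta.refdata import ACMNPV_TE_JUNCTIONS
from svmeta.tejunctions import (
    ChimericJunction,
    TEInsertion,
    build_te_table,
    classify_completeness,
    dedupe_pcr,
    detect_junctions,
    end_enrichment_test,
    resolve_long_read_hits,
    te_insertion_frequency,
    validate_chimera_flanks,
)


def aln(read_id, rs, re, target, kind, ts=None, te=None, score=None,
        read_length=151, strand="+"):
    span = re - rs + 1
    return ReadAlignment(
        read_id, rs, re, target, kind,
        ts or 1, te or span, strand,
        score if score is not None else 2.0 * span, read_length,
    )


class TestDetectJunctions:
    def test_clean_junction_passes_all_rules(self):
        hits = [
            aln("r1", 1, 80, "virus", "virus"),
            aln("r1", 81, 150, "te1", "host_te"),
        ]
        (j,) = detect_junctions(hits)
        assert j.overlap == 0
        assert j.virus_segment.target_kind == "virus"

    def test_short_host_segment_rejected(self):
        hits = [
            aln("r1", 1, 135, "virus", "virus"),
            aln("r1", 136, 150, "te1", "host_te"),  # 15 bp
        ]
        assert detect_junctions(hits) == []

    def test_excessive_overlap_rejected(self):
        hits = [
            aln("r1", 1, 90, "virus", "virus"),
            aln("r1", 66, 150, "te1", "host_te"),  # overlap 25
        ]
        assert detect_junctions(hits) == []

    def test_small_gap_allowed_but_not_large(self):
        base = [aln("r1", 1, 75, "virus", "virus")]
        ok = detect_junctions(base + [aln("r1", 80, 151, "te1", "host_te")])
        assert len(ok) == 1 and ok[0].overlap == -4
        too_far = detect_junctions(base + [aln("r1", 82, 151, "te1", "host_te")])
        assert too_far == []

    def test_short_total_alignment_rejected(self):
        hits = [
            aln("r1", 1, 60, "virus", "virus"),
            aln("r1", 61, 125, "te1", "host_te"),  # total 125 < 130
        ]
        assert detect_junctions(hits) == []

    def test_order_independent(self):
        hits = [
            aln("r1", 1, 80, "virus", "virus"),
            aln("r1", 81, 150, "te1", "host_te"),
            aln("r1", 85, 150, "te2", "host_te"),
            aln("r2", 1, 70, "virus", "virus"),
            aln("r2", 71, 151, "te1", "host_te"),
        ]
        reference = detect_junctions(hits)
        rng = random.Random(0)
        for _ in range(10):
            shuffled = hits[:]
            rng.shuffle(shuffled)
            got = detect_junctions(shuffled)
            assert [(j.read_id, j.host_segment.target_id) for j in got] == [
                (j.read_id, j.host_segment.target_id) for j in reference
            ]

    def test_superfamily_annotation(self):
        hits = [
            aln("r1", 1, 80, "virus", "virus"),
            aln("r1", 81, 150, "te1", "host_te"),
        ]
        (j,) = detect_junctions(hits, superfamily_map={"te1": "piggyBac"})
        assert j.superfamily == "piggyBac"


def junction(vts=100, vte=180, hts=1, hte=70, host="te1"):
    v = aln("r", 1, 80, "virus", "virus", ts=vts, te=vte)
    h = aln("r", 81, 150, host, "host_te", ts=hts, te=hte)
    return ChimericJunction("r", v, h, 0)


class TestDedupePcr:
    def test_identical_keys_collapse(self):
        unique, total = dedupe_pcr([junction(), junction(), junction()])
        assert (len(unique), total) == (1, 3)

    def test_all_distinct(self):
        js = [junction(vte=180 + i) for i in range(4)]
        unique, total = dedupe_pcr(js)
        assert (len(unique), total) == (4, 4)

    def test_mixed_keys(self):
        js = [junction(), junction(), junction(host="te2")]
        unique, total = dedupe_pcr(js)
        assert (len(unique), total) == (2, 3)
        assert len(unique) <= total


class TestBuildTeTable:
    def test_published_superfamily_rows_total_correctly(self):
        unique = {sf: u for sf, (u, t, f) in ACMNPV_TE_JUNCTIONS.items()}
        total = {sf: t for sf, (u, t, f) in ACMNPV_TE_JUNCTIONS.items()}
        freqs = {sf: f for sf, (u, t, f) in ACMNPV_TE_JUNCTIONS.items()}
        table = build_te_table(unique, total, freqs)
        total_row = table[table.superfamily == "Total"].iloc[0]
        assert total_row.unique_reads == 4993
        assert total_row.reads_with_duplicates == 6742
        assert total_row.insertion_frequency_pct == pytest.approx(1.554)

    def test_rows_sorted_by_unique_count(self):
        table = build_te_table(
            {"a": 5, "b": 50, "c": 20}, {"a": 6, "b": 55, "c": 21},
            {"a": 0.1, "b": 0.2, "c": 0.3},
        )
        assert list(table.superfamily[:3]) == ["b", "c", "a"]

    def test_single_row_totals_equal_row(self):
        table = build_te_table({"a": 5}, {"a": 8}, {"a": 0.4})
        assert list(table.unique_reads) == [5, 5]
        assert list(table.reads_with_duplicates) == [8, 8]

    def test_default_frequency_formula(self):
        assert te_insertion_frequency(0, 1000) == 0.0
        assert te_insertion_frequency(10, 990) == pytest.approx(1.0)


class TestResolveLongReadHits:
    def test_best_score_wins_among_overlaps(self):
        a = aln("r", 100, 500, "te1", "host_te", score=100, read_length=10_000)
        b = aln("r", 300, 700, "te2", "host_te", score=80, read_length=10_000)
        assert resolve_long_read_hits([a, b]) == [a]

    def test_disjoint_hits_all_kept(self):
        a = aln("r", 100, 500, "te1", "host_te", read_length=10_000)
        b = aln("r", 600, 900, "te2", "host_te", read_length=10_000)
        assert resolve_long_read_hits([b, a]) == [a, b]

    def test_tie_break_lower_read_start_then_target_id(self):
        a = aln("r", 100, 500, "zzz", "host_te", score=90, read_length=10_000)
        b = aln("r", 100, 500, "aaa", "host_te", score=90, read_length=10_000)
        assert resolve_long_read_hits([a, b]) == [b]
        c = aln("r", 90, 480, "mmm", "host_te", score=90, read_length=10_000)
        assert resolve_long_read_hits([a, c]) == [c]

    @pytest.mark.parametrize("seed", range(8))
    def test_brute_force_properties(self, seed):
        """Kept hits are disjoint and dominate every dropped hit."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        hits = []
        for i in range(n):
            rs = int(rng.integers(1, 9000))
            re = rs + int(rng.integers(50, 2000))
            hits.append(
                aln("r", rs, min(re, 10_000), f"te{i}", "host_te",
                    score=float(rng.integers(10, 200)), read_length=10_000)
            )
        kept = resolve_long_read_hits(hits)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert a.read_end < b.read_start or b.read_end < a.read_start
        dropped = [h for h in hits if h not in kept]
        for d in dropped:
            dominators = [
                k for k in kept
                if k.read_overlap(d) > 0 and k.score >= d.score
            ]
            assert dominators, "dropped hit not dominated by any kept hit"

    def test_mutually_overlapping_clique_keeps_global_best(self):
        hits = [
            aln("r", 100, 900, f"te{i}", "host_te", score=10.0 * (i + 1),
                read_length=10_000)
            for i in range(5)
        ]
        kept = resolve_long_read_hits(hits)
        assert [h.score for h in kept] == [50.0]

    def test_flank_validation(self):
        host = [aln("r", 500, 1500, "te1", "host_te", read_length=10_000)]
        virus_good = [aln("r", 1, 499, "virus", "virus", read_length=10_000)]
        virus_bad = [aln("r", 495, 1505, "virus", "virus", read_length=10_000)]
        assert validate_chimera_flanks(host, virus_good)
        assert not validate_chimera_flanks(host, virus_bad)


class TestClassifyCompleteness:
    def make(self, fraction):
        return TEInsertion("r", "piggyBac", "II", 10, 500, 10_000,
                           consensus_fraction=fraction)

    def test_complete_copy(self):
        assert classify_completeness(self.make(1.0)) == "full"

    def test_truncated_copy(self):
        assert classify_completeness(self.make(0.40)) == "truncated"

    def test_boundary_inclusive(self):
        assert classify_completeness(self.make(0.95)) == "full"

    def test_unknown_consensus_withheld(self):
        ins = TEInsertion("r", "piggyBac", "II", 10, 500, 10_000)
        assert classify_completeness(ins) is None
        assert ins.completeness is None


class TestEndEnrichmentTest:
    def insertions(self, n, k, read_length=10_000):
        out = []
        for i in range(n):
            if i < k:
                out.append(TEInsertion("r", "x", "II", 1, 500, read_length))
            else:
                out.append(TEInsertion("r", "x", "II", 50, 550, read_length))
        return out

    def test_zero_at_end_gives_unit_pvalue(self):
        test = end_enrichment_test(self.insertions(10, 0), 100_000, 10_000)
        assert test.p_value == 1.0

    def test_exact_tail_against_direct_summation(self):
        """Independent oracle: explicit binomial tail sum."""
        n, k, p0 = 20, 5, 0.1
        test = end_enrichment_test(
            self.insertions(n, k), total_read_bp=100_000, total_te_bp=10_000
        )
        oracle = sum(
            math.comb(n, i) * p0 ** i * (1 - p0) ** (n - i)
            for i in range(k, n + 1)
        )
        assert test.p_value == pytest.approx(oracle, rel=1e-12)
        assert test.p_value == pytest.approx(0.0432, abs=5e-4)

    def test_all_at_end_closed_form(self):
        n, p0 = 8, 0.05
        test = end_enrichment_test(
            self.insertions(n, n), total_read_bp=100_000, total_te_bp=5_000
        )
        assert test.p_value == pytest.approx(p0 ** n, rel=1e-9)

    def test_degenerate_proportion_is_error(self):
        with pytest.raises(ValueError):
            end_enrichment_test(self.insertions(5, 1), 100, 100)

    def test_at_read_end_detection(self):
        touching_last = TEInsertion("r", "x", "II", 9_000, 10_000, 10_000)
        interior = TEInsertion("r", "x", "II", 9_000, 9_999, 10_000)
        assert touching_last.at_read_end and not interior.at_read_end
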