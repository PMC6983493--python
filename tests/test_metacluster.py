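"""Meta-clustering: grid clustering, filters, dedupe, robust subset."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from svmeta.metacluster import (
    ClusteringGrid,
    ClusterPolicy,
    circular_filter,
    cluster_at,
    dedupe,
    filter_clusters,
    harmonize,
    run_grid,
    select_robust_subset,
)
from svmeta.models import SVCluster, SVType, Technology

from _util import mk_call, naive_ward_partition


class TestHarmonize:
    def test_low_support_removed(self):
        policy = ClusterPolicy()
        assert harmonize([mk_call("DEL", 100, 900, support=2)], policy) == []

    def test_minimum_length_boundary(self):
        policy = ClusterPolicy()
        short = mk_call("DEL", 100, 148)   # 49 bp
        exact = mk_call("DEL", 100, 149)   # 50 bp
        assert harmonize([short, exact], policy) == [exact]

    def test_empty_input(self):
        assert harmonize([], ClusterPolicy()) == []


class TestClusterAt:
    def test_identical_coordinates_always_cocluster(self):
        calls = [mk_call("DEL", 100, 900), mk_call("DEL", 100, 900, caller="lumpy")]
        assert len(cluster_at(calls, 0.001)) == 1

    def test_distant_calls_split_at_small_threshold(self):
        calls = [mk_call("DEL", 100, 200), mk_call("DEL", 500, 900)]
        assert len(cluster_at(calls, 5)) == 2

    def test_single_call_singleton(self):
        (cluster,) = cluster_at([mk_call("DUP", 10, 400)], 5)
        assert len(cluster.members) == 1

    def test_threshold_regimes_on_mixed_neighbourhood(self):
        """Two near-identical DELs plus a nearby DUP across thresholds."""
        calls = [
            mk_call("DEL", 1000, 5000, technology="short"),
            mk_call("DEL", 1003, 5004, technology="long", caller="sniffles"),
            mk_call("DUP", 1040, 5060, technology="short"),
        ]
        assert len(cluster_at(calls, 2)) == 3       # low: all singletons
        medium = cluster_at(calls, 20)              # medium: {DEL,DEL} + {DUP}
        assert sorted(len(c.members) for c in medium) == [1, 2]
        paired = next(c for c in medium if len(c.members) == 2)
        assert paired.sv_type is SVType.DEL
        assert len(cluster_at(calls, 100)) == 1     # high: one mixed cluster

    def test_consensus_inside_member_hull(self):
        calls = [mk_call("DEL", 1000, 5000), mk_call("DEL", 1010, 5008)]
        (cluster,) = cluster_at(calls, 50)
        assert 1000 <= cluster.consensus_start <= 1010
        assert 5000 <= cluster.consensus_end <= 5008

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("t", [5, 50, 300, 1000])
    def test_matches_naive_ward_partition(self, seed, t):
        """scipy-backed clustering equals a brute-force Ward implementation."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 31))
        starts = rng.integers(1, 1_000_000, n)
        calls = [
            mk_call("DEL", int(s), int(s + rng.integers(100, 50_000)),
                    call_id=f"c{i}")
            for i, s in enumerate(starts)
        ]
        clusters = cluster_at(calls, t)
        index = {c.id: i for i, c in enumerate(calls)}
        got = {frozenset(index[m.id] for m in cl.members) for cl in clusters}
        expected = naive_ward_partition([c.point for c in calls], t)
        assert got == expected

    @settings(derandomize=True, max_examples=40)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(1, 40),
        t=st.sampled_from([5, 30, 200, 1000]),
    )
    def test_partition_property(self, seed, n, t):
        rng = np.random.default_rng(seed)
        calls = []
        for i in range(n):
            s = int(rng.integers(1, 40_000))
            calls.append(mk_call("DEL", s, s + 500, call_id=f"c{i}"))
        clusters = cluster_at(calls, t)
        assert sum(len(c.members) for c in clusters) == n
        ids = [m.id for c in clusters for m in c.members]
        assert sorted(ids) == sorted(c.id for c in calls)


class TestFilterClusters:
    def cluster(self, *calls):
        return SVCluster.from_members(list(calls))

    def test_cross_technology_pair_retained(self):
        c = self.cluster(
            mk_call("DEL", 100, 900, technology="short"),
            mk_call("DEL", 102, 903, technology="long", caller="sniffles"),
        )
        assert filter_clusters([c], ClusterPolicy()) == [c]
        assert c.retained

    def test_mixed_type_cluster_discarded(self):
        c = self.cluster(
            mk_call("DEL", 100, 900, technology="short"),
            mk_call("INV", 101, 902, technology="long", caller="sniffles"),
        )
        assert filter_clusters([c], ClusterPolicy()) == []

    def test_single_caller_cluster_discarded(self):
        c = self.cluster(mk_call("DUP", 100, 900))
        assert filter_clusters([c], ClusterPolicy()) == []
        assert filter_clusters(
            [c], ClusterPolicy(support_mode="min_two_callers")
        ) == []

    def test_two_caller_mode(self):
        c = self.cluster(
            mk_call("DEL", 100, 900, caller="pindel"),
            mk_call("DEL", 101, 901, caller="lumpy"),
        )
        assert filter_clusters(
            [c], ClusterPolicy(support_mode="min_two_callers")
        ) == [c]
        # same technology twice fails cross-technology mode
        c2 = self.cluster(
            mk_call("DEL", 100, 900, caller="pindel"),
            mk_call("DEL", 101, 901, caller="lumpy"),
        )
        assert filter_clusters([c2], ClusterPolicy()) == []


class TestRunGrid:
    def test_single_caller_yields_nothing_in_cross_technology_mode(self):
        calls = [mk_call("DEL", 100, 900, support=50, call_id=f"c{i}")
                 for i in range(5)]
        assert run_grid(calls, policy=ClusterPolicy()) == []

    def test_cross_technology_pair_emitted_at_every_eligible_grid_point(self):
        calls = [
            mk_call("DEL", 1000, 5000, support=10, technology="short"),
            mk_call("DEL", 1000, 5000, support=10, technology="long",
                    caller="sniffles"),
        ]
        union = run_grid(calls)
        deduped = dedupe(union)
        assert len(deduped) == 1
        # support levels 3,4..10 (8) x 14 distance thresholds
        assert len(deduped[0].provenance) == 8 * 14

    def test_coordinate_disagreement_recovered_at_larger_thresholds(self):
        calls = [
            mk_call("DEL", 1000, 5000, support=10, technology="short"),
            mk_call("DEL", 1040, 5030, support=10, technology="long",
                    caller="sniffles"),
        ]
        deduped = dedupe(run_grid(calls))
        assert len(deduped) == 1
        ts = {t for _, t in deduped[0].provenance}
        assert min(ts) == 50 and not ts & {5, 10, 30}

    def test_artifact_rejection_without_cross_technology_neighbours(self):
        """Single-technology call sets can never produce retained SVs."""
        rng = np.random.default_rng(7)
        calls = []
        for i in range(10):
            s = int(rng.integers(1, 20_000))
            calls.append(mk_call("DEL", s, s + 600, support=20,
                                 technology="short", call_id=f"s{i}"))
        for i in range(10):
            s = int(rng.integers(60_000, 90_000))
            calls.append(mk_call("DEL", s, s + 600, support=20,
                                 technology="long", caller="sniffles",
                                 call_id=f"l{i}"))
        assert run_grid(calls) == []


class TestDedupe:
    def make_sv(self, start=1000, end=5000, support=10):
        return SVCluster.from_members(
            [mk_call("DEL", start, end, support=support)]
        )

    def test_identical_consensus_collapses(self):
        svs = [self.make_sv() for _ in range(40)]
        assert len(dedupe(svs)) == 1

    def test_one_bp_difference_kept_apart(self):
        assert len(dedupe([self.make_sv(1000), self.make_sv(1001)])) == 2

    def test_idempotent(self):
        svs = [self.make_sv(s) for s in (1000, 1000, 1200, 1500)]
        once = dedupe(svs)
        twice = dedupe(once)
        assert [s.identity_key() for s in once] == [
            s.identity_key() for s in twice
        ]

    def test_keeps_maximal_support_and_merges_provenance(self):
        a, b = self.make_sv(support=5), self.make_sv(support=50)
        a.provenance = {(3, 5)}
        b.provenance = {(4, 10)}
        (kept,) = dedupe([a, b])
        assert kept.total_read_support == 50
        assert kept.provenance == {(3, 5), (4, 10)}

    def test_grid_union_monotonicity(self):
        """Adding a distance threshold never removes an SV from the union."""
        rng = np.random.default_rng(2)
        calls = []
        for i in range(12):
            s = int(rng.integers(1, 30_000))
            e = s + int(rng.integers(100, 5000))
            calls.append(mk_call("DEL", s, e, support=10, technology="short",
                                 call_id=f"s{i}"))
            calls.append(mk_call("DEL", s + int(rng.integers(0, 20)),
                                 e + int(rng.integers(0, 20)), support=10,
                                 technology="long", caller="sniffles",
                                 call_id=f"l{i}"))
        small = ClusteringGrid((50, 100), (4,))
        large = ClusteringGrid((50, 100, 400), (4,))
        keys_small = {s.identity_key() for s in dedupe(run_grid(calls, small))}
        keys_large = {s.identity_key() for s in dedupe(run_grid(calls, large))}
        assert keys_small <= keys_large


class TestCircularFilter:
    def long_cluster(self, length, long_support, n_callers):
        members = []
        callers = ["pindel", "lumpy", "fermikit"][:max(n_callers - 1, 1)]
        members.append(
            mk_call("DEL", 1000, 1000 + length - 1, support=long_support,
                    technology="long", caller="sniffles")
        )
        for name in callers:
            members.append(
                mk_call("DEL", 1000, 1000 + length - 1, support=5,
                        caller=name)
            )
        return SVCluster.from_members(members)

    def test_oversized_weakly_supported_sv_removed(self):
        sv = self.long_cluster(70_000, long_support=10, n_callers=2)
        assert circular_filter([sv], 134_000) == []

    def test_oversized_but_well_supported_sv_kept(self):
        sv = self.long_cluster(70_000, long_support=25, n_callers=3)
        assert circular_filter([sv], 134_000) == [sv]

    def test_below_half_genome_untouched(self):
        sv = self.long_cluster(60_000, long_support=3, n_callers=2)
        assert circular_filter([sv], 134_000) == [sv]


class TestSelectRobustSubset:
    def make(self, n, n_two_caller, freq_fn=lambda i: 0.001 * (i + 1)):
        svs = []
        for i in range(n):
            members = [mk_call("DEL", 100 + 10 * i, 900 + 10 * i, support=5)]
            if i < n_two_caller:
                members.append(
                    mk_call("DEL", 100 + 10 * i, 900 + 10 * i, support=5,
                            caller="lumpy")
                )
            sv = SVCluster.from_members(members)
            sv.frequency = freq_fn(i)
            svs.append(sv)
        return svs

    def test_quota_filled_from_two_caller_svs(self):
        svs = self.make(100, 10)
        out = select_robust_subset(svs, 0.0498)  # k = ceil(4.98) = 5
        assert len(out) == 5
        assert all(s.n_callers >= 2 for s in out)
        freqs = [s.frequency for s in out]
        assert freqs == sorted(freqs, reverse=True)

    def test_deficit_topped_up_by_frequency(self):
        svs = self.make(100, 3)
        out = select_robust_subset(svs, 0.0498)
        assert len(out) == 5
        assert sum(1 for s in out if s.n_callers >= 2) == 3
        singles = [s for s in out if s.n_callers == 1]
        assert all(s.frequency >= 0.097 for s in singles)  # the two most frequent

    def test_empty_input(self):
        assert select_robust_subset([], 0.0498) == []
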