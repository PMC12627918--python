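"""De novo clustering: linkage vs reference agglomerative oracle, SWARM-style
components, greedy centroid scan, OTU-vs-BIN scoring."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from metaresolve.clustering import (cluster, cluster_error_profile,
                                    greedy_centroid_cluster, linkage_cluster,
                                    otu_vs_bin_errors, swarm_d,
                                    swarm_like_cluster)
from metaresolve.errors import BinAssignment, UndefinedRateError
from metaresolve.similarity import SimilarityTable
from oracles import (components_at_threshold, naive_agglomerative,
                     otu_errors_oracle)


def _table(sims):
    t = SimilarityTable()
    for (a, b), s in sims.items():
        t.add(a, b, s.numerator, s.denominator)
    return t


def _partition(assignment):
    groups = {}
    for k, v in assignment.items():
        groups.setdefault(v, set()).add(k)
    return sorted(map(sorted, groups.values()))


def _random_table(rng, n, lo=850, hi=1001):
    ids = [f"s{i:02d}" for i in range(n)]
    t = SimilarityTable()
    for a, b in combinations(ids, 2):
        t.add(a, b, int(rng.integers(lo, hi)), 1000)
    return ids, t


CHAIN = _table({("A", "B"): Fraction(99, 100), ("B", "C"): Fraction(99, 100),
                ("A", "C"): Fraction(90, 100)})


class TestSwarmD:
    def test_complement_reading(self):
        assert swarm_d(100, 97) == 3
        assert swarm_d(171, 97) == 5  # floor(171 * 0.03)

    def test_literal_reading_is_selectable_for_audit(self):
        assert swarm_d(100, 97, literal=True) == 97

    def test_d_zero_groups_identical_sequences_only(self):
        seqs = {"a": "ACGTACGTAC", "b": "ACGTACGTAC", "c": "ACGTACGTAA"}
        otus = swarm_like_cluster(seqs, 100)
        assert otus.assignment["a"] == otus.assignment["b"]
        assert otus.assignment["a"] != otus.assignment["c"]


class TestLinkage:
    @pytest.mark.parametrize("method", ["single", "complete", "upgma"])
    def test_one_merge_below_the_cut(self, method):
        table = _table({("a", "b"): Fraction(99, 100)})
        otus = linkage_cluster(table, ["a", "b"], method, 98)
        assert otus.n_otus == 1

    def test_chain_splits_under_complete_but_not_single(self):
        single = linkage_cluster(CHAIN, "ABC", "single", 98)
        complete = linkage_cluster(CHAIN, "ABC", "complete", 98)
        assert single.n_otus == 1
        assert complete.n_otus == 2
        assert complete.assignment["A"] == complete.assignment["B"]

    def test_all_pairs_below_cut_gives_singletons(self):
        rng = np.random.default_rng(0)
        ids, table = _random_table(rng, 8, lo=800, hi=900)
        assert linkage_cluster(table, ids, "single", 95).n_otus == 8

    def test_merge_at_exactly_the_cut_height_is_included(self):
        table = _table({("a", "b"): Fraction(97, 100)})
        assert linkage_cluster(table, ["a", "b"], "single", 97).n_otus == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_single_linkage_equals_connected_components(self, seed):
        rng = np.random.default_rng(seed)
        ids, table = _random_table(rng, 20)
        sims = {frozenset((a, b)): Fraction(m, c)
                for (a, b), (m, c) in table.entries.items()}
        for c_t in (90, 94, 97, 99):
            otus = linkage_cluster(table, ids, "single", c_t)
            expected = components_at_threshold(ids, sims, Fraction(c_t, 100))
            assert _partition(otus.assignment) == _partition(expected)

    @pytest.mark.parametrize("method", ["single", "complete", "upgma"])
    @pytest.mark.parametrize("seed", range(4))
    def test_agreement_with_naive_agglomerative_reference(self, method, seed):
        rng = np.random.default_rng(10 + seed)
        n = 15
        ids = [f"s{i:02d}" for i in range(n)]
        dist = np.zeros((n, n))
        table = SimilarityTable()
        for i, j in combinations(range(n), 2):
            # fine-grained similarities so merge-order ties cannot occur
            m = int(rng.integers(850_000_000, 1_000_000_001))
            dist[i, j] = dist[j, i] = 1 - m / 1_000_000_000
            table.add(ids[i], ids[j], m, 1_000_000_000)
        cut_ct = float(rng.uniform(90, 99.5))
        otus = linkage_cluster(table, ids, method, cut_ct)
        labels = naive_agglomerative(dist.tolist(), method, 1 - cut_ct / 100)
        assert _partition(otus.assignment) == _partition(
            {ids[i]: l for i, l in enumerate(labels)})

    def test_missing_prescreened_pairs_are_distant(self):
        table = SimilarityTable(prescreen_threshold=0.9)
        table.add("a", "b", 99, 100)
        otus = linkage_cluster(table, ["a", "b", "c"], "single", 95)
        assert otus.n_otus == 2
        assert otus.assignment["a"] == otus.assignment["b"]

    def test_nestedness_of_single_linkage_cuts(self):
        rng = np.random.default_rng(3)
        ids, table = _random_table(rng, 18)
        coarse = linkage_cluster(table, ids, "single", 92).assignment
        fine = linkage_cluster(table, ids, "single", 97).assignment
        # every fine cluster lies inside one coarse cluster
        for members in _partition(fine):
            assert len({coarse[m] for m in members}) == 1

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            linkage_cluster(CHAIN, "ABC", "median", 95)


class TestSwarmLike:
    def test_chain_links_transitively(self):
        # consecutive distances d, end-to-end 2d: one OTU
        seqs = {"x1": "AAAAAAAAAA", "x2": "AAAAAAAATT", "x3": "AAAAAATTTT"}
        otus = swarm_like_cluster(seqs, 80)  # d = floor(10 * 0.2) = 2
        assert otus.n_otus == 1

    def test_beyond_d_differences_do_not_link(self):
        seqs = {"x1": "AAAAAAAAAA", "x3": "AAAAAATTTT"}
        assert swarm_like_cluster(seqs, 80).n_otus == 2


class TestGreedyCentroid:
    def test_identical_sequences_one_otu(self):
        seqs = {f"s{i}": "ACGTACGTACGT" for i in range(4)}
        assert greedy_centroid_cluster(seqs, 99).n_otus == 1

    def test_scan_order_joins_first_acceptable_centroid(self):
        # A processed first (longest); B and C both join A despite B~C = 0.90
        seqs = {"A": "ACGTACGTACGTACGTACGTACGTA",  # 25 bp: first centroid
                "B": "ACGTACGTACGTACGTACGTACGT",
                "C": "ACGTACGTACGTACGTACGTACGG"}
        otus = greedy_centroid_cluster(seqs, 95)
        assert otus.n_otus == 1

    def test_unreachable_threshold_gives_singletons(self):
        rng = np.random.default_rng(1)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 30)) for i in range(5)}
        assert greedy_centroid_cluster(seqs, 100).n_otus == 5


class TestOtuVsBinErrors:
    def test_perfect_partition_scores_zero(self):
        from metaresolve.clustering import OtuAssignment
        bins = BinAssignment({"a": "B1", "b": "B1", "c": "B2", "d": "B2"})
        otus = OtuAssignment("single", 97, {"a": 0, "b": 0, "c": 1, "d": 1})
        assert otu_vs_bin_errors(otus, bins) == (0.0, 0.0)

    def test_everything_merged_overmerges_the_only_pair(self):
        from metaresolve.clustering import OtuAssignment
        bins = BinAssignment({"a": "B1", "b": "B1", "c": "B2"})
        otus = OtuAssignment("single", 90, {"a": 0, "b": 0, "c": 0})
        oversplit, overmerge = otu_vs_bin_errors(otus, bins)
        assert (oversplit, overmerge) == (0.0, 1.0)

    def test_vacuous_pair_class_raises(self):
        from metaresolve.clustering import OtuAssignment
        bins = BinAssignment({"a": "B1", "b": "B2"})
        otus = OtuAssignment("single", 90, {"a": 0, "b": 1})
        with pytest.raises(UndefinedRateError):
            otu_vs_bin_errors(
                OtuAssignment("single", 90, {"a": 0, "b": 1}),
                BinAssignment({"a": "B1", "b": "B1"}))
        with pytest.raises(UndefinedRateError):
            otu_vs_bin_errors(otus, BinAssignment({"a": "B1", "b": "B2"}))
        # single-BIN dataset: no inter pairs

    @pytest.mark.parametrize("seed", range(8))
    def test_random_partitions_match_pair_enumeration(self, seed):
        from metaresolve.clustering import OtuAssignment
        rng = np.random.default_rng(seed)
        ids = [f"s{i:03d}" for i in range(100)]
        bins = BinAssignment({i: f"B{rng.integers(12)}" for i in ids})
        otus = OtuAssignment("single", 95, {i: int(rng.integers(15)) for i in ids})
        got = otu_vs_bin_errors(otus, bins)
        expected = otu_errors_oracle(otus.assignment, bins.bins)
        assert got[0] == pytest.approx(float(expected[0]))
        assert got[1] == pytest.approx(float(expected[1]))


class TestClusterErrorProfile:
    def test_separated_data_has_zero_plateau_containing_c_opt(self, teleo1):
        seqs, table, bins = teleo1
        profiles = cluster_error_profile(seqs, table, bins,
                                         methods=("single", "upgma"))
        for p in profiles:
            i = p.thresholds.index(p.c_opt)
            assert p.global_error[i] == min(p.global_error)

    def test_single_point_grid(self):
        bins = BinAssignment({"A": "B1", "B": "B1", "C": "B2"})
        (profile,) = cluster_error_profile(
            {"A": "", "B": "", "C": ""}, CHAIN, bins, methods=("single",),
            grid=(97,))
        assert profile.c_opt == 97

    def test_single_and_complete_differ_on_the_chain_at_98(self):
        bins = BinAssignment({"A": "B1", "B": "B1", "C": "B2"})
        single, complete = cluster_error_profile(
            {"A": "", "B": "", "C": ""}, CHAIN, bins,
            methods=("single", "complete"), grid=(98,))
        assert single.overmerge_rate != complete.overmerge_rate

    def test_otu_count_non_decreasing_in_threshold_for_every_method(
            self, teleo1):
        seqs, table, bins = teleo1
        for method in ("single", "complete", "upgma", "swarm_like",
                       "greedy_centroid"):
            counts = [cluster(seqs, table, method, c_t).n_otus
                      for c_t in range(90, 100)]
            assert counts == sorted(counts), method

    def test_single_linkage_overmerge_at_least_raw_pairwise(self, teleo1):
        from metaresolve.errors import overmerge_rate
        seqs, table, bins = teleo1
        for c_t in (92, 95, 97, 99):
            otus = cluster(seqs, table, "single", c_t)
            _, om_cluster = otu_vs_bin_errors(otus, bins)
            om_raw = overmerge_rate(table, bins, c_t)
            assert om_cluster >= om_raw - 1e-12
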