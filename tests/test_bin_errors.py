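"""Over-splitting/over-merging rates against BINs: frozen examples, oracle
equality, monotonicity, threshold optimisation and grouped recomputation."""

from fractions import Fraction

import numpy as np
import pytest

from metaresolve.errors import (BinAssignment, ErrorProfile,
                                UndefinedRateError, error_profile, find_s_opt,
                                grouped_profiles, overmerge_rate,
                                oversplit_rate)
from metaresolve.similarity import SimilarityTable
from oracles import rates_oracle


def _table(sims: dict[tuple[str, str], Fraction],
           prescreen=None) -> SimilarityTable:
    t = SimilarityTable(prescreen_threshold=prescreen)
    for (a, b), s in sims.items():
        t.add(a, b, s.numerator, s.denominator)
    return t


def _random_dataset(rng, n_seqs, n_bins):
    ids = [f"s{i:03d}" for i in range(n_seqs)]
    bins = BinAssignment({i: f"B{rng.integers(n_bins):02d}" for i in ids})
    t = SimilarityTable()
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            t.add(a, b, int(rng.integers(80, 101)), 100)
    return t, bins


class TestRateExamples:
    def test_one_of_two_intra_pairs_below_threshold(self):
        table = _table({("a", "b"): Fraction(95, 100),
                        ("a", "c"): Fraction(99, 100),
                        ("b", "c"): Fraction(99, 100)})
        bins = BinAssignment({"a": "B1", "b": "B1", "c": "B1"})
        # pairs below 97%: only (a, b) and (a, c)? (a,c)=0.99 >= 0.97
        assert oversplit_rate(table, bins, 97) == pytest.approx(1 / 3)

    def test_identical_intra_sequences_never_split(self):
        table = _table({("a", "b"): Fraction(1)})
        bins = BinAssignment({"a": "B1", "b": "B1"})
        for s_t in range(90, 100):
            assert oversplit_rate(table, bins, s_t) == 0.0

    def test_overmerge_counts_pairs_at_or_above_threshold(self):
        table = _table({("a", "b"): Fraction(99, 100),
                        ("c", "d"): Fraction(80, 100),
                        ("a", "c"): Fraction(80, 100),
                        ("a", "d"): Fraction(80, 100),
                        ("b", "c"): Fraction(80, 100),
                        ("b", "d"): Fraction(80, 100)})
        bins = BinAssignment({"a": "B1", "b": "B2", "c": "B3", "d": "B4"})
        assert overmerge_rate(table, bins, 95) == pytest.approx(1 / 6)

    def test_exact_equality_at_threshold_is_an_overmerge(self):
        table = _table({("a", "b"): Fraction(97, 100)})
        bins = BinAssignment({"a": "B1", "b": "B2"})
        assert overmerge_rate(table, bins, 97) == 1.0
        assert oversplit_rate(
            _table({("a", "b"): Fraction(97, 100)}),
            BinAssignment({"a": "B1", "b": "B1"}), 97) == 0.0

    def test_undefined_rates_raise(self):
        table = _table({("a", "b"): Fraction(1)})
        with pytest.raises(UndefinedRateError):
            oversplit_rate(table, BinAssignment({"a": "B1", "b": "B2"}), 95)
        with pytest.raises(UndefinedRateError):
            overmerge_rate(table, BinAssignment({"a": "B1", "b": "B1"}), 95)


class TestErrorProfile:
    def test_separated_distributions_have_zero_global_error(self):
        sims = {("a", "b"): Fraction(999, 1000), ("c", "d"): Fraction(998, 1000)}
        for x in "ab":
            for y in "cd":
                sims[(x, y)] = Fraction(88, 100)
        table = _table(sims)
        bins = BinAssignment({"a": "B1", "b": "B1", "c": "B2", "d": "B2"})
        profile = error_profile(table, bins)
        for s_t, ge in zip(profile.thresholds, profile.global_error):
            if 91 <= s_t <= 99:
                assert ge == 0.0

    def test_single_bin_dataset_is_degenerate(self):
        table = _table({("a", "b"): Fraction(1)})
        with pytest.raises(UndefinedRateError):
            error_profile(table, BinAssignment({"a": "B1", "b": "B1"}))

    @pytest.mark.parametrize("seed", range(6))
    def test_profile_equals_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table, bins = _random_dataset(rng, int(rng.integers(10, 40)), 5)
        profile = error_profile(table, bins)
        sims = {frozenset((a, b)): Fraction(m, c)
                for (a, b), (m, c) in table.entries.items()}
        for i, s_t in enumerate(profile.thresholds):
            os_o, om_o = rates_oracle(sims, bins.bins, Fraction(s_t, 100))
            assert profile.oversplit_rate[i] == float(os_o)
            assert profile.overmerge_rate[i] == float(om_o)
            assert profile.global_error[i] == pytest.approx(
                float(os_o + om_o))

    @pytest.mark.parametrize("seed", range(8))
    def test_monotonicity_over_the_grid(self, seed):
        rng = np.random.default_rng(100 + seed)
        table, bins = _random_dataset(rng, 30, 6)
        profile = error_profile(table, bins)
        assert profile.oversplit_rate == sorted(profile.oversplit_rate)
        assert profile.overmerge_rate == sorted(profile.overmerge_rate,
                                                reverse=True)

    def test_prescreen_absent_pairs_count_as_below_threshold(self):
        full = _table({("a", "b"): Fraction(99, 100),
                       ("a", "c"): Fraction(85, 100),
                       ("b", "c"): Fraction(85, 100)})
        pruned = _table({("a", "b"): Fraction(99, 100)}, prescreen=0.9)
        bins = BinAssignment({"a": "B1", "b": "B1", "c": "B2"})
        p_full, p_pruned = error_profile(full, bins), error_profile(pruned, bins)
        assert p_full.oversplit_rate == p_pruned.oversplit_rate
        assert p_full.overmerge_rate == p_pruned.overmerge_rate

    def test_missing_pair_in_exhaustive_table_is_an_error(self):
        table = _table({("a", "b"): Fraction(1)})
        bins = BinAssignment({"a": "B1", "b": "B1", "c": "B2"})
        with pytest.raises(KeyError):
            error_profile(table, bins)


class TestOptimalThreshold:
    def _profile(self, ge):
        grid = tuple(range(90, 90 + len(ge)))
        return ErrorProfile("demo", grid, [0.0] * len(ge), list(ge), list(ge),
                            1, 1)

    def test_argmin_selected(self):
        opt = find_s_opt(self._profile([0.05, 0.03, 0.01, 0.02, 0.04]))
        assert opt.s_opt == 92
        assert opt.ge_min == pytest.approx(0.01)
        assert opt.ge_max == pytest.approx(0.05)

    def test_strictly_decreasing_picks_boundary(self):
        ge = [0.1 - 0.01 * i for i in range(10)]
        assert find_s_opt(self._profile(ge)).s_opt == 99

    def test_tie_breaks_toward_lower_threshold_even_on_reversed_grid(self):
        ge = [0.05, 0.04, 0.04, 0.01, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06]
        profile = self._profile(ge)
        assert find_s_opt(profile).s_opt == 93
        reversed_profile = ErrorProfile(
            "demo", tuple(reversed(profile.thresholds)), [0.0] * 10,
            list(reversed(ge)), list(reversed(ge)), 1, 1)
        assert find_s_opt(reversed_profile).s_opt == 93


class TestGroupedProfiles:
    def _dataset(self):
        ids, bins, tax = [], {}, {}
        sims = SimilarityTable()
        rng = np.random.default_rng(0)
        for order_i, order in enumerate(["Aformes", "Bformes"]):
            for b in range(4):
                for s in range(2):
                    i = f"{order[0]}{b}{s}"
                    ids.append(i)
                    bins[i] = f"{order[0]}BIN{b}"
                    tax[i] = (f"sp{b}", f"g{b}", "fam", order)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                sims.add(a, b, int(rng.integers(85, 101)), 100)
        return sims, BinAssignment(bins, tax)

    def test_groups_partition_and_exclude_cross_group_pairs(self):
        sims, bins = self._dataset()
        out = grouped_profiles(sims, bins, "order", min_bins=3)
        assert set(out) == {"Aformes", "Bformes"}
        only_a = bins.restrict([i for i in bins.ids() if i.startswith("A")])
        direct = error_profile(sims, only_a)
        assert out["Aformes"].oversplit_rate == direct.oversplit_rate
        assert out["Aformes"].n_inter_pairs == direct.n_inter_pairs

    def test_group_at_the_bin_count_boundary_is_skipped(self):
        sims, bins = self._dataset()
        # both orders hold exactly 4 BINs: "more than min_bins" excludes them
        with pytest.warns(UserWarning):
            out = grouped_profiles(sims, bins, "order", min_bins=4)
        assert out == {}

    def test_min_bins_zero_reports_every_group(self):
        sims, bins = self._dataset()
        assert set(grouped_profiles(sims, bins, "order", min_bins=0)) == {
            "Aformes", "Bformes"}
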