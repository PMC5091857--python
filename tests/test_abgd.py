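"""Barcode-gap detection and recursive partitioning."""

import math

import pytest

import delimkit as dk
from delimkit.abgd import (
    AbgdConfig,
    Partition,
    abgd_recursive,
    find_barcode_gap,
    partition_at_threshold,
    rank_distances,
)
from delimkit.errors import InputError
from delimkit.synthdata import SimConfig, make_dataset

from conftest import dm_from_dict


def bruteforce_components(ids, get, t):
    """BFS single-linkage oracle: components of the graph d < t."""
    ids = sorted(ids)
    seen, comps = set(), []
    for start in ids:
        if start in seen:
            continue
        comp, queue = {start}, [start]
        while queue:
            x = queue.pop()
            for y in ids:
                if y not in comp and get(x, y) < t:
                    comp.add(y)
                    queue.append(y)
        seen |= comp
        comps.append(frozenset(comp))
    return frozenset(comps)


class TestRankDistances:
    def test_identical_sequences(self):
        dm = dm_from_dict("abc", {})
        assert rank_distances(dm, "abc") == [0.0, 0.0, 0.0]

    def test_pair_count(self):
        dm = dm_from_dict("abcd", {("a", "b"): 0.1})
        assert len(rank_distances(dm, "abcd")) == 6

    def test_saturated_sorted_last(self):
        dm = dm_from_dict("abc", {("a", "b"): 0.2, ("b", "c"): 0.3},
                          saturated=[("a", "c")])
        ranked = rank_distances(dm, "abc")
        assert ranked[-1] == math.inf and ranked[:2] == [0.2, 0.3]

    def test_too_small_subset(self):
        dm = dm_from_dict("ab", {})
        with pytest.raises(InputError):
            rank_distances(dm, ["a"])


class TestFindBarcodeGap:
    cfg = AbgdConfig()

    def test_all_below_prior_returns_none(self):
        assert find_barcode_gap([0.0, 0.005, 0.01, 0.02], self.cfg) is None

    def test_planted_gap_found_in_gap_interval(self):
        lows = [i * 0.001 for i in range(10)]  # ten values in [0, 0.01]
        highs = [0.10 + i * 0.0025 for i in range(5)]  # five in [0.10, 0.11]
        sorted_d = lows + highs
        t = find_barcode_gap(sorted_d, self.cfg)
        assert t is not None and 0.01 < t < 0.10
        # brute-force scan: the largest gap over all split points is the
        # planted one, and the returned threshold is its midpoint
        gaps = [(sorted_d[i + 1] - sorted_d[i], i) for i in range(len(sorted_d) - 1)]
        _, i_star = max(gaps)
        assert t == pytest.approx(0.5 * (sorted_d[i_star] + sorted_d[i_star + 1]))

    @pytest.mark.parametrize("x", [1.0, 1.5, 3.0])
    def test_arithmetic_ladder_has_no_gap(self, x):
        ladder = [i * 0.01 for i in range(21)]  # 0.00 .. 0.20, constant gaps
        cfg = AbgdConfig(gap_width_X=x)
        assert find_barcode_gap(ladder, cfg) is None

    def test_non_ascending_rejected(self):
        with pytest.raises(InputError, match="ascending"):
            find_barcode_gap([0.1, 0.05], self.cfg)

    def test_saturated_tail_split_at_finite_value(self):
        sorted_d = [0.0, 0.001, 0.002, 0.04, math.inf, math.inf]
        t = find_barcode_gap(sorted_d, self.cfg)
        assert t is not None and math.isfinite(t)


class TestPartitionAtThreshold:
    dm = dm_from_dict(
        "abcd",
        {("a", "b"): 0.01, ("a", "c"): 0.10, ("a", "d"): 0.11,
         ("b", "c"): 0.10, ("b", "d"): 0.12, ("c", "d"): 0.008},
    )

    def test_tiny_threshold_all_singletons(self):
        p = partition_at_threshold(self.dm, self.dm.ids, 0.001)
        assert p.n_units == 4

    def test_huge_threshold_one_unit(self):
        p = partition_at_threshold(self.dm, self.dm.ids, 1.0)
        assert p.n_units == 1

    def test_two_planted_clusters(self):
        p = partition_at_threshold(self.dm, self.dm.ids, 0.05)
        expected = bruteforce_components(self.dm.ids, self.dm.get, 0.05)
        assert p.as_frozensets() == expected == frozenset(
            [frozenset("ab"), frozenset("cd")]
        )


class TestRecursive:
    def test_three_clusters_within_two_rounds(self):
        ids = [f"s{i}" for i in range(9)]
        groups = [ids[:3], ids[3:6], ids[6:]]
        dist = {}
        for gi, g in enumerate(groups):
            for gj, h in enumerate(groups):
                if gi >= gj:
                    continue
                between = 0.08 if (gi, gj) == (0, 1) else 0.8
                for a in g:
                    for b in h:
                        dist[(a, b)] = between
        for g in groups:
            dist[(g[0], g[1])] = dist[(g[0], g[2])] = dist[(g[1], g[2])] = 0.001
        dm = dm_from_dict(ids, dist)
        p = abgd_recursive(dm)
        assert p.n_units == 3
        assert max(r for r, _, _ in p.trace) <= 2
        assert p.as_frozensets() == frozenset(frozenset(g) for g in groups)

    def test_no_gap_one_unit_trace_length_one(self):
        dm = dm_from_dict("abcd", {(a, b): 0.01 for a in "abcd" for b in "abcd" if a < b})
        p = abgd_recursive(dm)
        assert p.n_units == 1 and len(p.trace) == 1

    def test_trace_rounds_capped_by_config(self):
        ds = make_dataset(SimConfig(seed=11))
        dm = dk.distance_matrix(ds.alignment)
        p = abgd_recursive(dm, AbgdConfig(max_rounds=10))
        assert all(r <= 10 for r, _, _ in p.trace)

    def test_partition_is_exhaustive_and_disjoint(self):
        ds = make_dataset(SimConfig(seed=5))
        dm = dk.distance_matrix(ds.alignment)
        p = abgd_recursive(dm)
        assert p.ids == frozenset(dm.ids)
        assert sum(len(m) for m in p.units().values()) == dm.n

    def test_determinism(self):
        ds = make_dataset(SimConfig(seed=3))
        dm = dk.distance_matrix(ds.alignment)
        p1, p2 = abgd_recursive(dm), abgd_recursive(dm)
        assert p1.assignment == p2.assignment and p1.trace == p2.trace

    def test_rounds_refine(self):
        ds = make_dataset(SimConfig(seed=3))
        dm = dk.distance_matrix(ds.alignment)
        coarse = abgd_recursive(dm, AbgdConfig(max_rounds=1))
        fine = abgd_recursive(dm, AbgdConfig(max_rounds=10))
        for unit in fine.as_frozensets():
            assert any(unit <= c for c in coarse.as_frozensets())

    def test_planted_recovery_sample(self):
        hits = 0
        for seed in range(5):
            ds = make_dataset(SimConfig(seed=100 + seed))
            p = abgd_recursive(dk.distance_matrix(ds.alignment))
            truth = Partition.from_groups(ds.true_partition_groups())
            hits += p.as_frozensets() == truth.as_frozensets()
        assert hits == 5

    def test_single_cluster_null(self):
        # i.i.d. distances below the prior: always one unit
        import numpy as np

        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(8)]
        dist = {
            (a, b): float(rng.uniform(0, 0.029))
            for i, a in enumerate(ids)
            for b in ids[i + 1:]
        }
        p = abgd_recursive(dm_from_dict(ids, dist))
        assert p.n_units == 1
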