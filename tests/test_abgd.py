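"""Gap detection, single linkage, recursion, prior scanning."""

import numpy as np
import pytest

from barcodekit.abgd import (
    ABGDParams,
    COI_PARAMS,
    Partition,
    find_gap,
    initial_partition,
    prior_series,
    recursive_partition,
    scan_priors,
    select_modal,
    single_linkage,
)
from barcodekit.distances import DistanceMatrix
from conftest import random_distance_matrix, truth_partition
from oracles import brute_force_components


class TestPriorSeries:
    def test_coi_series_endpoints_and_count(self):
        series = prior_series(COI_PARAMS)
        assert len(series) == 10
        assert series[0] == 0.001 and series[-1] == 0.1
        assert all(a < b for a, b in zip(series, series[1:]))

    def test_two_steps_is_exactly_bounds(self):
        series = prior_series(ABGDParams(p_min=0.002, p_max=0.07, x=1.5, steps=2))
        assert series == [0.002, 0.07]

    def test_geometric_second_value(self):
        series = prior_series(COI_PARAMS)
        assert series[1] == pytest.approx(0.001 * 100 ** (1 / 9), rel=1e-12)
        assert series[1] == pytest.approx(0.0016681, abs=5e-8)


class TestFindGap:
    def test_hand_traced_gap(self):
        res = find_gap([0.01, 0.02, 0.03, 0.15, 0.16], prior=0.05, x=1.5)
        assert res.found
        assert res.lower_edge == 0.03 and res.upper_edge == 0.15
        assert res.threshold == pytest.approx(0.09)

    def test_prior_beyond_data_finds_nothing(self):
        res = find_gap([0.01, 0.02, 0.03, 0.15, 0.16], prior=0.20, x=1.5)
        assert not res.found

    def test_uniform_distances_no_gap(self):
        assert not find_gap([0.1, 0.1, 0.1], prior=0.05, x=1.5).found

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            find_gap([0.2, 0.1], prior=0.05, x=1.5)

    def test_median_fallback_with_sparse_context(self):
        # only one gap precedes the candidate: falls back to median of all
        res = find_gap([0.01, 0.02, 0.30, 0.31], prior=0.05, x=1.5)
        assert res.found and res.lower_edge == 0.02


class TestSingleLinkage:
    def test_zero_threshold_all_singletons(self, small_coi_matrix):
        part = single_linkage(small_coi_matrix, 0.0)
        assert part.n_groups == len(small_coi_matrix.ids)

    def test_huge_threshold_single_group(self, small_coi_matrix):
        part = single_linkage(small_coi_matrix, 10.0)
        assert part.n_groups == 1

    def test_matches_brute_force_transitive_closure(self):
        rng = np.random.default_rng(21)
        for _ in range(60):
            n = int(rng.integers(2, 11))
            dm = random_distance_matrix(rng, n)
            threshold = float(rng.uniform(0, 0.6))
            got = {
                frozenset(int(s[1:]) for s in g)
                for g in single_linkage(dm, threshold).groups()
            }
            assert got == brute_force_components(dm.data, threshold)


class TestRecursivePartition:
    @pytest.mark.parametrize("prior", [0.02, 0.03, 0.04])
    def test_recovers_truth_on_clear_gap(self, small_coi_matrix, small_dataset, prior):
        """Any prior between the intraspecific range and the barcode gap
        recovers the true species partition."""
        _, _, truth = small_dataset
        part = recursive_partition(small_coi_matrix, COI_PARAMS, prior=prior)
        assert part.key() == truth_partition(truth)

    def test_single_species_one_group(self):
        rng = np.random.default_rng(3)
        n = 8
        data = np.triu(rng.uniform(0.001, 0.01, (n, n)), 1)
        dm = DistanceMatrix([f"t{i}" for i in range(n)], data + data.T, "p")
        part = recursive_partition(dm, COI_PARAMS, prior=0.01)
        assert part.n_groups == 1

    def test_two_level_structure_needs_recursion(self):
        """Secondary structure hidden by masking: cluster A is a diffuse
        continuum of distances (0.016..0.0636, even 0.0034 steps) that fills
        the distance range in which cluster B's two subclusters separate
        (~0.058-0.062), so the global ranked-distance list shows no jump
        there and the initial scan splits only at the big A-B gap
        (0.0636 -> 0.40).  Inside B alone the jump 0.014 -> 0.058 is wide
        against B's own small gaps, so recursion resolves B1 | B2."""
        a_ids = [f"a{i}" for i in range(6)]
        b_ids = [f"b{i}" for i in range(6)]  # B1 = b0-b2, B2 = b3-b5
        ids = a_ids + b_ids
        n = len(ids)
        data = np.zeros((n, n))
        a_vals = iter(0.016 + 0.0034 * k for k in range(15))
        for i in range(6):
            for j in range(i + 1, 6):
                data[i, j] = data[j, i] = next(a_vals)
        b_intra = {(0, 1): 0.004, (0, 2): 0.008, (1, 2): 0.012,
                   (3, 4): 0.006, (3, 5): 0.010, (4, 5): 0.014}
        sep = iter(0.058 + 0.0005 * k for k in range(9))
        for i in range(6):
            for j in range(i + 1, 6):
                v = b_intra.get((i, j), None)
                if v is None:
                    v = next(sep)
                data[6 + i, 6 + j] = data[6 + j, 6 + i] = v
        data[:6, 6:] = 0.40
        data[6:, :6] = 0.40
        dm = DistanceMatrix(ids, data, "p")
        params = ABGDParams(p_min=0.001, p_max=0.1, x=2.0, steps=10)
        first = initial_partition(dm, params, prior=0.02)
        assert {frozenset(g) for g in first.groups()} == {
            frozenset(a_ids), frozenset(b_ids)
        }
        rec = recursive_partition(dm, params, prior=0.02)
        assert {frozenset(g) for g in rec.groups()} == {
            frozenset(a_ids), frozenset(b_ids[:3]), frozenset(b_ids[3:])
        }

    def test_recursion_only_refines(self, small_coi_matrix):
        params = COI_PARAMS
        for prior in prior_series(params):
            first = {frozenset(g) for g in initial_partition(small_coi_matrix, params, prior).groups()}
            rec = recursive_partition(small_coi_matrix, params, prior)
            for group in rec.groups():
                assert any(group <= big for big in first)


class TestScanPriors:
    def test_selected_equals_truth(self, small_coi_matrix, small_dataset):
        _, _, truth = small_dataset
        scan = scan_priors(small_coi_matrix, COI_PARAMS)
        assert scan.selected.key() == truth_partition(truth)

    def test_histogram_covers_all_pairs(self, small_coi_matrix):
        scan = scan_priors(small_coi_matrix, COI_PARAMS)
        n = len(small_coi_matrix.ids)
        assert scan.histogram["count"].sum() == n * (n - 1) // 2

    def test_initial_group_count_non_increasing_in_prior(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            dm = random_distance_matrix(rng, int(rng.integers(5, 12)))
            counts = [
                initial_partition(dm, COI_PARAMS, prior).n_groups
                for prior in prior_series(COI_PARAMS)
            ]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_modal_selection_prefers_most_frequent(self):
        def part(prior, groups):
            return Partition.from_groups("COI", prior, [frozenset(g) for g in groups], "initial")

        a = [part(0.001, [{"x", "y"}, {"z"}])]
        b = [part(p, [{"x"}, {"y"}, {"z"}]) for p in (0.01, 0.02)]
        assert select_modal(a + b).key() == b[0].key()

    def test_all_distinct_selects_smallest_prior(self):
        def part(prior, groups):
            return Partition.from_groups("COI", prior, [frozenset(g) for g in groups], "initial")

        parts = [
            part(0.001, [{"x"}, {"y"}, {"z"}]),
            part(0.01, [{"x", "y"}, {"z"}]),
            part(0.1, [{"x", "y", "z"}]),
        ]
        assert select_modal(parts).prior == 0.001
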