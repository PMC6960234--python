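"""Cross-marker reconciliation rule and concordance counting."""

import numpy as np

from barcodekit.abgd import Partition
from barcodekit.consensus import (
    ConsensusThresholds,
    align_partitions,
    build_consensus,
    concordance_report,
    resolve_conflict,
)
from barcodekit.distances import DistanceMatrix


def part(marker, groups):
    return Partition.from_groups(marker, 0.01, [frozenset(g) for g in groups], "initial")


def dmat(ids, value_map, default=0.5):
    n = len(ids)
    data = np.full((n, n), default)
    np.fill_diagonal(data, 0.0)
    for (a, b), v in value_map.items():
        i, j = ids.index(a), ids.index(b)
        data[i, j] = data[j, i] = v
    return DistanceMatrix(list(ids), data, "JC69")


class TestAlignPartitions:
    def test_identical_partitions_no_conflict(self):
        p = part("COI", [{"a", "b"}, {"c", "d"}])
        q = part("16S", [{"a", "b"}, {"c", "d"}])
        blocks = align_partitions(p, q)
        assert len(blocks) == 2
        assert not any(b.is_conflict for b in blocks)

    def test_split_vs_lump_is_one_block(self):
        p = part("COI", [{"a", "b"}, {"c", "d"}])
        q = part("16S", [{"a", "b", "c", "d"}])
        blocks = align_partitions(p, q)
        assert len(blocks) == 1
        assert blocks[0].specimens == frozenset("abcd")
        assert blocks[0].is_conflict

    def test_disjoint_specimen_sets_no_conflict(self):
        p = part("COI", [{"a", "b"}])
        q = part("16S", [{"x", "y"}])
        blocks = align_partitions(p, q)
        assert len(blocks) == 2
        assert not any(b.is_conflict for b in blocks)

    def test_single_marker_specimen_inherits_group(self):
        p = part("COI", [{"a", "b"}])           # c has no COI
        q = part("16S", [{"a", "b", "c"}])
        (block,) = align_partitions(p, q)
        assert not block.is_conflict  # c joins a/b under both readings


class TestResolveConflict:
    ids = list("abcd")

    def _block(self):
        p = part("COI", [{"a", "b"}, {"c", "d"}])
        q = part("16S", [{"a", "b", "c", "d"}])
        (block,) = align_partitions(p, q)
        return block

    def test_divergent_split_accepted_by_coi(self):
        d_coi = dmat(self.ids, {("a", "b"): 0.01, ("c", "d"): 0.01}, default=0.08)
        d_16s = dmat(self.ids, {}, default=0.01)
        groups, outcome = resolve_conflict(self._block(), d_coi, d_16s)
        assert set(groups) == {frozenset("ab"), frozenset("cd")}
        assert outcome == "accepted_by_coi"

    def test_shallow_split_collapsed_by_fewer_otus_rule(self):
        d_coi = dmat(self.ids, {("a", "b"): 0.01, ("c", "d"): 0.01}, default=0.04)
        d_16s = dmat(self.ids, {("a", "b"): 0.005, ("c", "d"): 0.005}, default=0.02)
        groups, outcome = resolve_conflict(self._block(), d_coi, d_16s)
        assert set(groups) == {frozenset("abcd")}
        assert outcome == "fewer_otus"

    def test_boundary_exactly_at_threshold_accepted(self):
        # "at least 0.05" reads inclusive
        d_coi = dmat(self.ids, {("a", "b"): 0.01, ("c", "d"): 0.01}, default=0.05)
        d_16s = dmat(self.ids, {}, default=0.001)
        groups, outcome = resolve_conflict(self._block(), d_coi, d_16s)
        assert set(groups) == {frozenset("ab"), frozenset("cd")}

    def test_rescued_by_16s_divergence(self):
        d_coi = dmat(self.ids, {("a", "b"): 0.01, ("c", "d"): 0.01}, default=0.04)
        d_16s = dmat(self.ids, {("a", "b"): 0.005, ("c", "d"): 0.005}, default=0.03)
        groups, outcome = resolve_conflict(self._block(), d_coi, d_16s)
        assert set(groups) == {frozenset("ab"), frozenset("cd")}
        assert outcome == "accepted_by_16s"

    def test_missing_distances_fall_back_to_coarser(self):
        groups, outcome = resolve_conflict(self._block(), None, None)
        assert set(groups) == {frozenset("abcd")}
        assert outcome == "fewer_otus"


class TestBuildConsensus:
    def _setup(self, coi_default, s16_default):
        p = part("COI", [{"a", "b"}, {"c", "d"}, {"e"}])
        q = part("16S", [{"a", "b", "c", "d"}, {"e"}])
        d_coi = dmat(
            list("abcde"), {("a", "b"): 0.01, ("c", "d"): 0.01}, default=coi_default
        )
        d_16s = dmat(list("abcde"), {("a", "b"): 0.004, ("c", "d"): 0.004}, default=s16_default)
        return p, q, d_coi, d_16s

    def test_zero_like_thresholds_keep_finer(self):
        p, q, d_coi, d_16s = self._setup(0.04, 0.02)
        res = build_consensus(p, q, d_coi, d_16s, ConsensusThresholds(1e-9, 1e-9))
        assert res.n_otus == 3

    def test_huge_thresholds_keep_coarser(self):
        p, q, d_coi, d_16s = self._setup(0.3, 0.3)
        res = build_consensus(p, q, d_coi, d_16s, ConsensusThresholds(0.9, 0.9))
        assert res.n_otus == 2

    def test_final_count_bounded_by_marker_counts(self):
        p, q, d_coi, d_16s = self._setup(0.08, 0.02)
        res = build_consensus(p, q, d_coi, d_16s)
        assert min(p.n_groups, q.n_groups) <= res.n_otus <= max(p.n_groups, q.n_groups)

    def test_order_independent(self):
        p, q, d_coi, d_16s = self._setup(0.08, 0.02)
        res1 = build_consensus(p, q, d_coi, d_16s)
        # rebuild with permuted specimen insertion order
        p2 = Partition("COI", 0.01, dict(sorted(p.mapping.items(), reverse=True)), "initial")
        q2 = Partition("16S", 0.01, dict(sorted(q.mapping.items(), reverse=True)), "initial")
        res2 = build_consensus(p2, q2, d_coi, d_16s)
        assert res1.partition.key() == res2.partition.key()

    def test_conflict_log_records_outcome(self):
        p, q, d_coi, d_16s = self._setup(0.08, 0.02)
        res = build_consensus(p, q, d_coi, d_16s)
        assert len(res.conflicts) == 1
        assert res.conflicts.iloc[0]["outcome"] == "accepted_by_coi"


class TestConcordance:
    def test_perfect_recovery_all_single_name(self):
        final = part("consensus", [{"a", "b"}, {"c", "d"}])
        names = {"a": "X y", "b": "X y", "c": "Z w", "d": "Z w"}
        rep = concordance_report(final, names)
        assert rep.n_otus == 2
        assert rep.n_single_name == 2
        assert rep.n_multi_name == 0 and rep.n_split_morphospecies == 0

    def test_multi_name_otu_counted(self):
        final = part("consensus", [{"a", "b"}])
        rep = concordance_report(final, {"a": "X y", "b": "X z"})
        assert rep.n_multi_name == 1

    def test_split_morphospecies_counted(self):
        # one name spanning two OTUs (e.g. 8 + 1 specimens of the same
        # nominal species falling into separate clusters)
        final = part("consensus", [{f"s{i}" for i in range(8)}, {"s8"}])
        names = {f"s{i}": "Tozeuma-like sp" for i in range(9)}
        rep = concordance_report(final, names)
        assert rep.n_split_morphospecies == 1
        assert rep.n_single_name == 2  # each OTU itself carries one name
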