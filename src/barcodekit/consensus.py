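"""Cross-marker OTU reconciliation and morphospecies concordance.

When the COI and 16S partitions disagree about a set of specimens, the
finer grouping is accepted only if every extra group it proposes diverges
from everything else in the conflict block by at least 0.05 substitutions
per site in COI **or** 0.03 in 16S; otherwise the option producing fewer
OTUs wins.  Divergence is the minimum inter-group distance within the
conflict block (the conflict is local, so the check is local too).
Specimens sequenced for a single marker inherit that marker's group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .abgd import Partition
from .distances import DistanceMatrix


@dataclass(frozen=True)
class ConsensusThresholds:
    """Minimum divergence ("at least", so inclusive) for accepting a split."""

    min_div_coi: float = 0.05
    min_div_16s: float = 0.03

    def __post_init__(self) -> None:
        if self.min_div_coi <= 0 or self.min_div_16s <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ConflictBlock:
    specimens: frozenset[str]
    coi_groups: list[frozenset[str]]
    rrna_groups: list[frozenset[str]]

    @property
    def is_conflict(self) -> bool:
        return set(self.coi_groups) != set(self.rrna_groups)


@dataclass
class ConsensusResult:
    partition: Partition
    conflicts: pd.DataFrame  # block, outcome, n_fine, n_coarse, specimens

    @property
    def n_otus(self) -> int:
        return self.partition.n_groups


def _extend_grouping(
    block: frozenset[str],
    own: dict[str, int],
    other: dict[str, int],
) -> list[frozenset[str]]:
    """Grouping a marker implies on a block, with single-marker specimens
    attached via their other-marker co-group (or kept as their own group)."""
    groups: dict[int, set[str]] = {}
    orphans: list[str] = []
    for sid in block:
        if sid in own:
            groups.setdefault(own[sid], set()).add(sid)
        else:
            orphans.append(sid)
    extra: dict[int, set[str]] = {}
    for sid in sorted(orphans):
        mates = sorted(
            s for s in block
            if s != sid and s in other and sid in other and other[s] == other[sid] and s in own
        )
        if mates:
            groups[own[mates[0]]].add(sid)
        else:
            key = other.get(sid, -1)
            extra.setdefault(key, set()).add(sid)
    out = [frozenset(g) for g in groups.values()]
    out.extend(frozenset(g) for g in extra.values())
    return out


def align_partitions(p_coi: Partition, p_16s: Partition) -> list[ConflictBlock]:
    """Partition the joint specimen space into blocks linked by either marker.

    Returns the connected components of the join graph, each carrying the
    grouping every marker implies on it; blocks where the two groupings
    coincide are non-conflicts.
    """
    specimens = sorted(set(p_coi.mapping) | set(p_16s.mapping))
    parent = {s: s for s in specimens}

    def find(s: str) -> str:
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for mapping in (p_coi.mapping, p_16s.mapping):
        by_group: dict[int, list[str]] = {}
        for sid, gid in mapping.items():
            by_group.setdefault(gid, []).append(sid)
        for members in by_group.values():
            members = sorted(members)
            for other in members[1:]:
                union(members[0], other)

    comps: dict[str, set[str]] = {}
    for s in specimens:
        comps.setdefault(find(s), set()).add(s)

    blocks = []
    for members in sorted(comps.values(), key=min):
        block = frozenset(members)
        blocks.append(
            ConflictBlock(
                specimens=block,
                coi_groups=sorted(
                    _extend_grouping(block, p_coi.mapping, p_16s.mapping), key=min
                ),
                rrna_groups=sorted(
                    _extend_grouping(block, p_16s.mapping, p_coi.mapping), key=min
                ),
            )
        )
    return blocks


def _min_intergroup_distance(
    group: frozenset[str], rest: frozenset[str], dm: Optional[DistanceMatrix]
) -> Optional[float]:
    """Smallest distance from any group member to any outside specimen,
    over pairs present in the matrix; None when no pair is measurable."""
    if dm is None:
        return None
    ids = set(dm.ids)
    a = [s for s in group if s in ids]
    b = [s for s in rest if s in ids]
    if not a or not b:
        return None
    ia = [dm.ids.index(s) for s in a]
    ib = [dm.ids.index(s) for s in b]
    return float(dm.data[np.ix_(ia, ib)].min())


def _meet(a: Sequence[frozenset[str]], b: Sequence[frozenset[str]]) -> list[frozenset[str]]:
    out = []
    for ga in a:
        for gb in b:
            inter = ga & gb
            if inter:
                out.append(frozenset(inter))
    return sorted(out, key=min)


def resolve_conflict(
    block: ConflictBlock,
    d_coi: Optional[DistanceMatrix],
    d_16s: Optional[DistanceMatrix],
    thresholds: ConsensusThresholds = ConsensusThresholds(),
) -> tuple[list[frozenset[str]], str]:
    """Resolve one conflict block; returns (groups, outcome tag).

    The finer candidate (the markers' common refinement when they cross)
    is accepted only if each of its extra groups clears the COI or the 16S
    divergence floor against the rest of the block; otherwise the
    coarser candidate wins (``fewer_otus``).
    """
    a, b = block.coi_groups, block.rrna_groups
    if set(a) == set(b):
        return list(a), "no_conflict"
    fine = _meet(a, b)
    coarse = a if len(a) <= len(b) else b
    if len(fine) == len(coarse):  # crossing with equal counts: join is one group
        coarse = [block.specimens]

    coarse_set = set(coarse)
    any_16s = False
    unresolved = False
    for group in fine:
        if group in coarse_set:
            continue
        rest = block.specimens - group
        if not rest:
            continue
        m_coi = _min_intergroup_distance(group, rest, d_coi)
        m_16s = _min_intergroup_distance(group, rest, d_16s)
        if m_coi is None and m_16s is None:
            unresolved = True
            break
        if m_coi is not None and m_coi >= thresholds.min_div_coi:
            continue
        if m_16s is not None and m_16s >= thresholds.min_div_16s:
            any_16s = True
            continue
        unresolved = True
        break

    if unresolved:
        return list(coarse), "fewer_otus"
    return list(fine), ("accepted_by_16s" if any_16s else "accepted_by_coi")


def build_consensus(
    p_coi: Partition,
    p_16s: Partition,
    d_coi: Optional[DistanceMatrix],
    d_16s: Optional[DistanceMatrix],
    thresholds: ConsensusThresholds = ConsensusThresholds(),
) -> ConsensusResult:
    """Reconcile per-marker partitions into the final consensus OTUs."""
    blocks = align_partitions(p_coi, p_16s)
    final_groups: list[frozenset[str]] = []
    log_rows = []
    for idx, block in enumerate(blocks):
        if not block.is_conflict:
            final_groups.extend(block.coi_groups)
            continue
        groups, outcome = resolve_conflict(block, d_coi, d_16s, thresholds)
        final_groups.extend(groups)
        log_rows.append(
            {
                "block": idx,
                "specimens": ";".join(sorted(block.specimens)),
                "n_coi_groups": len(block.coi_groups),
                "n_16s_groups": len(block.rrna_groups),
                "n_final_groups": len(groups),
                "outcome": outcome,
            }
        )
    partition = Partition.from_groups("consensus", float("nan"), final_groups, "consensus")
    log = pd.DataFrame(
        log_rows,
        columns=["block", "specimens", "n_coi_groups", "n_16s_groups", "n_final_groups", "outcome"],
    )
    return ConsensusResult(partition, log)


@dataclass
class ConcordanceSummary:
    per_otu: pd.DataFrame
    n_otus: int
    n_single_name: int
    n_multi_name: int
    n_split_morphospecies: int


def concordance_report(
    final: Partition, morphospecies: dict[str, str]
) -> ConcordanceSummary:
    """Compare OTUs against morphology-based names.

    Counts OTUs carrying exactly one morphospecies name, OTUs lumping
    several names (possible synonymies or over-splitting by morphology),
    and morphospecies split across several OTUs (potential cryptic species).
    """
    rows = []
    names_to_otus: dict[str, set[int]] = {}
    for gid, group in enumerate(final.groups()):
        names = sorted({morphospecies.get(s, "?") for s in group})
        for name in names:
            names_to_otus.setdefault(name, set()).add(gid)
        rows.append(
            {
                "otu_id": gid,
                "n_individuals": len(group),
                "n_names": len(names),
                "morphospecies": ";".join(names),
            }
        )
    per_otu = pd.DataFrame(rows, columns=["otu_id", "n_individuals", "n_names", "morphospecies"])
    n_single = int((per_otu["n_names"] == 1).sum())
    n_multi = int((per_otu["n_names"] > 1).sum())
    n_split = sum(1 for otus in names_to_otus.values() if len(otus) > 1)
    return ConcordanceSummary(per_otu, len(rows), n_single, n_multi, n_split)
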