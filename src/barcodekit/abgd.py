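"""Automatic Barcode Gap Discovery (ABGD) OTU delimitation.

The method assumes that, when a sample mixes several species, the pairwise
distance distribution is bimodal: small intraspecific distances, larger
interspecific ones, separated by a "barcode gap".  Given a prior maximal
intraspecific divergence P, the detector scans the ranked distances for the
first conspicuously wide jump beyond P, partitions the sample by single
linkage below that gap, and recurses inside each group (secondary gaps can
hide within coarse groups).  The whole procedure is repeated over a
geometric series of priors from ``p_min`` to ``p_max``; the partition
returned most often across the series is selected.

Gap significance is relative: a candidate jump ``g`` counts only if
``g > x * s`` where ``s`` estimates the local gap scale (the mean of the
preceding consecutive gaps, or the median of all gaps when too few
precede).  Smaller ``x`` therefore makes the detector more sensitive —
which is why shallowly diverged markers need ``x`` below the usual 1.5.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix


@dataclass(frozen=True)
class ABGDParams:
    """Prior series and gap-detection settings.

    p_min, p_max : bounds of the geometric prior series on maximal
        intraspecific divergence.
    x : relative gap width — a jump must exceed ``x`` times the local gap
        scale to count as the barcode gap.
    steps : number of priors in the series.
    min_gap_context : minimum number of preceding gaps required before the
        local mean is trusted over the global median.
    """

    p_min: float = 0.001
    p_max: float = 0.1
    x: float = 1.125
    steps: int = 10
    min_gap_context: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.p_min < self.p_max < 1:
            raise ValueError("need 0 < p_min < p_max < 1")
        if self.x <= 1:
            raise ValueError("x must exceed 1")
        if self.steps < 2:
            raise ValueError("steps must be >= 2")


COI_PARAMS = ABGDParams(p_min=0.001, p_max=0.1, x=1.125, steps=10)
RRNA_PARAMS = ABGDParams(p_min=0.001, p_max=0.05, x=1.5, steps=10)


@dataclass(frozen=True)
class GapResult:
    found: bool
    lower_edge: float = float("nan")
    upper_edge: float = float("nan")
    threshold: float = float("nan")
    rank_index: int = -1


@dataclass
class Partition:
    """Assignment of specimens to OTU groups.

    Group ids are consecutive integers ordered by each group's smallest
    member id, so identical groupings always serialise identically.
    """

    marker: str
    prior: float
    mapping: dict[str, int]
    provenance: str = "initial"

    @classmethod
    def from_groups(
        cls, marker: str, prior: float, groups: Sequence[frozenset[str]], provenance: str
    ) -> "Partition":
        ordered = sorted(groups, key=lambda g: min(g))
        mapping = {sid: gid for gid, group in enumerate(ordered) for sid in sorted(group)}
        return cls(marker, prior, mapping, provenance)

    def groups(self) -> list[frozenset[str]]:
        out: dict[int, set[str]] = {}
        for sid, gid in self.mapping.items():
            out.setdefault(gid, set()).add(sid)
        return [frozenset(out[g]) for g in sorted(out)]

    def key(self) -> frozenset[frozenset[str]]:
        """Canonical grouping identity, ignoring group labels."""
        return frozenset(self.groups())

    @property
    def n_groups(self) -> int:
        return len(set(self.mapping.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"specimen_id": sid, "otu_id": gid, "prior": self.prior}
            for sid, gid in sorted(self.mapping.items())
        ]
        return pd.DataFrame(rows, columns=["specimen_id", "otu_id", "prior"])


def prior_series(params: ABGDParams) -> list[float]:
    """Geometric series of priors: P_k = p_min * (p_max/p_min)^(k/(steps-1))."""
    ratio = params.p_max / params.p_min
    series = [
        params.p_min * ratio ** (k / (params.steps - 1)) for k in range(params.steps)
    ]
    series[0], series[-1] = params.p_min, params.p_max  # endpoints exact
    return series


def find_gap(
    sorted_distances: Sequence[float],
    prior: float,
    x: float,
    min_gap_context: int = 2,
    slope_window: int = 10,
) -> GapResult:
    """Locate the first significant distance gap beyond the prior.

    Scans consecutive gaps ``g_i = d[i+1] - d[i]`` in rank order; a gap is
    a candidate iff its upper edge exceeds *prior* and significant iff it is
    more than *x* times the local gap scale — the mean of the (up to
    *slope_window*) immediately preceding gaps.  A local window, rather
    than all preceding gaps, estimates the slope of the ranked-distance
    curve where the candidate sits; a global mean is dragged toward zero
    by the many near-tied small distances at the bottom of the ranking and
    would declare ordinary spacing in the distance continuum significant.
    When fewer than *min_gap_context* gaps precede, the median of all gaps
    is used instead.  The partition threshold is the gap midpoint.
    """
    d = list(sorted_distances)
    if len(d) < 2:
        return GapResult(found=False)
    if any(b < a for a, b in zip(d, d[1:])):
        raise ValueError("distances must be sorted ascending")
    gaps = [b - a for a, b in zip(d, d[1:])]
    overall = statistics.median(gaps)
    for i, g in enumerate(gaps):
        if d[i + 1] <= prior:
            continue
        preceding = gaps[max(0, i - slope_window) : i]
        scale = (
            statistics.fmean(preceding) if len(preceding) >= min_gap_context else overall
        )
        if g > x * scale:
            return GapResult(
                found=True,
                lower_edge=d[i],
                upper_edge=d[i + 1],
                threshold=(d[i] + d[i + 1]) / 2,
                rank_index=i,
            )
    return GapResult(found=False)


def single_linkage(dm: DistanceMatrix, threshold: float, prior: float = float("nan")) -> Partition:
    """Connected components of the graph with edges ``d(i,j) < threshold``.

    Edges strictly below the threshold, so the gap itself is never bridged.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    adj = csr_matrix(dm.data < threshold)
    _, labels = connected_components(adj, directed=False)
    groups: dict[int, set[str]] = {}
    for sid, lab in zip(dm.ids, labels):
        groups.setdefault(int(lab), set()).add(sid)
    return Partition.from_groups(
        marker="", prior=prior, groups=[frozenset(g) for g in groups.values()],
        provenance="initial",
    )


def recursive_partition(
    dm: DistanceMatrix, params: ABGDParams, prior: float, marker: str = ""
) -> Partition:
    """Split at the detected gap, then recurse independently inside each
    group using only intra-group distances.

    Recursion stops when no significant gap remains or a group has fewer
    than 3 members (a 2-member group has a single internal distance, so no
    gap is definable).
    """

    def _split(sub: DistanceMatrix) -> list[frozenset[str]]:
        dists = np.sort(sub.condensed())
        gap = find_gap(dists, prior, params.x, params.min_gap_context)
        if not gap.found:
            return [frozenset(sub.ids)]
        part = single_linkage(sub, gap.threshold)
        groups = part.groups()
        if len(groups) == 1:
            return groups
        out: list[frozenset[str]] = []
        for group in groups:
            if len(group) >= 3:
                out.extend(_split(sub.submatrix(sorted(group))))
            else:
                out.append(group)
        return out

    groups = _split(dm)
    return Partition.from_groups(marker, prior, groups, provenance="recursive")


def initial_partition(
    dm: DistanceMatrix, params: ABGDParams, prior: float, marker: str = ""
) -> Partition:
    """One-shot (non-recursive) split at the first detected gap."""
    dists = np.sort(dm.condensed())
    gap = find_gap(dists, prior, params.x, params.min_gap_context)
    if not gap.found:
        return Partition.from_groups(marker, prior, [frozenset(dm.ids)], "initial")
    part = single_linkage(dm, gap.threshold, prior)
    return Partition.from_groups(marker, prior, part.groups(), "initial")


@dataclass
class ScanResult:
    priors: list[float]
    partitions: list[Partition]
    selected: Partition
    histogram: pd.DataFrame

    def group_counts(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "prior": self.priors,
                "n_groups": [p.n_groups for p in self.partitions],
            }
        )


def distance_histogram(dm: DistanceMatrix, bin_width: float = 0.005) -> pd.DataFrame:
    """Histogram of pairwise distances (prior-choice diagnostic)."""
    d = dm.condensed()
    upper = max(float(d.max()), bin_width) if len(d) else bin_width
    edges = np.arange(0.0, upper + bin_width, bin_width)
    counts, edges = np.histogram(d, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def scan_priors(dm: DistanceMatrix, params: ABGDParams, marker: str = "") -> ScanResult:
    """Delimit at every prior in the series and select the modal partition.

    The selected partition is the grouping produced by the largest number
    of priors; ties go to the grouping first seen at the smaller prior.
    """
    priors = prior_series(params)
    partitions = [recursive_partition(dm, params, p, marker) for p in priors]
    return ScanResult(priors, partitions, select_modal(partitions), distance_histogram(dm))


def select_modal(partitions: Sequence[Partition]) -> Partition:
    """Most frequent identical grouping; ties go to the smallest prior
    (partitions are assumed ordered by increasing prior)."""
    tally: dict[frozenset, int] = {}
    first_seen: dict[frozenset, int] = {}
    for idx, part in enumerate(partitions):
        k = part.key()
        tally[k] = tally.get(k, 0) + 1
        first_seen.setdefault(k, idx)
    best_key = max(tally, key=lambda k: (tally[k], -first_seen[k]))
    return partitions[first_seen[best_key]]
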