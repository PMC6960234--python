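"""Pairwise nucleotide distances with pairwise deletion.

Distances are computed under three models on the proportion of differing
sites *p* (and, for K2P, the transition/transversion split P/Q):

* ``p``    — uncorrected p-distance, d = p
* ``JC69`` — Jukes–Cantor one-parameter correction,
  d = -(3/4) ln(1 - (4/3) p)
* ``K2P``  — Kimura two-parameter correction,
  d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)

Sites where either sequence carries a gap or an ambiguity code are dropped
for that pair only (pairwise deletion) — the standard barcoding convention,
which keeps indel-rich 16S pairs comparable.  Saturated pairs (outside a
model's domain) raise :class:`SaturationError` rather than emitting NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

MODELS = ("p", "JC69", "K2P")

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i  # A=0 C=1 G=2 T=3; everything else (gaps, N, R, ...) = 4


class SaturationError(ValueError):
    """Observed divergence outside the distance model's domain."""


class IncomparablePairError(ValueError):
    """A sequence pair shares no comparable (ungapped, unambiguous) site."""


@dataclass
class AlignedMarkerSet:
    """An aligned set of sequences for one marker (equal row lengths)."""

    marker: str
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows are not aligned: lengths {sorted(lengths)}")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")

    def encoded(self) -> np.ndarray:
        arr = np.frombuffer("".join(r.upper() for r in self.rows).encode(), dtype=np.uint8)
        return _CODE[arr.reshape(len(self.rows), -1)]

    def resample_columns(self, rng: np.random.Generator) -> "AlignedMarkerSet":
        """Bootstrap replicate: columns drawn with replacement."""
        length = len(self.rows[0])
        cols = rng.integers(0, length, size=length)
        rows = ["".join(row[c] for c in cols) for row in self.rows]
        return AlignedMarkerSet(self.marker, list(self.ids), rows)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances tagged with the model that produced them."""

    ids: list[str]
    data: np.ndarray
    model: str
    comparable_sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.data) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite distances")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.data[i, j])

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in row-major order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.data[iu]

    def submatrix(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in keep]
        sub = self.data[np.ix_(idx, idx)]
        cs = None
        if self.comparable_sites is not None:
            cs = self.comparable_sites[np.ix_(idx, idx)]
        return DistanceMatrix(list(keep), sub, self.model, cs)

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for name, row in zip(self.ids, self.data):
                fh.write(name + "\t" + "\t".join(f"{v:.9f}" for v in row) + "\n")

    @classmethod
    def from_phylip(cls, path: str | Path, model: str = "p") -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            ids, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                ids.append(parts[0])
                rows.append([float(v) for v in parts[1 : n + 1]])
        return cls(ids, np.array(rows), model)


def pairwise_counts(row_i: str, row_j: str) -> tuple[int, int, int, int]:
    """Count (comparable_sites, differences, transitions, transversions)
    between two aligned rows under pairwise deletion.

    Transitions are A<->G and C<->T; all other mismatches are transversions.
    """
    if len(row_i) != len(row_j):
        raise ValueError("rows must have equal aligned length")
    a = _CODE[np.frombuffer(row_i.upper().encode(), dtype=np.uint8)]
    b = _CODE[np.frombuffer(row_j.upper().encode(), dtype=np.uint8)]
    valid = (a < 4) & (b < 4)
    diff = valid & (a != b)
    # purines A(0), G(2) have even codes; pyrimidines C(1), T(3) odd
    ts = diff & ((a % 2) == (b % 2))
    n_diff = int(diff.sum())
    n_ts = int(ts.sum())
    return int(valid.sum()), n_diff, n_ts, n_diff - n_ts


def jc69(p: float) -> float:
    """Jukes–Cantor distance from a proportion of differing sites."""
    if not 0 <= p < 0.75:
        raise SaturationError(f"JC69 undefined for p = {p} (needs 0 <= p < 0.75)")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def k2p(P: float, Q: float) -> float:
    """Kimura two-parameter distance from transition (P) and transversion
    (Q) proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P undefined for P = {P}, Q = {Q}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def build_matrix(aln: AlignedMarkerSet, model: str = "JC69") -> DistanceMatrix:
    """Compute the full pairwise distance matrix under *model*.

    Any pair without comparable sites, or outside the model's domain, is a
    hard error naming the offending pair(s).
    """
    return matrix_from_encoded(list(aln.ids), aln.encoded(), model)


def matrix_from_encoded(ids: list[str], enc: np.ndarray, model: str = "JC69") -> DistanceMatrix:
    """Distance matrix from pre-encoded rows (codes 0-3 = ACGT, 4 = excluded).

    Fast path shared by :func:`build_matrix` and the bootstrap, which
    resamples encoded columns directly.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    valid_rows = enc < 4
    purine = (enc % 2) == 0
    D = np.zeros((n, n))
    CS = np.zeros((n, n), dtype=int)
    bad_pairs: list[tuple[str, str, str]] = []
    for i in range(n - 1):
        valid = valid_rows[i] & valid_rows[i + 1 :]
        diff = valid & (enc[i] != enc[i + 1 :])
        ts = diff & (purine[i] == purine[i + 1 :])
        comparable = valid.sum(axis=1)
        n_diff = diff.sum(axis=1)
        n_ts = ts.sum(axis=1)
        for k, j in enumerate(range(i + 1, n)):
            CS[i, j] = CS[j, i] = comparable[k]
            if comparable[k] == 0:
                bad_pairs.append((ids[i], ids[j], "no comparable sites"))
                continue
            p = n_diff[k] / comparable[k]
            try:
                if model == "p":
                    d = p
                elif model == "JC69":
                    d = jc69(p)
                else:
                    d = k2p(n_ts[k] / comparable[k], (n_diff[k] - n_ts[k]) / comparable[k])
            except SaturationError as exc:
                bad_pairs.append((ids[i], ids[j], str(exc)))
                continue
            D[i, j] = D[j, i] = d
    if bad_pairs:
        listing = "; ".join(f"{a} vs {b}: {why}" for a, b, why in bad_pairs)
        if any("no comparable" in why for *_ignored, why in bad_pairs):
            raise IncomparablePairError(listing)
        raise SaturationError(listing)
    return DistanceMatrix(list(ids), D, model, CS)


def records_to_alignment(records, marker: str) -> AlignedMarkerSet:
    """Build an :class:`AlignedMarkerSet` from records of one marker.

    Unaligned (unequal-length) inputs are rejected; the pipeline consumes
    pre-aligned FASTA.
    """
    recs = [r for r in records if r.marker == marker]
    return AlignedMarkerSet(marker, [r.specimen_id for r in recs], [r.residues for r in recs])
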