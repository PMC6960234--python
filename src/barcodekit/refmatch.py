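"""Identity-based matching against a local reference library.

A deterministic stand-in for BLAST searches of GenBank/BOLD: each query is
globally aligned (affine gaps, terminal gaps free — appropriate for
near-full-length amplicons of the same locus) against every reference, and
classified by percent identity: sequences > 95% identical to a non-target
(non-decapod) reference are contamination; COI queries are "known" above
95% identity to a target reference and "new additions" otherwise; 16S uses
a 97% threshold.  Thresholds are strict, so boundary values classify as
new/kept.

The aligner maximises, lexicographically, (alignment score, number of
matches, minus aligned columns), which makes the reported identity
deterministic even when several alignments share the optimal score.
Scoring: match +1, mismatch -1, gap open -5 (first gap column), gap extend
-2.  Identity = 100 x matches / aligned columns, terminal-gap columns
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -1, -5, -2

# lexicographic packing: combined = score*_S1 + matches*_S2 - columns
_S2 = 1 << 12
_S1 = 1 << 26
_NEG = np.int64(-(1 << 50))


@dataclass(frozen=True)
class NoveltyThresholds:
    """Percent-identity cutoffs (strict comparisons)."""

    coi_known_identity: float = 95.0
    rrna_known_identity: float = 97.0
    contaminant_identity: float = 95.0

    def __post_init__(self) -> None:
        for v in (self.coi_known_identity, self.rrna_known_identity, self.contaminant_identity):
            if not 0 < v <= 100:
                raise ValueError("thresholds must be in (0, 100]")

    def known_cut(self, marker: str) -> float:
        return self.coi_known_identity if marker == "COI" else self.rrna_known_identity


@dataclass
class ReferenceSeq:
    ref_id: str
    taxon: str
    target: bool
    residues: str


@dataclass
class MatchResult:
    query_id: str
    best_ref: Optional[str]
    best_taxon: Optional[str]
    identity: float
    classification: str  # known | new | contaminant
    name_concordance: str


def read_reference_library(path: str | Path) -> list[ReferenceSeq]:
    """Read a FASTA with headers ``refID|taxon_name|target_or_nontarget``."""
    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description or rec.id
        parts = header.split("|")
        if len(parts) != 3 or parts[2] not in ("target", "nontarget"):
            raise ValueError(
                f"reference header {header!r} must be 'refID|taxon_name|target_or_nontarget'"
            )
        refs.append(
            ReferenceSeq(parts[0], parts[1], parts[2] == "target", str(rec.seq).upper().replace("-", ""))
        )
    return refs


def _align_combined(a: str, b: str) -> int:
    """Packed (score, matches, -columns) of the optimal overlap alignment."""
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    n, m = len(x), len(y)
    d_match = np.int64(MATCH * _S1 + _S2 - 1)
    d_mis = np.int64(MISMATCH * _S1 - 1)
    d_open = np.int64(GAP_OPEN * _S1 - 1)
    d_ext = np.int64(GAP_EXTEND * _S1 - 1)

    # rows over a; free leading/trailing gaps via zero boundary and final max
    prev_B = np.zeros(m + 1, dtype=np.int64)  # B[0][j] = 0 (skip prefix of b)
    prev_X = np.full(m + 1, _NEG)
    best_end = np.int64(0) if (n == 0 or m == 0) else _NEG
    ks = np.arange(m, dtype=np.int64)
    for i in range(1, n + 1):
        sub = np.where(y == x[i - 1], d_match, d_mis)
        M = prev_B[:-1] + sub  # M[j] for j=1..m
        X = np.maximum(prev_B[1:] + d_open, prev_X[1:] + d_ext)
        base = np.maximum(M, X)
        # Y[j] = max_{k<j} base[k] + open + (j-1-k)*ext   (gap in a, along b)
        acc = np.maximum.accumulate(base - ks * d_ext)
        Y = np.full(m, _NEG)
        if m > 1:
            Y[1:] = acc[:-1] + d_open + (ks[1:] - 1) * d_ext
        B = np.maximum(base, Y)
        cur_B = np.empty(m + 1, dtype=np.int64)
        cur_B[0] = 0  # skip prefix of a (free leading gap)
        cur_B[1:] = B
        cur_X = np.empty(m + 1, dtype=np.int64)
        cur_X[0] = _NEG
        cur_X[1:] = X
        if i == n:
            best_end = max(best_end, int(cur_B.max()))  # trailing b free
        best_end = max(best_end, int(cur_B[m]))  # trailing a free
        prev_B, prev_X = cur_B, cur_X
    return int(best_end)


def _decode(combined: int) -> tuple[int, int, int]:
    score = int(round(combined / _S1))
    low = combined - score * _S1
    matches = -((-low) // _S2)
    columns = matches * _S2 - low
    return score, matches, columns


def align_stats(a: str, b: str) -> tuple[int, int, int]:
    """(score, matches, aligned_columns) of the optimal overlap alignment,
    with the documented tie-break (max matches, then fewest columns)."""
    if not a or not b:
        raise ValueError("empty sequence")
    return _decode(_align_combined(a.upper(), b.upper()))


def pairwise_identity(query: str, reference: str) -> float:
    """Percent identity over aligned columns, terminal gaps excluded."""
    _, matches, columns = align_stats(query, reference)
    if columns == 0:
        return 0.0
    return 100.0 * matches / columns


def effective_identity(query: str, reference: str, min_coverage: float = 0.5) -> float:
    """Identity for classification: 0 when the optimal alignment covers
    less than *min_coverage* of the shorter sequence.

    With terminal gaps free, two unrelated sequences can share a short
    perfect overlap whose raw identity is high; amplicons of the same
    locus, by contrast, align near-full-length.  The coverage floor keeps
    short accidental overlaps from masquerading as database matches."""
    _, matches, columns = align_stats(query, reference)
    if columns == 0 or columns < min_coverage * min(len(query), len(reference)):
        return 0.0
    return 100.0 * matches / columns


def classify_novelty(
    best_identity: float, marker: str, thresholds: NoveltyThresholds = NoveltyThresholds()
) -> str:
    """``known`` strictly above the marker's cutoff, else ``new``."""
    return "known" if best_identity > thresholds.known_cut(marker) else "new"


def screen_contamination(
    query: str,
    nontarget_refs: Sequence[ReferenceSeq],
    threshold: float = 95.0,
    min_coverage: float = 0.5,
) -> bool:
    """True (drop) iff best identity to any non-target reference is > threshold."""
    for ref in nontarget_refs:
        if effective_identity(query, ref.residues, min_coverage) > threshold:
            return True
    return False


_QUALIFIERS = {"cf.", "aff.", "nr.", "cf", "aff", "nr"}


def _parse_name(name: str) -> Optional[tuple[str, Optional[str]]]:
    parts = [p for p in name.strip().split() if p.lower() not in _QUALIFIERS]
    if not parts or not parts[0][0].isalpha():
        return None
    genus = parts[0]
    epithet = parts[1] if len(parts) > 1 else None
    if epithet is not None and epithet.lower() in ("sp.", "sp", "spp.", "spp"):
        epithet = None
    return genus, epithet


def name_concordance(query_name: str, reference_name: str) -> str:
    """Compare two binomials (qualifiers like cf./aff./nr. stripped).

    concordant: genus and epithet equal; better_resolution: same genus and
    only the query carries an epithet; discordant_species: same genus,
    different epithets; discordant_higher: different genus; n/a: unparsable.
    """
    q = _parse_name(query_name) if query_name else None
    r = _parse_name(reference_name) if reference_name else None
    if q is None or r is None:
        return "n/a"
    if q[0] != r[0]:
        return "discordant_higher"
    if q[1] == r[1]:
        return "concordant" if q[1] is not None else "concordant"
    if r[1] is None and q[1] is not None:
        return "better_resolution"
    if q[1] is None:
        return "discordant_species"
    return "discordant_species"


def match_query(
    query: str,
    query_id: str,
    marker: str,
    refs: Sequence[ReferenceSeq],
    thresholds: NoveltyThresholds = NoveltyThresholds(),
    query_name: str = "",
) -> MatchResult:
    """Best-hit classification of one query against the library.

    Non-target hits above the contamination threshold dominate; otherwise
    the best target hit (ties to the lexicographically smallest ref id)
    decides known/new and name concordance.
    """
    nontargets = [r for r in refs if not r.target]
    if screen_contamination(query, nontargets, thresholds.contaminant_identity):
        hits = sorted(
            ((effective_identity(query, r.residues), r) for r in nontargets),
            key=lambda t: (-t[0], t[1].ref_id),
        )
        ident, ref = hits[0]
        return MatchResult(query_id, ref.ref_id, ref.taxon, ident, "contaminant", "n/a")
    targets = [r for r in refs if r.target]
    if not targets:
        return MatchResult(query_id, None, None, 0.0, "new", "n/a")
    hits = sorted(
        ((effective_identity(query, r.residues), r) for r in targets),
        key=lambda t: (-t[0], t[1].ref_id),
    )
    ident, ref = hits[0]
    cls = classify_novelty(ident, marker, thresholds)
    concord = name_concordance(query_name, ref.taxon) if cls == "known" else "n/a"
    return MatchResult(query_id, ref.ref_id, ref.taxon, ident, cls, concord)


def match_table(results: Iterable[MatchResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_id": r.query_id,
                "best_ref": r.best_ref or "",
                "best_taxon": r.best_taxon or "",
                "identity": r.identity,
                "class": r.classification,
                "name_concordance": r.name_concordance,
            }
            for r in results
        ],
        columns=["query_id", "best_ref", "best_taxon", "identity", "class", "name_concordance"],
    )
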