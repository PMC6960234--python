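"""Screening coding barcodes for mitochondrial pseudogene (NUMT) signatures.

Nuclear copies of mitochondrial genes escape the functional constraints of
the organellar original, so they accumulate frame-disrupting indels,
in-frame stop codons, unusual amino-acid changes, and drift toward the
nuclear genome's base composition.  The screen therefore flags, per
sequence: stop codons under the invertebrate mitochondrial code (table 5,
where AGA/AGG encode serine and TGA tryptophan — only TAA/TAG stop),
length or gap patterns inconsistent with the reading frame, outlying GC
content relative to the marker cohort, and translations far from the
cohort consensus.  A positive COI–16S GC correlation across specimens is
the expected mitochondrial signature; its absence in a subset is a
pseudogene warning sign.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .records import SequenceRecord

INVERTEBRATE_MT_TABLE = 5


def count_stops(seq: str, frame: int, table: int = INVERTEBRATE_MT_TABLE) -> int:
    """Number of in-frame stop codons; the trailing partial codon is ignored."""
    if frame not in (1, 2, 3):
        raise ValueError("frame must be 1, 2 or 3")
    sub = seq.upper().replace("-", "")[frame - 1 :]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return 0
    return str(Seq(sub).translate(table=table)).count("*")


def best_reading_frame(seq: str, table: int = INVERTEBRATE_MT_TABLE) -> tuple[int, int]:
    """Frame (1-3) minimising the stop count; ties go to the lowest frame."""
    if len(seq.replace("-", "")) < 6:
        raise ValueError("sequence too short to frame")
    counts = [(count_stops(seq, f, table), f) for f in (1, 2, 3)]
    n, f = min(counts)
    return f, n


def detect_frameshift(
    seq: str,
    reference_length_mod3: int,
    aligned: bool = False,
) -> bool:
    """Flag a frame-disrupting indel.

    Alignment-free mode compares ungapped length mod 3 against the
    expectation; aligned mode additionally flags any internal gap run whose
    length is not a multiple of 3 (an in-frame 3n-base indel is tolerated).
    """
    ungapped = seq.replace("-", "")
    if len(ungapped) % 3 != reference_length_mod3 % 3:
        return True
    if aligned:
        inner = seq.strip("-")
        run = 0
        for ch in inner:
            if ch == "-":
                run += 1
            elif run:
                if run % 3 != 0:
                    return True
                run = 0
    return False


def gc_percent(seq: str) -> float:
    """GC% over ungapped, unambiguous (ACGT) bases."""
    s = seq.upper()
    counts = Counter(s)
    denom = sum(counts[b] for b in "ACGT")
    if denom == 0:
        raise ValueError("no unambiguous bases")
    return 100.0 * (counts["G"] + counts["C"]) / denom


@dataclass
class GCStats:
    per_sequence: pd.DataFrame  # specimen_id, gc_pct, gc_z, gc_outlier
    gc_min: float
    gc_max: float
    mean: float
    sd: float
    excluded: list[str] = field(default_factory=list)


def gc_stats(records: Sequence[SequenceRecord], z_cut: float = 3.0) -> GCStats:
    """Per-sequence GC% with cohort z-scores and |z| > z_cut outlier flags."""
    rows = []
    excluded = []
    for r in records:
        try:
            rows.append({"specimen_id": r.specimen_id, "gc_pct": gc_percent(r.residues)})
        except ValueError:
            excluded.append(r.specimen_id)
    if len(rows) < 2:
        raise ValueError("need >= 2 sequences with unambiguous bases for z-scores")
    frame = pd.DataFrame(rows)
    mean = float(frame["gc_pct"].mean())
    sd = float(frame["gc_pct"].std(ddof=1))
    frame["gc_z"] = 0.0 if sd == 0 else (frame["gc_pct"] - mean) / sd
    frame["gc_outlier"] = frame["gc_z"].abs() > z_cut
    return GCStats(
        per_sequence=frame,
        gc_min=float(frame["gc_pct"].min()),
        gc_max=float(frame["gc_pct"].max()),
        mean=mean,
        sd=sd,
        excluded=excluded,
    )


def gc_histogram(values: Iterable[float], bin_width: float = 1.0) -> pd.DataFrame:
    vals = np.asarray(list(values), dtype=float)
    edges = np.arange(np.floor(vals.min()), np.ceil(vals.max()) + bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})


def gc_correlation(
    coi_records: Sequence[SequenceRecord],
    rrna_records: Sequence[SequenceRecord],
) -> Optional[float]:
    """Pearson r of (GC%_COI, GC%_16S) over specimens carrying both markers.

    Returns None (undefined) when either marker shows zero variance.
    """
    coi = {r.specimen_id: gc_percent(r.residues) for r in coi_records}
    rrna = {r.specimen_id: gc_percent(r.residues) for r in rrna_records}
    shared = sorted(set(coi) & set(rrna))
    if len(shared) < 3:
        raise ValueError("need >= 3 shared specimens")
    x = np.array([coi[s] for s in shared])
    y = np.array([rrna[s] for s in shared])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def _aa_distance(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x != y for x, y in zip(a[:n], b[:n])) / n


def _modal_translation(translations: Sequence[str]) -> str:
    """Position-wise modal amino acid over the cohort (ties: alphabetical)."""
    width = max(len(t) for t in translations)
    out = []
    for i in range(width):
        column = [t[i] for t in translations if i < len(t)]
        most = Counter(column).most_common()
        top = most[0][1]
        out.append(min(aa for aa, c in most if c == top))
    return "".join(out)


@dataclass
class PseudogeneReport:
    per_sequence: pd.DataFrame
    gc: dict[str, GCStats]
    pearson_r: Optional[float]

    def flagged(self) -> pd.DataFrame:
        return self.per_sequence[self.per_sequence["flags"] != ""]


def screen_pseudogenes(
    coi_records: Sequence[SequenceRecord],
    rrna_records: Sequence[SequenceRecord] = (),
    expected_length_mod3: Optional[int] = None,
    z_cut: float = 3.0,
    aa_divergence_cut: float = 0.20,
) -> PseudogeneReport:
    """Run the full screen over a COI cohort (plus 16S for the GC link).

    Per sequence: best reading frame and stop count, frameshift flag
    against the expected length mod 3 (default: the cohort's modal
    expected_length), GC z-score, and amino-acid divergence from the
    cohort's modal translation.  Flags: ``stop``, ``indel``, ``gc_outlier``,
    ``aa_divergent``.
    """
    if not coi_records:
        raise ValueError("no COI records to screen")
    if expected_length_mod3 is None:
        lens = [r.expected_length for r in coi_records if r.expected_length]
        expected_length_mod3 = (Counter(lens).most_common(1)[0][0] % 3) if lens else 1

    gc = {"COI": gc_stats(coi_records, z_cut)}
    if len(rrna_records) >= 2:
        gc["16S"] = gc_stats(list(rrna_records), z_cut)
    gc_by_id = dict(
        zip(gc["COI"].per_sequence["specimen_id"], zip(
            gc["COI"].per_sequence["gc_pct"],
            gc["COI"].per_sequence["gc_z"],
            gc["COI"].per_sequence["gc_outlier"],
        ))
    )

    translations = {}
    for r in coi_records:
        s = r.ungapped
        s = s[: len(s) - len(s) % 3]
        translations[r.specimen_id] = str(Seq(s).translate(table=INVERTEBRATE_MT_TABLE))
    modal = _modal_translation(list(translations.values()))

    rows = []
    for r in coi_records:
        frame, n_best = best_reading_frame(r.residues)
        n_stops = count_stops(r.residues, 1)
        shifted = detect_frameshift(r.residues, expected_length_mod3, aligned="-" in r.residues)
        gc_pct, gc_z, gc_out = gc_by_id.get(r.specimen_id, (np.nan, np.nan, False))
        aa_div = _aa_distance(translations[r.specimen_id], modal)
        flags = []
        if n_stops > 0:
            flags.append("stop")
        if shifted:
            flags.append("indel")
        if gc_out:
            flags.append("gc_outlier")
        if aa_div > aa_divergence_cut:
            flags.append("aa_divergent")
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "best_frame": frame,
                "n_stops_frame1": n_stops,
                "n_stops_best": n_best,
                "frameshift": shifted,
                "gc_pct": gc_pct,
                "gc_z": gc_z,
                "aa_divergence": aa_div,
                "flags": ",".join(flags),
            }
        )

    r_value = None
    if len(rrna_records) >= 3 and len(coi_records) >= 3:
        try:
            r_value = gc_correlation(coi_records, list(rrna_records))
        except ValueError:
            r_value = None
    return PseudogeneReport(pd.DataFrame(rows), gc, r_value)
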