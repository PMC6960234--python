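"""Length and Phred quality screening of barcode sequences.

A record passes only if its ungapped length is strictly more than 90% of
the expected amplicon length and strictly more than 85% of its bases reach
Phred Q30 (both fractions configurable).  Records without qualities (plain
archival FASTA) skip the Phred test but not the length test; alignment gaps
never count as bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .records import SequenceRecord


@dataclass(frozen=True)
class QCParams:
    """Quality-control thresholds.

    min_len_frac : ungapped length must exceed this fraction of the
        expected amplicon length (default 0.90).
    min_phred : per-base Phred score counted as "high quality" (default 30).
    min_frac_above : fraction of bases that must reach ``min_phred``
        (default 0.85); the comparison is strict.
    """

    min_len_frac: float = 0.90
    min_phred: int = 30
    min_frac_above: float = 0.85

    def __post_init__(self) -> None:
        if not 0 < self.min_len_frac <= 1:
            raise ValueError("min_len_frac must be in (0, 1]")
        if not 0 < self.min_frac_above <= 1:
            raise ValueError("min_frac_above must be in (0, 1]")
        if self.min_phred < 0:
            raise ValueError("min_phred must be >= 0")


def passes_qc(record: SequenceRecord, params: QCParams = QCParams()) -> tuple[bool, str]:
    """Apply the length and quality filters to one record.

    Returns ``(flag, reason)``; *reason* is ``"pass"`` or names the failed
    test.  Both thresholds are strict ("more than").
    """
    if record.expected_length is None:
        raise ValueError(f"{record.specimen_id}/{record.marker}: expected_length missing")
    n = len(record.ungapped)
    if not n > params.min_len_frac * record.expected_length:
        return False, (
            f"length {n} <= {params.min_len_frac:.0%} of expected {record.expected_length}"
        )
    if record.qualities is not None and n > 0:
        frac = sum(q >= params.min_phred for q in record.qualities) / n
        if not frac > params.min_frac_above:
            return False, (
                f"only {frac:.1%} of bases >= Q{params.min_phred} "
                f"(need > {params.min_frac_above:.0%})"
            )
    return True, "pass"


def filter_dataset(
    records: Iterable[SequenceRecord],
    params: QCParams = QCParams(),
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Partition records into (kept, dropped_with_reasons), order preserved."""
    kept: list[SequenceRecord] = []
    dropped: list[tuple[SequenceRecord, str]] = []
    for rec in records:
        ok, reason = passes_qc(rec, params)
        if ok:
            kept.append(rec)
        else:
            dropped.append((rec, reason))
    return kept, dropped


def write_drop_log(dropped: Sequence[tuple[SequenceRecord, str]], path: str | Path) -> None:
    rows = [
        {"specimen_id": r.specimen_id, "marker": r.marker, "reason": reason}
        for r, reason in dropped
    ]
    pd.DataFrame(rows, columns=["specimen_id", "marker", "reason"]).to_csv(
        path, sep="\t", index=False
    )
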