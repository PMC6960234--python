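"""Two-marker synthetic barcode datasets with known species truth.

The generator emulates the data regime of a decapod barcoding survey: for
each of ``n_species`` species it draws a pair of ancestral haplotypes (a
protein-coding COI-like marker under the invertebrate mitochondrial code,
and an indel-bearing 16S-like rRNA marker), then samples individuals around
each ancestor so that within-species pairwise p-distances concentrate near
``intra_div`` while between-species distances stay above ``inter_div`` — a
controllable barcode gap.  Optionally a fraction of COI records is replaced
by pseudogene copies carrying exactly the defects the pseudogene screen
detects (frameshifts, in-frame stops, shifted GC content), and per-base
Phred qualities are simulated for the quality filter.

Species ancestors are generated star-wise from a common random root (no
tree-shaped interspecific structure): each ancestor is the root mutated at
~0.9x (rRNA) or ~1.3x (coding, where third-position targeting raises the
collision rate) ``inter_div`` of its sites, accepted only if it stays at least
``1.25 x inter_div + 2 x intra_div`` from every previously accepted
ancestor, which (with per-individual mutation counts capped at
``intra_div x length``) guarantees every between-species pairwise distance
exceeds ``inter_div``.  The rRNA marker uses half the COI divergences,
mirroring the roughly 2:1 COI:16S divergence ratio of real decapod data,
and is emitted pre-aligned (deletions as ``-``) so downstream stages need
no aligner.

Randomness: one master seed; every record draws from a substream derived by
stable hashing of the specimen ID and purpose, so insertion order never
changes output and reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .records import SequenceRecord, write_fasta, write_fastq, write_metadata

BASES = np.array(list("ACGT"))
_STOPS_TABLE5 = {"TAA", "TAG"}  # TGA is Trp, AGA/AGG are Ser in table 5
INVERTEBRATE_TABLE = 5

# divergence of the rRNA-like marker relative to the coding marker
RRNA_DIVERGENCE_RATIO = 0.5

PSEUDOGENE_MODES = ("frameshift", "stop", "gc_shift")


@dataclass
class SimConfig:
    """Parameters of one synthetic two-marker dataset.

    ``intra_div`` and ``inter_div`` are per-site p-distances for the coding
    marker; the rRNA marker uses half of each.  ``pseudo_fraction`` of COI
    records are replaced by pseudogene copies (modes cycled).  ``mean_q``
    and ``bad_tail_fraction`` control the simulated Phred profile.
    """

    n_species: int = 20
    seqs_per_species: int = 5
    coi_length: int = 658
    rrna_length: int = 550
    intra_div: float = 0.01
    inter_div: float = 0.10
    pseudo_fraction: float = 0.0
    indel_rate_16S: float = 0.005
    gc_target: float = 0.38
    gc_species_sd: float = 0.02
    mean_q: float = 42.0
    bad_tail_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.intra_div < self.inter_div <= 0.75):
            raise ValueError(
                f"need 0 <= intra_div < inter_div <= 0.75 (no barcode gap to "
                f"recover otherwise); got intra={self.intra_div}, inter={self.inter_div}"
            )
        if not 0 <= self.pseudo_fraction <= 1:
            raise ValueError("pseudo_fraction must be in [0, 1]")
        if self.coi_length <= 0 or self.rrna_length <= 0:
            raise ValueError("sequence lengths must be positive")
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must be in (0, 1)")


def _substream(master_seed: int, *tokens) -> np.random.Generator:
    """Derive an order-independent RNG substream from the master seed."""
    digest = hashlib.blake2b(
        ("/".join([str(master_seed), *map(str, tokens)])).encode(), digest_size=8
    ).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big") % (2**31))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return BASES[rng.choice(4, size=length, p=p)]


def _fix_stops(seq: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Remove in-frame (frame 1) stop codons by redrawing the third base."""
    seq = seq.copy()
    for start in range(0, len(seq) - 2, 3):
        if "".join(seq[start : start + 3]) in _STOPS_TABLE5:
            seq[start + 2] = rng.choice(["C", "T"])  # TAC/TAT: Tyr
    return seq


def _silent_alternatives(codon: str, offset: int) -> list[str]:
    """Bases that can replace position *offset* of *codon* without changing
    the table-5 amino acid (and without creating a stop)."""
    aa = str(Seq(codon).translate(table=INVERTEBRATE_TABLE))
    out = []
    for alt in "ACGT":
        if alt == codon[offset]:
            continue
        new = codon[:offset] + alt + codon[offset + 1 :]
        if new not in _STOPS_TABLE5 and str(Seq(new).translate(table=INVERTEBRATE_TABLE)) == aa:
            out.append(alt)
    return out


def _mutate(
    seq: np.ndarray,
    n_mut: int,
    rng: np.random.Generator,
    coding: bool,
) -> np.ndarray:
    """Substitute ``n_mut`` distinct sites; coding mutations are biased to
    third codon positions and to synonymous changes (purifying selection on
    a functional mitochondrial gene), and never create an in-frame stop."""
    out = seq.copy()
    n_mut = min(n_mut, len(seq))
    if coding:
        weights = np.ones(len(seq))
        third = np.arange(2, len(seq) - len(seq) % 3, 3)
        weights[third] = 8.0
        weights /= weights.sum()
        positions = rng.choice(len(seq), size=n_mut, replace=False, p=weights)
    else:
        positions = rng.choice(len(seq), size=n_mut, replace=False)
    for pos in positions:
        if coding:
            start = (pos // 3) * 3
            if start + 3 > len(out):  # trailing partial codon: free site
                alternatives = [b for b in "ACGT" if b != out[pos]]
                out[pos] = alternatives[rng.integers(len(alternatives))]
                continue
            codon = "".join(out[start : start + 3])
            silent = _silent_alternatives(codon, pos - start)
            if silent:
                out[pos] = silent[rng.integers(len(silent))]
                continue
            alternatives = []
            for alt in "ACGT":
                if alt == out[pos]:
                    continue
                new = codon[: pos - start] + alt + codon[pos - start + 1 :]
                if new not in _STOPS_TABLE5:
                    alternatives.append(alt)
            if alternatives:
                out[pos] = alternatives[rng.integers(len(alternatives))]
        else:
            alternatives = [b for b in "ACGT" if b != out[pos]]
            out[pos] = alternatives[rng.integers(len(alternatives))]
    return out


def _p_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(a != b))


def _species_ancestors(
    cfg: SimConfig,
    marker: str,
    length: int,
    inter: float,
    intra: float,
) -> list[np.ndarray]:
    """Draw one ancestor per species around a common root, enforcing a
    minimum pairwise separation that survives individual-level mutation."""
    coding = marker == "COI"
    root_rng = _substream(cfg.seed, marker, "root")
    root = _random_seq(root_rng, length, cfg.gc_target)
    if coding:
        root = _fix_stops(root, root_rng)
    # coding ancestors need more raw substitutions because third-position
    # targeting concentrates them on fewer sites (higher collision rate)
    n_mut = int(round((1.3 if coding else 0.9) * inter * length))
    min_sep = 1.25 * inter + 2 * intra
    ancestors: list[np.ndarray] = []
    for sp in range(cfg.n_species):
        # per-species GC offset shared between markers: emulates the
        # taxon-level base-composition variation that makes COI and 16S
        # GC% positively correlated across specimens
        gc_delta = float(
            _substream(cfg.seed, "gcdrift", sp).normal(0.0, cfg.gc_species_sd)
        )
        for attempt in range(200):
            rng = _substream(cfg.seed, marker, "ancestor", sp, attempt)
            cand = _mutate(root, n_mut, rng, coding)
            if abs(gc_delta) > 0:
                if coding:
                    cand = _shift_gc(cand, gc_delta, rng)
                else:
                    cand = _shift_gc_noncoding(cand, gc_delta, rng)
            if all(_p_distance(cand, other) >= min_sep for other in ancestors):
                ancestors.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place species {sp} at separation >= {min_sep:.3f}; "
                "inter_div is too close to saturation for this length"
            )
    return ancestors


def inject_pseudogene(
    record: SequenceRecord,
    mode: str,
    seed: int,
    gc_delta: float = 0.12,
    keep_alignment: bool = False,
) -> SequenceRecord:
    """Turn a coding-marker record into a pseudogene copy.

    ``frameshift`` deletes one base at a random internal position (emitted
    as ``-`` when *keep_alignment*), ``stop`` rewrites one internal in-frame
    codon to TAA/TAG, and ``gc_shift`` flips silent third-codon positions to
    move GC content by *gc_delta* while preserving the amino-acid sequence.
    """
    if record.marker != "COI":
        raise ValueError(f"pseudogene injection requires a coding marker, got {record.marker}")
    if mode not in PSEUDOGENE_MODES:
        raise ValueError(f"mode must be one of {PSEUDOGENE_MODES}")
    rng = _substream(seed, "pseudo", record.specimen_id, mode)
    seq = np.array(list(record.ungapped))

    if mode == "frameshift":
        pos = int(rng.integers(1, len(seq) - 1))
        if keep_alignment:
            seq[pos] = "-"
            residues = "".join(seq)
        else:
            residues = "".join(np.delete(seq, pos))
    elif mode == "stop":
        n_codons = len(seq) // 3
        codon = int(rng.integers(1, n_codons))
        stop = rng.choice(sorted(_STOPS_TABLE5))
        seq[codon * 3 : codon * 3 + 3] = list(stop)
        residues = "".join(seq)
    else:  # gc_shift
        residues = "".join(_shift_gc(seq, gc_delta, rng))

    return record.copy(residues=residues, qualities=None)


def _shift_gc(seq: np.ndarray, delta: float, rng: np.random.Generator) -> np.ndarray:
    """Flip silent third-position bases to change GC by ~delta, keeping the
    frame-1 translation (table 5) unchanged."""
    seq = seq.copy()
    want_gc = delta > 0
    candidates = []
    for start in range(0, len(seq) - 2, 3):
        codon = "".join(seq[start : start + 3])
        third = codon[2]
        pool = "GC" if want_gc else "AT"
        if third in pool:
            continue
        aa = str(Seq(codon).translate(table=5))
        for alt in pool:
            new = codon[:2] + alt
            if new not in _STOPS_TABLE5 and str(Seq(new).translate(table=5)) == aa:
                candidates.append((start + 2, alt))
                break
    rng.shuffle(candidates)
    n_flip = int(round(abs(delta) * len(seq)))
    for pos, alt in candidates[:n_flip]:
        seq[pos] = alt
    return seq


def _shift_gc_noncoding(seq: np.ndarray, delta: float, rng: np.random.Generator) -> np.ndarray:
    """Flip random bases toward (delta > 0) or away from G/C in a
    non-coding sequence."""
    seq = seq.copy()
    source, dest = ("AT", "GC") if delta > 0 else ("GC", "AT")
    candidates = np.flatnonzero(np.isin(seq, list(source)))
    rng.shuffle(candidates)
    n_flip = min(int(round(abs(delta) * len(seq))), len(candidates))
    for pos in candidates[:n_flip]:
        seq[pos] = dest[rng.integers(2)]
    return seq


def simulate_qualities(
    record: SequenceRecord,
    mean_q: float,
    bad_tail_fraction: float,
    seed: int,
    tail_mean_q: float = 10.0,
    sd: float = 3.0,
) -> SequenceRecord:
    """Attach simulated per-base Phred scores (Sanger scale, clipped to [2, 60]).

    The trailing ``bad_tail_fraction`` of bases is drawn from a low-quality
    distribution centred on *tail_mean_q*, emulating 3' trace decay.
    """
    if not 2 <= mean_q <= 60:
        raise ValueError("mean_q must be in [2, 60]")
    rng = _substream(seed, "qual", record.specimen_id, record.marker)
    n = len(record.ungapped)
    if n == 0:
        return record.copy(qualities=[])
    n_tail = int(round(bad_tail_fraction * n))
    good = rng.normal(mean_q, sd, size=n - n_tail)
    tail = rng.normal(tail_mean_q, sd, size=n_tail)
    quals = np.clip(np.rint(np.concatenate([good, tail])), 2, 60).astype(int)
    return record.copy(qualities=quals.tolist())


def generate_dataset(cfg: SimConfig) -> tuple[dict[str, list[SequenceRecord]], pd.DataFrame]:
    """Generate the two linked marker sets plus a truth table.

    Returns ``(records, truth)`` where ``records`` maps marker name to a
    list of :class:`SequenceRecord` (one per specimen per marker, qualities
    attached) and ``truth`` is a DataFrame with columns ``specimen_id``,
    ``species_index``, ``is_pseudogene``.
    """
    cfg.validate()
    markers = {
        "COI": (cfg.coi_length, cfg.inter_div, cfg.intra_div),
        "16S": (
            cfg.rrna_length,
            cfg.inter_div * RRNA_DIVERGENCE_RATIO,
            cfg.intra_div * RRNA_DIVERGENCE_RATIO,
        ),
    }
    ancestors = {
        m: _species_ancestors(cfg, m, length, inter, intra)
        for m, (length, inter, intra) in markers.items()
    }

    records: dict[str, list[SequenceRecord]] = {"COI": [], "16S": []}
    truth_rows = []
    specimen_ids = []
    for sp in range(cfg.n_species):
        for rep in range(cfg.seqs_per_species):
            specimen_ids.append((f"SP{sp:03d}-{rep:02d}", sp))

    # deterministic pseudogene assignment: first k specimens in hash order
    n_pseudo = int(round(cfg.pseudo_fraction * len(specimen_ids)))
    hash_order = sorted(
        range(len(specimen_ids)),
        key=lambda i: hashlib.blake2b(
            f"{cfg.seed}/assign/{specimen_ids[i][0]}".encode(), digest_size=8
        ).digest(),
    )
    pseudo_idx = set(hash_order[:n_pseudo])

    for i, (sid, sp) in enumerate(specimen_ids):
        name = f"Simulocaris species{sp:03d}"
        for m, (length, inter, intra) in markers.items():
            rng = _substream(cfg.seed, m, "individual", sid)
            cap = max(1, int(np.ceil(intra * length)))
            n_mut = min(int(rng.binomial(length, intra / 2)), cap)
            seq = _mutate(ancestors[m][sp], n_mut, rng, coding=(m == "COI"))
            if m == "16S" and cfg.indel_rate_16S > 0:
                gaps = rng.random(length) < cfg.indel_rate_16S
                seq = seq.copy()
                seq[gaps] = "-"
            rec = SequenceRecord(
                specimen_id=sid,
                marker=m,
                residues="".join(seq),
                morphospecies=name,
                expected_length=length,
            )
            if m == "COI" and i in pseudo_idx:
                mode = PSEUDOGENE_MODES[len([j for j in pseudo_idx if j < i]) % 3]
                rec = inject_pseudogene(rec, mode, cfg.seed, keep_alignment=True)
            rec = simulate_qualities(rec, cfg.mean_q, cfg.bad_tail_fraction, cfg.seed)
            records[m].append(rec)
        truth_rows.append(
            {"specimen_id": sid, "species_index": sp, "is_pseudogene": i in pseudo_idx}
        )

    truth = pd.DataFrame(truth_rows)
    return records, truth


def write_dataset(
    records: dict[str, list[SequenceRecord]],
    truth: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write per-marker aligned FASTA + FASTQ, metadata TSV and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    all_records: list[SequenceRecord] = []
    for marker, recs in records.items():
        tag = marker.lower()
        paths[f"{tag}_fasta"] = outdir / f"{tag}.fasta"
        write_fasta(recs, paths[f"{tag}_fasta"])
        paths[f"{tag}_fastq"] = outdir / f"{tag}.fastq"
        write_fastq(recs, paths[f"{tag}_fastq"])
        all_records.extend(recs)
    paths["metadata"] = outdir / "metadata.tsv"
    write_metadata(all_records, paths["metadata"])
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
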