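"""End-to-end orchestration: QC -> contamination screen -> distances ->
trees -> per-marker ABGD -> consensus -> reference match -> pseudogene
screen -> OTU summary.

Every stage output is a pure function of (inputs, config, seed); the run
manifest records every parameter so a rerun is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import abgd as abgd_mod
from .abgd import ABGDParams, COI_PARAMS, RRNA_PARAMS, scan_priors
from .consensus import (
    ConsensusResult,
    ConsensusThresholds,
    build_consensus,
    concordance_report,
)
from .distances import DistanceMatrix, build_matrix, records_to_alignment
from .pseudogene import screen_pseudogenes
from .qc import QCParams, filter_dataset, write_drop_log
from .records import SequenceRecord, read_marker_file, read_metadata
from .refmatch import (
    MatchResult,
    NoveltyThresholds,
    match_query,
    match_table,
    read_reference_library,
)
from .trees import bootstrap_support, write_newick


@dataclass
class PipelineConfig:
    """Everything one run needs; marker-specific ABGD settings default to
    the standard decapod survey values (COI 0.001/0.1/1.125/10,
    16S 0.001/0.05/1.5/10)."""

    coi_path: Optional[str] = None
    rrna_path: Optional[str] = None
    coi_format: str = "fasta"
    rrna_format: str = "fasta"
    metadata_path: Optional[str] = None
    reference_path: Optional[str] = None
    outdir: str = "barcodekit_out"
    qc: QCParams = field(default_factory=QCParams)
    abgd_coi: ABGDParams = field(default_factory=lambda: COI_PARAMS)
    abgd_16s: ABGDParams = field(default_factory=lambda: RRNA_PARAMS)
    consensus: ConsensusThresholds = field(default_factory=ConsensusThresholds)
    novelty: NoveltyThresholds = field(default_factory=NoveltyThresholds)
    distance_model: str = "JC69"
    pseudo_z_cut: float = 3.0
    bootstrap_reps: int = 100
    seed: int = 0


@dataclass
class PipelineResult:
    kept: dict[str, list[SequenceRecord]]
    dropped: dict[str, list]
    contaminants: dict[str, list[str]]
    matrices: dict[str, DistanceMatrix]
    scans: dict[str, abgd_mod.ScanResult]
    consensus: ConsensusResult
    matches: dict[str, list[MatchResult]]
    pseudogene_report: object
    otu_summary: pd.DataFrame
    headline: dict


def _load_records(cfg: PipelineConfig) -> dict[str, list[SequenceRecord]]:
    meta = read_metadata(cfg.metadata_path)
    records = {}
    if cfg.coi_path:
        records["COI"] = read_marker_file(cfg.coi_path, cfg.coi_format, meta, "COI")
    if cfg.rrna_path:
        records["16S"] = read_marker_file(cfg.rrna_path, cfg.rrna_format, meta, "16S")
    if not records:
        raise ValueError("no marker files configured")
    return records


def _otu_novelty(
    group: frozenset[str], matches: Sequence[MatchResult], cutoff: float
) -> str:
    """An OTU is new for a marker iff none of its members exceeds the
    identity cutoff against the reference library."""
    member = [m for m in matches if m.query_id in group and m.classification != "contaminant"]
    if not member:
        return "n/a"
    return "known" if any(m.identity > cutoff for m in member) else "new"


def run_pipeline(
    cfg: PipelineConfig,
    records: Optional[dict[str, list[SequenceRecord]]] = None,
    write: bool = True,
) -> PipelineResult:
    """Run every stage; *records* may be passed directly (testing) instead
    of being read from the configured paths."""
    if records is None:
        records = _load_records(cfg)
    outdir = Path(cfg.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    refs = read_reference_library(cfg.reference_path) if cfg.reference_path else []
    nontargets = [r for r in refs if not r.target]

    kept: dict[str, list[SequenceRecord]] = {}
    dropped: dict[str, list] = {}
    contaminants: dict[str, list[str]] = {}
    matches: dict[str, list[MatchResult]] = {}
    matrices: dict[str, DistanceMatrix] = {}
    scans: dict[str, abgd_mod.ScanResult] = {}

    for marker, recs in records.items():
        keep, drop = filter_dataset(recs, cfg.qc)
        dropped[marker] = drop
        # contamination + reference matching on ungapped sequences
        marker_matches = []
        clean = []
        contaminated = []
        for r in keep:
            res = match_query(
                r.ungapped, r.specimen_id, marker, refs, cfg.novelty, r.morphospecies or ""
            )
            marker_matches.append(res)
            if res.classification == "contaminant":
                contaminated.append(r.specimen_id)
            else:
                clean.append(r)
        kept[marker] = clean
        contaminants[marker] = contaminated
        matches[marker] = marker_matches
        if len(clean) < 2:
            raise RuntimeError(f"stage distances [{marker}]: fewer than 2 sequences survive QC")
        aln = records_to_alignment(clean, marker)
        dm = build_matrix(aln, cfg.distance_model)
        matrices[marker] = dm
        params = cfg.abgd_coi if marker == "COI" else cfg.abgd_16s
        scans[marker] = scan_priors(dm, params, marker)
        if write:
            tag = marker.lower()
            write_drop_log(drop, outdir / f"{tag}_qc_drops.tsv")
            dm.to_phylip(outdir / f"{tag}_{cfg.distance_model.lower()}.phylip")
            if len(clean) >= 3:
                boot = bootstrap_support(aln, cfg.distance_model, cfg.bootstrap_reps, cfg.seed)
                write_newick(boot.tree, outdir / f"{tag}_bionj.nwk")
            scans[marker].selected.to_frame().to_csv(
                outdir / f"{tag}_otus.tsv", sep="\t", index=False
            )
            pd.concat([p.to_frame() for p in scans[marker].partitions]).to_csv(
                outdir / f"{tag}_otus_per_prior.tsv", sep="\t", index=False
            )
            scans[marker].histogram.to_csv(
                outdir / f"{tag}_distance_histogram.tsv", sep="\t", index=False
            )
            scans[marker].group_counts().to_csv(
                outdir / f"{tag}_group_counts.tsv", sep="\t", index=False
            )

    p_coi = scans.get("COI", None)
    p_16s = scans.get("16S", None)
    if p_coi and p_16s:
        consensus = build_consensus(
            p_coi.selected, p_16s.selected, matrices["COI"], matrices["16S"], cfg.consensus
        )
    else:
        only = (p_coi or p_16s).selected
        consensus = build_consensus(
            only, only, matrices.get("COI"), matrices.get("16S"), cfg.consensus
        )

    morpho = {
        r.specimen_id: (r.morphospecies or "?")
        for recs in records.values()
        for r in recs
    }
    concord = concordance_report(consensus.partition, morpho)

    coi_for_screen = kept.get("COI", [])
    pseudo = None
    if coi_for_screen:
        pseudo = screen_pseudogenes(
            coi_for_screen, kept.get("16S", []), z_cut=cfg.pseudo_z_cut
        )

    # Table-1-style OTU summary
    rows = []
    for gid, group in enumerate(consensus.partition.groups()):
        names = sorted({morpho.get(s, "?") for s in group})
        rows.append(
            {
                "otu_id": gid,
                "morphospecies": ";".join(names),
                "n_individuals": len(group),
                "coi_new": _otu_novelty(
                    group, matches.get("COI", []), cfg.novelty.coi_known_identity
                ),
                "rrna_new": _otu_novelty(
                    group, matches.get("16S", []), cfg.novelty.rrna_known_identity
                ),
            }
        )
    otu_summary = pd.DataFrame(
        rows, columns=["otu_id", "morphospecies", "n_individuals", "coi_new", "rrna_new"]
    )

    headline = summarize_counts(scans, consensus, concord, matches, otu_summary)

    if write:
        consensus.partition.to_frame().to_csv(outdir / "consensus_otus.tsv", sep="\t", index=False)
        consensus.conflicts.to_csv(outdir / "conflicts.tsv", sep="\t", index=False)
        for marker, mm in matches.items():
            match_table(mm).to_csv(outdir / f"{marker.lower()}_matches.tsv", sep="\t", index=False)
        if pseudo is not None:
            pseudo.per_sequence.to_csv(outdir / "pseudogene_report.tsv", sep="\t", index=False)
        otu_summary.to_csv(outdir / "otu_summary.tsv", sep="\t", index=False)
        manifest = {
            "config": _config_dict(cfg),
            "headline": headline,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(
        kept, dropped, contaminants, matrices, scans, consensus, matches,
        pseudo, otu_summary, headline,
    )


def _config_dict(cfg: PipelineConfig) -> dict:
    out = asdict(cfg)
    return out


def summarize_counts(
    scans: dict[str, abgd_mod.ScanResult],
    consensus: ConsensusResult,
    concord,
    matches: dict[str, list[MatchResult]],
    otu_summary: pd.DataFrame,
) -> dict:
    """Headline counts: per-marker and consensus OTUs, novelty, concordance."""
    out = {
        "consensus_otus": consensus.n_otus,
        "otus_single_morphospecies": concord.n_single_name,
        "otus_multiple_morphospecies": concord.n_multi_name,
        "morphospecies_split_across_otus": concord.n_split_morphospecies,
        "n_conflict_blocks": int(len(consensus.conflicts)),
    }
    for marker, scan in scans.items():
        out[f"{marker.lower()}_otus"] = scan.selected.n_groups
    for marker in scans:
        col = "coi_new" if marker == "COI" else "rrna_new"
        out[f"{marker.lower()}_new_otus"] = int((otu_summary[col] == "new").sum())
        out[f"{marker.lower()}_known_otus"] = int((otu_summary[col] == "known").sum())
        out[f"{marker.lower()}_contaminants"] = sum(
            1 for m in matches.get(marker, []) if m.classification == "contaminant"
        )
    return out
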