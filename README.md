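# barcodekit

A toolkit for multi-locus DNA barcoding surveys of the kind used to build
reference libraries for under-sampled invertebrate groups (the motivating
case is decapod crustaceans sequenced for the mitochondrial *COI* barcode
fragment, ~658 bp, and a 16S rRNA fragment). It takes per-marker sequence
files plus a specimen metadata table and produces, reproducibly and
without any network access:

1. **Quality screening** — records are kept only if their length exceeds
   90% of the expected amplicon length and more than 85% of bases reach
   Phred Q30 (both strict, both configurable).
2. **Distances and trees** — pairwise distances with pairwise deletion
   under the p, Jukes–Cantor (d = −¾ ln(1 − 4p/3)) or Kimura
   two-parameter (d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)) models; BIONJ
   neighbour-joining trees with Felsenstein bootstrap support.
3. **OTU delimitation** — Automatic Barcode Gap Discovery (ABGD): the
   ranked pairwise distances are scanned for the first gap that is wide
   relative to the local slope and lies beyond a prior maximal
   intraspecific divergence P; the sample is split by single linkage below
   the gap and the procedure recurses within groups. A geometric series
   of priors (P_min → P_max, default 0.001 → 0.1 with X = 1.125 for COI;
   0.001 → 0.05 with X = 1.5 for 16S; 10 steps) is scanned and the modal
   partition selected.
4. **Cross-marker consensus** — where COI and 16S partitions disagree, a
   split is accepted only if it diverges from everything else in the
   conflict block by ≥ 0.05 substitutions/site in COI or ≥ 0.03 in 16S;
   otherwise the option producing fewer OTUs wins.
5. **Reference matching** — a local-library stand-in for BLAST: global
   alignment with free terminal gaps; > 95% identity to a non-target
   reference flags contamination; COI OTUs ≤ 95% (16S ≤ 97%) identical to
   their best target hit are "new additions"; matched names are compared
   for concordance.
6. **Pseudogene (NUMT) screening** — in-frame stop codons under the
   invertebrate mitochondrial code (table 5: TGA = Trp, AGA/AGG = Ser),
   frame-disrupting indels, GC% outliers against the marker cohort, and
   the COI~16S GC correlation expected of genuine mitochondrial sequences.

A synthetic-data generator (`barcodekit.synthetic`) produces two-marker
datasets with known species truth, a controllable barcode gap, optional
pseudogene contamination and simulated base qualities, so the whole
pipeline is testable end-to-end.

## Worked example

```sh
barcodekit simulate --n-species 8 --seqs-per-species 4 --seed 42 --outdir data

cat > run.cfg <<CFG
coi_path = data/coi.fasta
rrna_path = data/16s.fasta
metadata_path = data/metadata.tsv
outdir = results
bootstrap_reps = 50
seed = 42
CFG

barcodekit all --config run.cfg
```

prints

```
16s_contaminants: 0
16s_known_otus: 0
16s_new_otus: 8
16s_otus: 8
coi_contaminants: 0
coi_known_otus: 0
coi_new_otus: 8
coi_otus: 8
consensus_otus: 8
morphospecies_split_across_otus: 0
n_conflict_blocks: 0
otus_multiple_morphospecies: 0
otus_single_morphospecies: 8
```

Each marker's ABGD scan delimits 8 OTUs matching the 8 simulated species;
the markers agree (no conflict blocks), every consensus OTU carries exactly
one morphospecies name, and — with no reference library configured — every
OTU is flagged as a new addition for both markers. `results/` holds the
per-marker distance matrices (PHYLIP), bootstrap-annotated Newick trees,
per-prior partition tables, distance histograms, the conflict log, the
Table-style OTU summary (`otu_summary.tsv`), and a manifest recording every
parameter:

```
otu_id  morphospecies           n_individuals  coi_new  rrna_new
0       Simulocaris species000  4              new      new
1       Simulocaris species001  4              new      new
...
```

The pseudogene screen runs standalone too:

```sh
barcodekit pseudo --coi data/coi.fasta --rrna data/16s.fasta \
    --metadata data/metadata.tsv --out pseudo.tsv
# 0 flagged of 32; GC range 40.27-48.18%; COI~16S GC r = 0.910 -> pseudo.tsv
```

No sequence in this clean simulation is flagged, and the per-species GC
drift shared between markers shows up as the expected positive COI~16S GC
correlation.

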