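# corecruit

Toolkit for comparative analysis of co-repressor recruitment motif evolution
in protostome transcription factors. It implements, as reusable tested
components, the pipeline stages needed to ask whether a repressor complex was
assembled by direct short-linear-motif recruitment or via an adaptor protein:

- **`seqio`** — FASTA/GFF3 readers, CDS translation, single-ORF frame
  inference for expression-construct inserts.
- **`motif_scan`** — strict degenerate-pattern matching (e.g.
  `P[ILMV]D[ILMV]S`), log-odds PSSM training/scanning with
  min-training-score threshold calibration (leave-one-out optional), and
  contact-residue checks for SBD-like motifs (four hydrophobic main-body
  positions plus a downstream tryptophan followed by a hydrophobic residue).
- **`exon_map`** — protein↔genomic codon mapping and splice-junction
  (codon index, phase) comparison across genes.
- **`synteny`** — gene-family adjacency detection and orientation
  classification (tandem/divergent/convergent) on annotated scaffolds.
- **`phylo_state`** — Fitch and Dollo parsimony for binary presence/absence
  characters on species trees (polytomies and missing data supported), and
  flagging of "hybrid" species carrying both recruitment mechanisms.
- **`constructs`** — verification of the packaged expression-construct
  inserts and primers: translation, substitution counting, stop-anchored
  coordinate mapping, primer replacement-peptide extraction.
- **`synthetic_data`** — seeded generators for proteomes with planted motif
  instances, multi-exon gene models with controlled junction placement and
  family adjacency, and binary characters evolved by explicit gain/loss
  events; every generator emits a ground-truth record.
- **`cli_report`** — pipeline orchestration from a YAML config and summary
  reports (motif table, junction report, synteny table, parsimony JSON,
  protein length statistics with extreme fold ratio).

Packaged plain-text fixtures (under `src/corecruit/data/`) transcribe the
published motif table (35 species), the codon-optimized construct inserts and
primers, and a small arthropod tree/character matrix.

## CLI

```sh
corecruit scan --proteins proteins.fa --out hits.tsv        # packaged motif config
corecruit junctions --gff genes.gff3 --fasta genome.fa --out junctions.tsv
corecruit synteny --gff genes.gff3 --family-a S-CAP --family-b MTA --out pairs.tsv
corecruit parsimony --tree tree.nwk --matrix characters.tsv --method fitch --out rec.json
corecruit constructs-verify --out report.json
corecruit simulate --seed 0 --out demo/
corecruit report --config pipeline.yaml --out reports/
```

`corecruit report` reads a YAML config naming the inputs; each stage runs
when its inputs are present:

```yaml
proteins: proteins.fa
motifs: motifs.yaml            # optional; defaults to the packaged config
genes: {gff: genes.gff3, fasta: genome.fa}
synteny: {family_a: S-CAP, family_b: MTA, max_intervening: 2}
tree: tree.nwk
characters: characters.tsv
```

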