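"""Seeded generators for synthetic proteomes, gene models and characters.

Every generator takes an explicit seed (via :class:`SynthConfig`) and emits a
ground-truth record alongside the data, so each pipeline stage can be tested
for exact recovery without external downloads.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .exon_map import gff_phase_from_break
from .motif_scan import Pssm
from .phylo_state import CharacterMatrix, _clade
from .seqio import AMINO_ACIDS, GeneModel, ProteinRecord, reverse_complement, write_scaffolds

_CODON_TABLE = unambiguous_dna_by_id[1]
_BACK_TABLE: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON_TABLE.forward_table.items()):
    _BACK_TABLE.setdefault(_aa, []).append(_codon)
_STOPS = sorted(_CODON_TABLE.stop_codons)

PLANT_MODES = ("consensus", "training", "decoy")


class SynthesisError(ValueError):
    pass


@dataclass(frozen=True)
class PlantSpec:
    """Plant one motif instance into one generated protein."""

    protein_id: str
    mode: str  # consensus | training | decoy
    position: int | None = None  # 1-based start; random when None

    def __post_init__(self) -> None:
        if self.mode not in PLANT_MODES:
            raise SynthesisError(f"unknown plant mode {self.mode!r}")


@dataclass(frozen=True)
class GeneSpec:
    """One gene to synthesize: protein to encode, placement and junctions.

    ``junctions`` are (codon_index, phase) marks in absolute protein
    coordinates; an intron is inserted after ``3*(codon_index-1)+phase``
    CDS nucleotides.
    """

    gene_id: str
    protein: str
    family: str | None = None
    strand: str = "+"
    scaffold: str = "scf1"
    junctions: tuple[tuple[int, int], ...] = ()
    intron_length: int = 60
    gap_before: int | None = None


@dataclass
class SynthConfig:
    seed: int = 0
    n_proteins: int = 10
    protein_length: int = 120
    background: Mapping[str, float] | None = None  # uniform when None
    pssm: Pssm | None = None
    plants: tuple[PlantSpec, ...] = ()
    decoy_margin: float = 2.0
    genes: tuple[GeneSpec, ...] = ()
    intergenic: int = 200


def _background_sampler(config: SynthConfig, rng: random.Random):
    if config.background is None:
        return lambda n: "".join(rng.choices(AMINO_ACIDS, k=n))
    residues = sorted(config.background)
    weights = [config.background[r] for r in residues]
    return lambda n: "".join(rng.choices(residues, weights=weights, k=n))


def _make_decoy(pssm: Pssm, margin: float, rng: random.Random) -> str:
    """Random walk from the consensus until the score drops below
    threshold - margin."""
    seq = list(pssm.consensus)
    for _ in range(10000):
        if pssm.score_window("".join(seq)) <= pssm.threshold - margin:
            return "".join(seq)
        pos = rng.randrange(len(seq))
        seq[pos] = rng.choice(AMINO_ACIDS)
    raise SynthesisError("failed to generate a sub-threshold decoy")


def gen_proteome(config: SynthConfig) -> tuple[list[ProteinRecord], dict]:
    """Background proteome with planted motif instances and a truth table."""
    rng = random.Random(config.seed)
    sample = _background_sampler(config, rng)
    plants_by_id = {p.protein_id: p for p in config.plants}
    if plants_by_id and config.pssm is None:
        raise SynthesisError("plants requested but no PSSM configured")
    records = []
    truth: dict = {}
    for i in range(config.n_proteins):
        pid = f"prot{i:03d}"
        seq = sample(config.protein_length)
        plant = plants_by_id.get(pid)
        if plant is not None:
            pssm = config.pssm
            if pssm.width > len(seq):
                raise SynthesisError("plant longer than sequence")
            if plant.mode == "consensus":
                instance = pssm.consensus
            elif plant.mode == "training":
                instance = rng.choice(pssm.training_instances)
            else:
                instance = _make_decoy(pssm, config.decoy_margin, rng)
            if plant.position is None:
                start = rng.randint(1, len(seq) - pssm.width + 1)
            else:
                start = plant.position
                if not 1 <= start <= len(seq) - pssm.width + 1:
                    raise SynthesisError("plant position outside sequence")
            seq = seq[:start - 1] + instance + seq[start - 1 + pssm.width:]
            truth[pid] = {
                "start": start,
                "end": start + pssm.width - 1,
                "instance": instance,
                "mode": plant.mode,
                "score": pssm.score_window(instance),
            }
        records.append(ProteinRecord(id=pid, sequence=seq, species=f"sp{i:03d}"))
    return records, truth


def _reverse_translate(protein: str, rng: random.Random) -> str:
    codons = [rng.choice(_BACK_TABLE[aa]) for aa in protein]
    codons.append(rng.choice(_STOPS))
    return "".join(codons)


def _random_intron(length: int, rng: random.Random) -> str:
    if length < 4:
        raise SynthesisError("intron length must be >= 4")
    core = "".join(rng.choices("ACGT", k=length - 4))
    return "GT" + core + "AG"


def gen_genes(
    config: SynthConfig,
) -> tuple[dict[str, str], list[GeneModel], dict]:
    """Scaffolds plus gene models encoding the configured proteins exactly.

    Introns are inserted at the requested (codon_index, phase) marks; gene
    order, strand and spacing follow the spec list.  The truth record carries
    each gene's protein, junction marks and genomic span.
    """
    rng = random.Random(config.seed)
    scaffolds: dict[str, list[str]] = {}
    lengths: dict[str, int] = {}
    models: list[GeneModel] = []
    truth: dict = {"genes": {}}

    for spec in config.genes:
        cds = _reverse_translate(spec.protein, rng)
        breaks = []
        for ci, phase in spec.junctions:
            b = 3 * (ci - 1) + phase
            if not 0 < b < len(cds):
                raise SynthesisError(
                    f"{spec.gene_id}: junction ({ci},{phase}) outside CDS"
                )
            breaks.append(b)
        if breaks != sorted(set(breaks)):
            raise SynthesisError(f"{spec.gene_id}: junctions must be increasing")
        pieces = []
        prev = 0
        for b in breaks:
            pieces.append(cds[prev:b])
            prev = b
        pieces.append(cds[prev:])

        segment_parts = []
        exon_offsets = []  # (start, end) 1-based within forward segment
        pos = 1
        for i, piece in enumerate(pieces):
            exon_offsets.append((pos, pos + len(piece) - 1))
            segment_parts.append(piece)
            pos += len(piece)
            if i < len(pieces) - 1:
                intron = _random_intron(spec.intron_length, rng)
                segment_parts.append(intron)
                pos += len(intron)
        segment = "".join(segment_parts)

        if spec.strand == "-":
            L = len(segment)
            segment = reverse_complement(segment)
            exon_offsets = [(L - e + 1, L - s + 1) for s, e in exon_offsets]

        parts = scaffolds.setdefault(spec.scaffold, [])
        offset = lengths.get(spec.scaffold, 0)
        gap = spec.gap_before if spec.gap_before is not None else config.intergenic
        parts.append("".join(rng.choices("ACGT", k=gap)))
        offset += gap
        exons = tuple((offset + s, offset + e) for s, e in exon_offsets)
        parts.append(segment)
        lengths[spec.scaffold] = offset + len(segment)

        model = GeneModel(
            gene_id=spec.gene_id,
            scaffold=spec.scaffold,
            strand=spec.strand,
            exons=exons,
            protein_id=f"{spec.gene_id}.p1",
            family=spec.family,
        )
        models.append(model)
        truth["genes"][spec.gene_id] = {
            "protein": spec.protein,
            "junctions": [list(j) for j in spec.junctions],
            "span": list(model.span),
            "strand": spec.strand,
            "scaffold": spec.scaffold,
            "family": spec.family,
        }

    for name in scaffolds:
        tail = "".join(rng.choices("ACGT", k=config.intergenic))
        scaffolds[name].append(tail)
    return {k: "".join(v) for k, v in scaffolds.items()}, models, truth


def write_gff(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/CDS features (GFF3) for generated gene models."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start, end = m.span
            attrs = f"ID={m.gene_id}"
            if m.family:
                attrs += f";family={m.family}"
            fh.write(
                f"{m.scaffold}\tcorecruit\tgene\t{start}\t{end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            mrna = f"{m.gene_id}.t1"
            fh.write(
                f"{m.scaffold}\tcorecruit\tmRNA\t{start}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={mrna};Parent={m.gene_id}\n"
            )
            cum = 0
            cds_lines = []
            for s, e in m.exons:  # transcription order for correct phase
                phase = gff_phase_from_break(cum) if cum else 0
                cds_lines.append((s, e, phase))
                cum += e - s + 1
            for s, e, phase in sorted(cds_lines):
                attrs = f"ID={m.gene_id}.cds;Parent={mrna}"
                if m.protein_id:
                    attrs += f";protein_id={m.protein_id}"
                fh.write(
                    f"{m.scaffold}\tcorecruit\tCDS\t{s}\t{e}\t.\t{m.strand}\t{phase}\t{attrs}\n"
                )


def write_dataset(
    out_dir: str | Path,
    scaffolds: Mapping[str, str],
    models: Sequence[GeneModel],
    truth: dict,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_scaffolds(scaffolds, out / "genome.fa")
    write_gff(models, out / "genes.gff3")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def gen_characters(
    tree: dendropy.Tree,
    events: Sequence[tuple[frozenset[str] | set[str] | str, str]],
    character: str = "character",
) -> tuple[CharacterMatrix, dict]:
    """Leaf states implied by propagating gain/loss events root-to-tips.

    Each event names a branch by the leaf set below it (a single leaf label
    is accepted for terminal branches).  A loss on a path that is still in
    state 0, or a gain on a path already in state 1, is inconsistent.
    """
    by_clade: dict[frozenset[str], str] = {}
    for clade, kind in events:
        if isinstance(clade, str):
            clade = frozenset({clade})
        clade = frozenset(clade)
        if kind not in ("gain", "loss"):
            raise SynthesisError(f"unknown event kind {kind!r}")
        by_clade[clade] = kind

    clades = {_clade(node) for node in tree.preorder_node_iter()}
    unknown = set(by_clade) - clades
    if unknown:
        raise SynthesisError(f"events reference clades not on the tree: {unknown}")

    states: dict[str, str] = {}

    def walk(node: dendropy.Node, state: int) -> None:
        kind = by_clade.get(_clade(node))
        if kind == "gain":
            if state == 1:
                raise SynthesisError("gain on a path already in state 1")
            state = 1
        elif kind == "loss":
            if state == 0:
                raise SynthesisError("loss before gain on a path")
            state = 0
        if node.is_leaf():
            states[node.taxon.label] = str(state)
        for child in node.child_nodes():
            walk(child, state)

    walk(tree.seed_node, 0)
    species = tuple(sorted(states))
    matrix = CharacterMatrix(
        species=species,
        characters=(character,),
        states={(sp, character): states[sp] for sp in species},
    )
    truth = {
        "events": sorted(
            (sorted(clade), kind) for clade, kind in by_clade.items()
        )
    }
    return matrix, truth
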