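"""Sequence I/O primitives: FASTA/GFF3 readers, CDS translation, frame detection.

Coordinate conventions
----------------------
Genomic coordinates are 1-based inclusive (GFF3); protein coordinates are
1-based.  ``GeneModel.exons`` are CDS intervals listed in *transcription*
order, i.e. ascending genomic coordinate on the ``+`` strand and descending
on the ``-`` strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class SequenceError(ValueError):
    """Malformed sequence content (bad residues, bad frame, internal stop)."""


class OrfError(ValueError):
    """No (or no unique) qualifying reading frame in an insert."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with a species tag.

    ``region_boundary`` optionally marks the last residue of the N-terminal
    scan window (1-based, inclusive); motif hits beyond it are reported but
    flagged as out-of-region.
    """

    id: str
    sequence: str
    species: str = ""
    region_boundary: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"{self.id}: empty sequence")
        for i, ch in enumerate(self.sequence):
            if ch not in _AA_SET:
                raise SequenceError(
                    f"{self.id}: invalid residue {ch!r} at position {i + 1}"
                )
        if self.region_boundary is not None and not (
            1 <= self.region_boundary <= len(self.sequence)
        ):
            raise SequenceError(
                f"{self.id}: region_boundary {self.region_boundary} outside "
                f"[1, {len(self.sequence)}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """Ordered CDS exon intervals of one gene on one scaffold.

    Exons are (start, end) 1-based inclusive pairs in transcription order.
    """

    gene_id: str
    scaffold: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    protein_id: str | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")
        for s, e in self.exons:
            if s > e or s < 1:
                raise ValueError(f"{self.gene_id}: bad exon interval ({s}, {e})")
        by_start = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(by_start, by_start[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        # transcription order: ascending on +, descending on -
        keys = [s for s, _ in self.exons]
        expect = sorted(keys, reverse=(self.strand == "-"))
        if keys != expect:
            raise ValueError(
                f"{self.gene_id}: exons not in transcription order for "
                f"strand {self.strand}"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def frame_consistent(self) -> bool:
        """True when the total CDS length is a whole number of codons."""
        return self.cds_length % 3 == 0

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)


def _parse_description(description: str) -> tuple[str, str, int | None]:
    tokens = description.split()
    ident = tokens[0] if tokens else ""
    species = ""
    boundary: int | None = None
    for tok in tokens[1:]:
        if tok.startswith("species="):
            species = tok[len("species="):]
        elif tok.startswith("region_boundary="):
            boundary = int(tok[len("region_boundary="):])
    return ident, species, boundary


def read_fasta(path: str | Path, uppercase: bool = True) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    The first whitespace-delimited token of each description line becomes the
    id; ``species=`` and ``region_boundary=`` key=value tokens are recognised.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ident, species, boundary = _parse_description(rec.description)
        seq = str(rec.seq)
        if uppercase:
            seq = seq.upper()
        records.append(
            ProteinRecord(
                id=ident, sequence=seq, species=species, region_boundary=boundary
            )
        )
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.species:
                header += f" species={rec.species}"
            if rec.region_boundary is not None:
                header += f" region_boundary={rec.region_boundary}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_scaffolds(path: str | Path) -> dict[str, str]:
    """Read scaffold nucleotide sequences keyed by the first header token."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_scaffolds(scaffolds: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in scaffolds:
            fh.write(f">{name}\n")
            seq = scaffolds[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_gff_genes(
    path: str | Path,
    fasta: str | Path | None = None,
    family_key: str = "family",
) -> list[GeneModel]:
    """Read gene models (grouped CDS features) from a GFF3 file.

    CDS features are grouped per gene via their Parent chain and returned in
    transcription order.  The optional ``fasta`` is used only to verify that
    every referenced scaffold exists.  A stored CDS phase inconsistent with
    the cumulative CDS length triggers a warning and is recomputed.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    scaffolds = read_scaffolds(fasta) if fasta is not None else None
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        cds = list(db.children(gene, featuretype="CDS", order_by="start"))
        if not cds:
            continue
        if scaffolds is not None and gene.seqid not in scaffolds:
            raise SequenceError(
                f"{gene.id}: scaffold {gene.seqid!r} not present in FASTA"
            )
        strand = gene.strand
        if strand == "-":
            cds = list(reversed(cds))
        exons = tuple((c.start, c.end) for c in cds)
        # verify the stored phase column against the cumulative CDS length
        cum = 0
        for c in cds:
            expected = (3 - cum % 3) % 3
            stored = c.frame
            if stored not in (".", None, "") and int(stored) != expected:
                warnings.warn(
                    f"{gene.id}: CDS phase {stored} inconsistent with "
                    f"cumulative length (expected {expected}); recomputed",
                    stacklevel=2,
                )
            cum += c.end - c.start + 1
        protein_id = None
        for c in cds:
            if "protein_id" in c.attributes:
                protein_id = c.attributes["protein_id"][0]
                break
        if protein_id is None:
            mrnas = list(db.children(gene, featuretype="mRNA"))
            if mrnas:
                protein_id = mrnas[0].id
        family = gene.attributes[family_key][0] if family_key in gene.attributes else None
        models.append(
            GeneModel(
                gene_id=gene.id,
                scaffold=gene.seqid,
                strand=strand,
                exons=exons,
                protein_id=protein_id,
                family=family,
            )
        )
    return models


def spliced_cds(model: GeneModel, scaffolds: Mapping[str, str]) -> str:
    """Concatenate exon sequences in transcription order (strand-corrected)."""
    scaffold = scaffolds[model.scaffold]
    parts = []
    for s, e in model.exons:
        chunk = scaffold[s - 1:e]
        if model.strand == "-":
            chunk = reverse_complement(chunk)
        parts.append(chunk)
    return "".join(parts).upper()


def translate(cds: str) -> str:
    """Translate a CDS (standard code); strips one trailing stop.

    Raises :class:`SequenceError` on length not divisible by 3 or an internal
    stop codon (the 1-based codon index is named in the message).
    """
    if len(cds) < 3:
        raise SequenceError("CDS shorter than one codon")
    if len(cds) % 3:
        raise SequenceError(f"CDS length {len(cds)} not divisible by 3")
    peptide = str(Seq(cds).translate())
    if peptide.endswith("*"):
        peptide = peptide[:-1]
    star = peptide.find("*")
    if star != -1:
        raise SequenceError(f"internal stop codon at codon {star + 1}")
    return peptide


def translate_cds(model: GeneModel, scaffolds: Mapping[str, str]) -> str:
    """Translate a gene model against its scaffold sequences."""
    return translate(spliced_cds(model, scaffolds))


def find_single_orf(insert: str) -> tuple[int, str]:
    """Infer the reading frame of a forward-strand insert from its stop codon.

    A frame qualifies when its complete codons contain exactly one stop.  The
    unique qualifying frame offset (0/1/2) and the peptide encoded upstream of
    that stop are returned.  Zero qualifying frames, or more than one, raise
    :class:`OrfError` (the ambiguous case reports all candidates).
    """
    insert = insert.upper()
    candidates: list[tuple[int, str]] = []
    for frame in range(3):
        ncod = (len(insert) - frame) // 3
        codons = [insert[frame + 3 * i: frame + 3 * i + 3] for i in range(ncod)]
        stops = [i for i, c in enumerate(codons) if c in STOP_CODONS]
        if len(stops) == 1:
            peptide = str(Seq("".join(codons[: stops[0]])).translate())
            candidates.append((frame, peptide))
    if not candidates:
        raise OrfError("no frame with exactly one stop codon")
    if len(candidates) > 1:
        frames = ", ".join(str(f) for f, _ in candidates)
        raise OrfError(f"ambiguous insert: frames {frames} all qualify")
    return candidates[0]
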