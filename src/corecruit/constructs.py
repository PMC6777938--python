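"""Verification of printed expression constructs and primers.

Inserts are translated via single-ORF frame inference; peptide coordinates
are anchored at the C-terminal stop codon against the construct's stated
full-protein residue range (the vector-derived N-terminal linker length is
not printed, so the stop is the only reliable anchor).  Residues upstream of
the stated span are flagged as linker.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq

from . import resources
from .seqio import STOP_CODONS, find_single_orf


class ConstructError(ValueError):
    pass


@dataclass(frozen=True)
class ConstructRecord:
    """One printed insert with optional stated residue range."""

    name: str
    insert_dna: str
    stated_range: tuple[int, int] | None = None
    role: str = "wild_type"

    def __post_init__(self) -> None:
        if self.stated_range is not None:
            first, last = self.stated_range
            if last < first:
                raise ConstructError(f"{self.name}: bad stated range {self.stated_range}")
        if self.role not in ("wild_type", "mutant"):
            raise ConstructError(f"{self.name}: unknown role {self.role!r}")


@dataclass(frozen=True)
class AnchoredResidue:
    peptide_index: int  # 1-based position within the translated peptide
    coordinate: int  # full-protein coordinate
    is_linker: bool


def construct_peptide(construct: ConstructRecord) -> str:
    """Translated peptide upstream of the insert's unique terminal stop.

    Vector-linker residues are retained; downstream operations anchor on the
    stop codon rather than the N terminus.
    """
    _, peptide = find_single_orf(construct.insert_dna)
    return peptide


def substitution_count(
    wt: ConstructRecord, mut: ConstructRecord
) -> tuple[int, list[tuple[int, str, str]]]:
    """Protein-level Hamming distance between a WT/mutant pair.

    Returns the count and a position-sorted list of (peptide position,
    wild-type residue, mutant residue).  Codon-level silent differences are
    ignored by construction.  Unequal peptide lengths signal a frame or
    transcription error and raise.
    """
    pep_wt = construct_peptide(wt)
    pep_mut = construct_peptide(mut)
    if len(pep_wt) != len(pep_mut):
        raise ConstructError(
            f"peptide length mismatch: {wt.name} ({len(pep_wt)}) vs "
            f"{mut.name} ({len(pep_mut)})"
        )
    subs = [
        (i + 1, a, b) for i, (a, b) in enumerate(zip(pep_wt, pep_mut)) if a != b
    ]
    return len(subs), subs


def anchor_coordinates(
    construct: ConstructRecord, peptide: str
) -> list[AnchoredResidue]:
    """Map peptide positions onto full-protein coordinates via the stop anchor.

    The final pre-stop residue is assigned the last coordinate of the stated
    range; coordinates decrease toward the N terminus.  Positions mapping
    below the first stated coordinate are linker residues.
    """
    if construct.stated_range is None:
        raise ConstructError(f"{construct.name}: no stated residue range")
    first, last = construct.stated_range
    span = last - first + 1
    if len(peptide) < span:
        raise ConstructError(
            f"{construct.name}: peptide length {len(peptide)} shorter than "
            f"stated span {span}"
        )
    out = []
    for i in range(1, len(peptide) + 1):
        coord = last - (len(peptide) - i)
        out.append(
            AnchoredResidue(peptide_index=i, coordinate=coord, is_linker=coord < first)
        )
    return out


def primer_replacement_peptide(
    reverse_primer: str, template_anchor: str = "CATGGGGCC"
) -> str:
    """Residues a reverse primer inserts between template and stop codon.

    ``template_anchor`` is the in-frame template-matching segment (as printed,
    primer orientation) immediately downstream of the replaced codons.  The
    primer is reverse-complemented and the codons between the anchor and the
    first stop are translated; an empty string denotes pure truncation.
    """
    rc = str(Seq(reverse_primer).reverse_complement()).upper()
    anchor_rc = str(Seq(template_anchor).reverse_complement()).upper()
    idx = rc.find(anchor_rc)
    if idx == -1:
        raise ConstructError(
            f"template anchor {template_anchor!r} not found on primer"
        )
    tail = rc[idx + len(anchor_rc):]
    residues = []
    for j in range(0, len(tail) - 2, 3):
        codon = tail[j:j + 3]
        if codon in STOP_CODONS:
            return "".join(residues)
        residues.append(str(Seq(codon).translate()))
    raise ConstructError("no in-frame stop codon on the primer reverse complement")


def _parse_header(description: str) -> dict[str, str]:
    tokens = description.split()
    fields = {"name": tokens[0]}
    for tok in tokens[1:]:
        if "=" in tok:
            k, v = tok.split("=", 1)
            fields[k] = v
    return fields


def load_constructs(path: str | Path) -> dict[str, ConstructRecord]:
    """Load construct inserts from FASTA (header keys: role, range, pair)."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = _parse_header(rec.description)
        stated = None
        if "range" in fields:
            first, last = fields["range"].split("-")
            stated = (int(first), int(last))
        out[fields["name"]] = ConstructRecord(
            name=fields["name"],
            insert_dna=str(rec.seq),
            stated_range=stated,
            role=fields.get("role", "wild_type"),
        )
    return out


def load_primers(path: str | Path) -> dict[str, str]:
    """Load primers from FASTA with case preserved (case marks the printed
    template boundary)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def packaged_constructs() -> dict[str, ConstructRecord]:
    return load_constructs(resources.constructs_path())


def packaged_primers() -> dict[str, str]:
    return load_primers(resources.primers_path())


def construct_pairs(
    constructs: Mapping[str, ConstructRecord] | None = None,
) -> list[tuple[ConstructRecord, ConstructRecord]]:
    """(wild_type, mutant) pairs grouped by the ``pair`` header tag."""
    constructs = constructs if constructs is not None else packaged_constructs()
    groups: dict[str, dict[str, ConstructRecord]] = {}
    for rec in SeqIO.parse(str(resources.constructs_path()), "fasta"):
        fields = _parse_header(rec.description)
        if fields["name"] in constructs and "pair" in fields:
            groups.setdefault(fields["pair"], {})[
                constructs[fields["name"]].role
            ] = constructs[fields["name"]]
    return [
        (g["wild_type"], g["mutant"])
        for g in groups.values()
        if "wild_type" in g and "mutant" in g
    ]


def verification_report() -> dict:
    """Machine-readable verification of the packaged constructs and primers."""
    constructs = packaged_constructs()
    report: dict = {"constructs": {}, "pairs": {}, "primers": {}}
    for name, rec in sorted(constructs.items()):
        frame, peptide = find_single_orf(rec.insert_dna)
        entry = {
            "frame": frame,
            "peptide_length": len(peptide),
            "role": rec.role,
        }
        if rec.stated_range:
            entry["stated_range"] = list(rec.stated_range)
            anchored = anchor_coordinates(rec, peptide)
            entry["linker_residues"] = sum(a.is_linker for a in anchored)
        report["constructs"][name] = entry
    for wt, mut in construct_pairs(constructs):
        count, subs = substitution_count(wt, mut)
        pair_entry = {
            "substitutions": count,
            "all_to_alanine": all(b == "A" for _, _, b in subs),
            "positions": [p for p, _, _ in subs],
        }
        if wt.stated_range:
            anchored = {
                a.peptide_index: a.coordinate
                for a in anchor_coordinates(wt, construct_peptide(wt))
            }
            pair_entry["coordinates"] = [anchored[p] for p, _, _ in subs]
        report["pairs"][wt.name.rsplit("_", 1)[0]] = pair_entry
    for name, primer in sorted(packaged_primers().items()):
        if name.endswith("-r") and name.startswith(("mbeta", "HISmbetatrunc")):
            report["primers"][name] = {
                "replacement_peptide": primer_replacement_peptide(primer)
            }
    return report


def write_verification_report(path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(verification_report(), fh, indent=2, sort_keys=True)
        fh.write("\n")
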