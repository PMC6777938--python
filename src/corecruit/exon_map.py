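"""Protein-to-genome coordinate mapping and splice-junction comparison.

A :class:`JunctionMark` records where an intron interrupts a codon window:
``codon_index`` is the 1-based codon the junction interrupts (or, at phase 0,
immediately precedes) and ``phase`` is the number of nucleotides of that
codon on the upstream exon.  Note this "phase" is a property of the junction
within the protein, not the GFF3 CDS phase column (which encodes frame
restoration); :func:`gff_phase_from_break` converts explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import GeneModel


@dataclass(frozen=True, order=True)
class JunctionMark:
    codon_index: int  # 1-based, window-relative when produced by junctions_in_window
    phase: int  # upstream-exon nucleotides of the interrupted codon, in {0,1,2}

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0/1/2, got {self.phase}")
        if self.codon_index < 1:
            raise ValueError("codon_index must be >= 1")


def cds_genomic_positions(model: GeneModel) -> list[int]:
    """Genomic position of every CDS nucleotide, in transcription order."""
    positions: list[int] = []
    for s, e in model.exons:
        if model.strand == "+":
            positions.extend(range(s, e + 1))
        else:
            positions.extend(range(e, s - 1, -1))
    return positions


def protein_to_genomic(
    model: GeneModel, residue_index: int
) -> tuple[tuple[int, int], ...]:
    """Genomic interval(s) of one codon: 1-2 intervals totaling 3 bases."""
    n_codons = model.cds_length // 3
    if not 1 <= residue_index <= n_codons:
        raise IndexError(
            f"residue {residue_index} outside [1, {n_codons}] for {model.gene_id}"
        )
    positions = cds_genomic_positions(model)[3 * (residue_index - 1): 3 * residue_index]
    step = 1 if model.strand == "+" else -1
    intervals: list[tuple[int, int]] = []
    run = [positions[0]]
    for p in positions[1:]:
        if p == run[-1] + step:
            run.append(p)
        else:
            intervals.append((min(run), max(run)))
            run = [p]
    intervals.append((min(run), max(run)))
    return tuple(intervals)


def genomic_to_protein(model: GeneModel, position: int) -> int:
    """Residue index whose codon covers a genomic CDS position."""
    positions = cds_genomic_positions(model)
    try:
        idx = positions.index(position)
    except ValueError:
        raise IndexError(
            f"genomic position {position} is not in the CDS of {model.gene_id}"
        ) from None
    return idx // 3 + 1


def junction_breaks(model: GeneModel) -> list[int]:
    """Cumulative CDS nucleotide counts at each internal exon boundary."""
    breaks = []
    cum = 0
    for s, e in model.exons[:-1]:
        cum += e - s + 1
        breaks.append(cum)
    return breaks


def junction_marks(model: GeneModel) -> list[JunctionMark]:
    """All intron junctions of a gene in absolute protein coordinates."""
    marks = []
    for b in junction_breaks(model):
        marks.append(JunctionMark(codon_index=b // 3 + 1, phase=b % 3))
    return marks


def gff_phase_from_break(cumulative_upstream_nt: int) -> int:
    """GFF3 phase column of the exon following a junction."""
    return (3 - cumulative_upstream_nt % 3) % 3


def junctions_in_window(
    model: GeneModel, start_residue: int, end_residue: int
) -> list[JunctionMark]:
    """Junctions falling within a protein window, in window-relative coordinates.

    A phase-0 junction immediately after the window's last codon is reported
    with ``codon_index = width + 1``.
    """
    if start_residue < 1 or end_residue < start_residue:
        raise IndexError("bad window")
    out = []
    for mark in junction_marks(model):
        ci, phase = mark.codon_index, mark.phase
        upper = end_residue + 1 if phase == 0 else end_residue
        if start_residue <= ci <= upper:
            out.append(JunctionMark(codon_index=ci - start_residue + 1, phase=phase))
    return out


def compare_junctions(
    a: list[JunctionMark], b: list[JunctionMark], alignment_offset: int = 0
) -> str:
    """Compare two junction lists under a gap-free alignment offset.

    Returns ``"same"`` when the offset lists agree exactly in (index, phase),
    ``"incomparable"`` when either list is empty (single-exon encoding), and
    ``"different"`` otherwise.
    """
    if not a or not b:
        return "incomparable"
    shifted = sorted(
        JunctionMark(m.codon_index + alignment_offset, m.phase) for m in a
    )
    return "same" if shifted == sorted(b) else "different"
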