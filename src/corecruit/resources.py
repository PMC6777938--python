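"""Packaged reference fixtures and default motif configuration.

The shipped data files transcribe sequences printed in the source
publication: the aligned co-repressor recruitment motif table for 35
protostome species, the codon-optimized expression-construct inserts and
primers, plus a small arthropod species-tree/character-matrix fixture used
by the reporting examples.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources as _importlib_resources
from pathlib import Path

from .motif_scan import ContactSpec, MotifPattern, Pssm, build_pssm, compile_pattern

#: canonical CtBP recruitment pattern (phi = I/L/M/V)
CTBP_STRICT_PATTERN = "P[ILMV]D[ILMV]S"

#: SBD-like contact requirements: four hydrophobic main-body positions of the
#: 15-residue motif, plus the downstream tryptophan rule
SBD_CONTACTS = ContactSpec(
    name="SBD_contacts",
    contacts=(
        (3, frozenset("ILMV")),
        (5, frozenset("FILMV")),
        (13, frozenset("ILMV")),
        (15, frozenset("ILMV")),
    ),
    w_max_distance=20,
)

_CONTEXT_RE = re.compile(r"^([A-Z]*)\[([A-Z]+)\]([A-Z]*)$")


@dataclass(frozen=True)
class MotifTableRow:
    species: str
    ctbp_context: str  # full context string, brackets removed
    ctbp_motif: str
    ctbp_start: int  # 1-based start of the motif within the context
    gro_context: str | None = None
    gro_motif: str | None = None
    gro_start: int | None = None


def _data_path(name: str) -> Path:
    return Path(str(_importlib_resources.files("corecruit").joinpath("data", name)))


def _parse_context(text: str) -> tuple[str, str, int]:
    m = _CONTEXT_RE.match(text)
    if not m:
        raise ValueError(f"malformed motif context {text!r}")
    pre, motif, post = m.groups()
    return pre + motif + post, motif, len(pre) + 1


def motif_table_rows() -> list[MotifTableRow]:
    """The 35-species recruitment-motif table (bracketed spans = instances)."""
    rows = []
    lines = _data_path("protostome_suh_motifs.tsv").read_text().splitlines()
    for line in lines[1:]:
        parts = line.rstrip("\n").split("\t")
        species, ctbp = parts[0], parts[1]
        gro = parts[2] if len(parts) > 2 and parts[2] else None
        c_full, c_motif, c_start = _parse_context(ctbp)
        if gro:
            g_full, g_motif, g_start = _parse_context(gro)
            rows.append(
                MotifTableRow(species, c_full, c_motif, c_start, g_full, g_motif, g_start)
            )
        else:
            rows.append(MotifTableRow(species, c_full, c_motif, c_start))
    return rows


def ctbp_instances() -> list[str]:
    """All 35 annotated CtBP 5-mers (strict and near-canonical)."""
    return [row.ctbp_motif for row in motif_table_rows()]


def gro_core_instances(width: int = 9) -> list[str]:
    """First ``width`` residues of each annotated Gro span (the named core)."""
    return [
        row.gro_motif[:width] for row in motif_table_rows() if row.gro_motif
    ]


def ctbp_strict_pattern() -> MotifPattern:
    return compile_pattern(CTBP_STRICT_PATTERN, name="CtBP_strict")


def ctbp_relaxed_pssm(pseudocount: float = 0.5, leave_one_out: bool = False) -> Pssm:
    return build_pssm(
        ctbp_instances(),
        pseudocount=pseudocount,
        name="CtBP_relaxed",
        training_ids=[r.species for r in motif_table_rows()],
        leave_one_out=leave_one_out,
    )


def gro_core_pssm(pseudocount: float = 0.5, leave_one_out: bool = False) -> Pssm:
    return build_pssm(
        gro_core_instances(),
        pseudocount=pseudocount,
        name="Gro_core",
        training_ids=[r.species for r in motif_table_rows() if r.gro_motif],
        leave_one_out=leave_one_out,
    )


def default_motif_config() -> dict:
    """Motif configuration built from the packaged table (same shape as
    :func:`corecruit.motif_scan.load_motif_config` output)."""
    return {
        "patterns": [ctbp_strict_pattern()],
        "pssms": [ctbp_relaxed_pssm(), gro_core_pssm()],
        "contact_specs": [SBD_CONTACTS],
    }


def constructs_path() -> Path:
    return _data_path("expression_constructs.fasta")


def primers_path() -> Path:
    return _data_path("primers.fasta")


def tree_path() -> Path:
    return _data_path("arthropod_tree.nwk")


def characters_path() -> Path:
    return _data_path("characters.tsv")
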