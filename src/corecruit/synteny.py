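"""Microsynteny detection: classified adjacency between two gene families."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import GeneModel

ORIENTATION_CLASSES = ("tandem_ab", "tandem_ba", "divergent", "convergent")


class SyntenyError(ValueError):
    pass


@dataclass(frozen=True)
class SyntenyPair:
    """A classified adjacency between one family-A and one family-B gene."""

    gene_a: str
    gene_b: str
    scaffold: str
    intervening: int
    separation_bp: int
    orientation_class: str

    def __post_init__(self) -> None:
        if self.intervening < 0:
            raise SyntenyError("intervening must be >= 0")
        if self.orientation_class not in ORIENTATION_CLASSES:
            raise SyntenyError(f"unknown orientation class {self.orientation_class!r}")


def classify_orientation(a: GeneModel, b: GeneModel) -> str:
    """Orientation class of two genes on one scaffold.

    Classes are keyed to left-to-right gene order: ``tandem_ab`` / ``tandem_ba``
    (equal strands, A resp. B leftmost), ``divergent`` (head-to-head: left gene
    on ``-``, right on ``+``) and ``convergent`` (tail-to-tail).  Overlapping
    spans are rejected as order-ambiguous.
    """
    if a.scaffold != b.scaffold:
        raise SyntenyError("genes on different scaffolds")
    (a_start, a_end), (b_start, b_end) = a.span, b.span
    if a_start <= b_end and b_start <= a_end:
        raise SyntenyError(
            f"overlapping gene spans for {a.gene_id} and {b.gene_id}"
        )
    left, right = (a, b) if a_start < b_start else (b, a)
    if a.strand == b.strand:
        return "tandem_ab" if left is a else "tandem_ba"
    if left.strand == "-" and right.strand == "+":
        return "divergent"
    return "convergent"


def _separation(a: GeneModel, b: GeneModel) -> int:
    left, right = sorted((a.span, b.span))
    return max(0, right[0] - left[1] - 1)


def _intervening(a: GeneModel, b: GeneModel, genes: Sequence[GeneModel]) -> int:
    left, right = sorted((a.span, b.span))
    count = 0
    for g in genes:
        if g.gene_id in (a.gene_id, b.gene_id):
            continue
        s, e = g.span
        if s > left[1] and e < right[0]:
            count += 1
    return count


def neighbor_pairs(
    genes: Iterable[GeneModel],
    family_a: str,
    family_b: str,
    max_intervening: int = 2,
) -> list[SyntenyPair]:
    """All (family A, family B) same-scaffold pairs within ``max_intervening``.

    Every qualifying pair is reported (paralogous copies yield multiple rows;
    no one-to-one matching is imposed).  Result is sorted by intervening gene
    count, then separation.
    """
    if max_intervening < 0:
        raise SyntenyError("max_intervening must be >= 0")
    genes = list(genes)
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    pairs = []
    for scaffold, group in by_scaffold.items():
        fam_a = [g for g in group if g.family == family_a]
        fam_b = [g for g in group if g.family == family_b]
        for ga in fam_a:
            for gb in fam_b:
                if ga.gene_id == gb.gene_id:
                    continue
                inter = _intervening(ga, gb, group)
                if inter > max_intervening:
                    continue
                pairs.append(
                    SyntenyPair(
                        gene_a=ga.gene_id,
                        gene_b=gb.gene_id,
                        scaffold=scaffold,
                        intervening=inter,
                        separation_bp=_separation(ga, gb),
                        orientation_class=classify_orientation(ga, gb),
                    )
                )
    pairs.sort(key=lambda p: (p.intervening, p.separation_bp, p.gene_a, p.gene_b))
    return pairs


def write_pairs_tsv(pairs: Iterable[SyntenyPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_a\tgene_b\tscaffold\tintervening\tseparation_bp\torientation\n"
        )
        for p in pairs:
            fh.write(
                f"{p.gene_a}\t{p.gene_b}\t{p.scaffold}\t{p.intervening}\t"
                f"{p.separation_bp}\t{p.orientation_class}\n"
            )
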