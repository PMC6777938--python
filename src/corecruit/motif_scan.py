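"""Short-linear-motif detection: strict degenerate patterns and PSSM scanning.

Two scanning modes are provided.  ``scan_strict`` matches a degenerate
residue-class pattern exactly (e.g. ``P[ILMV]D[ILMV]S``).  ``scan_pssm``
scores every window with a log-odds position-specific scoring matrix trained
on aligned instances; with the default min-training-score threshold, every
training instance is recovered by construction, which is the calibration that
admits near-canonical instances a strict pattern rejects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .seqio import AMINO_ACIDS, ProteinRecord

_AA_SET = frozenset(AMINO_ACIDS)

UNIFORM_BACKGROUND: dict[str, float] = {aa: 1.0 / 20.0 for aa in AMINO_ACIDS}

#: residues treated as hydrophobic for contact checks (class for the
#: post-motif tryptophan's follower, typically V or I)
HYDROPHOBIC = frozenset("AFILMV")


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class MotifPattern:
    """Degenerate pattern: one allowed-residue set per column."""

    name: str
    columns: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.columns:
            raise MotifError(f"{self.name}: pattern has zero width")
        for i, col in enumerate(self.columns):
            if not col:
                raise MotifError(f"{self.name}: empty residue class at column {i + 1}")
            bad = set(col) - _AA_SET
            if bad:
                raise MotifError(f"{self.name}: non-residue letters {sorted(bad)}")

    @property
    def width(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class Pssm:
    """Log-odds scoring matrix (bits) with a calibrated threshold."""

    name: str
    scores: tuple[Mapping[str, float], ...]
    background: Mapping[str, float]
    pseudocount: float
    threshold: float
    training_instances: tuple[str, ...] = ()
    training_ids: tuple[str, ...] = ()

    @property
    def width(self) -> int:
        return len(self.scores)

    def score_window(self, window: str) -> float:
        if len(window) != self.width:
            raise MotifError(
                f"{self.name}: window length {len(window)} != width {self.width}"
            )
        return sum(self.scores[i][window[i]] for i in range(self.width))

    @property
    def consensus(self) -> str:
        return "".join(
            max(col, key=lambda aa: (col[aa], aa)) for col in self.scores
        )

    @property
    def max_score(self) -> float:
        return sum(max(col.values()) for col in self.scores)


@dataclass(frozen=True)
class MotifHit:
    """A scored pattern/PSSM match; span is 1-based inclusive."""

    protein_id: str
    pattern_name: str
    start: int
    end: int
    matched: str
    score: float
    in_region: bool = True

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.matched):
            raise MotifError("hit span inconsistent with matched string")


@dataclass(frozen=True)
class ContactSpec:
    """Motif-relative contact-residue requirements.

    ``contacts`` are (1-based offset within the motif, allowed residue set)
    pairs.  The downstream-tryptophan rule looks for a W within
    ``w_max_distance`` residues after the motif that is immediately followed
    by a hydrophobic residue.
    """

    name: str
    contacts: tuple[tuple[int, frozenset[str]], ...] = ()
    w_max_distance: int = 20
    hydrophobic: frozenset[str] = HYDROPHOBIC

    def __post_init__(self) -> None:
        if self.w_max_distance < 0:
            raise MotifError("w_max_distance must be >= 0")


@dataclass(frozen=True)
class ContactReport:
    satisfied: tuple[tuple[int, str], ...]
    violated: tuple[tuple[int, str], ...]
    w_position: int | None  # absolute 1-based protein coordinate
    w_follower: str | None

    @property
    def all_satisfied(self) -> bool:
        return not self.violated


def compile_pattern(spec: str, name: str | None = None) -> MotifPattern:
    """Compile a pattern string like ``"P[ILMV]D[ILMV]S"``.

    Literal letters become singleton columns; ``[...]`` groups become
    residue-class columns.
    """
    columns: list[frozenset[str]] = []
    i = 0
    while i < len(spec):
        ch = spec[i]
        if ch == "[":
            j = spec.find("]", i)
            if j == -1:
                raise MotifError(f"unclosed bracket in pattern {spec!r}")
            group = spec[i + 1:j]
            if not group:
                raise MotifError(f"empty bracket class in pattern {spec!r}")
            columns.append(frozenset(group))
            i = j + 1
        else:
            columns.append(frozenset(ch))
            i += 1
    return MotifPattern(name=name or spec, columns=tuple(columns))


def scan_strict(pattern: MotifPattern, protein: ProteinRecord) -> list[MotifHit]:
    """All windows satisfying every column, sorted by start (overlaps kept).

    Strict hits carry ``score = +inf`` as a sentinel.
    """
    seq = protein.sequence
    w = pattern.width
    hits = []
    for start in range(len(seq) - w + 1):
        window = seq[start:start + w]
        if all(window[i] in pattern.columns[i] for i in range(w)):
            hits.append(
                MotifHit(
                    protein_id=protein.id,
                    pattern_name=pattern.name,
                    start=start + 1,
                    end=start + w,
                    matched=window,
                    score=math.inf,
                    in_region=_in_region(protein, start + 1, start + w),
                )
            )
    return hits


def _in_region(protein: ProteinRecord, start: int, end: int) -> bool:
    if protein.region_boundary is None:
        return True
    return end <= protein.region_boundary


def build_pssm(
    instances: Sequence[str],
    background: Mapping[str, float] | None = None,
    pseudocount: float = 0.5,
    name: str = "pssm",
    training_ids: Sequence[str] = (),
    leave_one_out: bool = False,
) -> Pssm:
    """Train a log-odds PSSM (bits) from gap-free aligned instances.

    ``score(col, aa) = log2((count + pc*bg[aa]) / (N + pc)) - log2(bg[aa])``.
    The default threshold is the minimum score any training instance attains
    under the finished matrix; with ``leave_one_out=True`` each instance is
    instead scored under a matrix trained without it (an honesty option that
    breaks the circularity of self-scoring).
    """
    if len(instances) < 2:
        raise MotifError("need at least 2 training instances")
    width = len(instances[0])
    for inst in instances:
        if len(inst) != width:
            raise MotifError("training instances have unequal lengths")
        if "-" in inst:
            raise MotifError("gapped training instances are not supported")
    bg = dict(background) if background is not None else dict(UNIFORM_BACKGROUND)
    for inst in instances:
        for aa in inst:
            if bg.get(aa, 0.0) <= 0.0:
                raise MotifError(f"zero background frequency for observed residue {aa!r}")

    def matrix(train: Sequence[str]) -> tuple[dict[str, float], ...]:
        n = len(train)
        cols = []
        for c in range(width):
            col = {}
            for aa in AMINO_ACIDS:
                count = sum(1 for s in train if s[c] == aa)
                col[aa] = math.log2(
                    (count + pseudocount * bg[aa]) / (n + pseudocount)
                ) - math.log2(bg[aa])
            cols.append(col)
        return tuple(cols)

    scores = matrix(instances)

    def score_with(cols, s: str) -> float:
        return sum(cols[i][s[i]] for i in range(width))

    if leave_one_out:
        loo = []
        for i, inst in enumerate(instances):
            rest = list(instances[:i]) + list(instances[i + 1:])
            loo.append(score_with(matrix(rest), inst))
        threshold = min(loo)
    else:
        threshold = min(score_with(scores, inst) for inst in instances)

    return Pssm(
        name=name,
        scores=scores,
        background=bg,
        pseudocount=pseudocount,
        threshold=threshold,
        training_instances=tuple(instances),
        training_ids=tuple(training_ids),
    )


def scan_pssm(
    pssm: Pssm,
    protein: ProteinRecord,
    threshold_override: float | None = None,
) -> list[MotifHit]:
    """All windows scoring at or above threshold, by start then by -score."""
    threshold = pssm.threshold if threshold_override is None else threshold_override
    seq = protein.sequence
    w = pssm.width
    hits = []
    for start in range(len(seq) - w + 1):
        window = seq[start:start + w]
        s = pssm.score_window(window)
        if s >= threshold:
            hits.append(
                MotifHit(
                    protein_id=protein.id,
                    pattern_name=pssm.name,
                    start=start + 1,
                    end=start + w,
                    matched=window,
                    score=s,
                    in_region=_in_region(protein, start + 1, start + w),
                )
            )
    hits.sort(key=lambda h: (h.start, -h.score))
    return hits


def check_contacts(
    hit: MotifHit, protein: ProteinRecord, spec: ContactSpec
) -> ContactReport:
    """Report which contact offsets are satisfied and locate the downstream W.

    The W search covers the ``spec.w_max_distance`` residues immediately
    following the hit; a W counts only when followed by a hydrophobic residue.
    """
    seq = protein.sequence
    if protein.id != hit.protein_id:
        raise MotifError("hit does not refer to this protein")
    satisfied = []
    violated = []
    for offset, allowed in spec.contacts:
        pos = hit.start + offset - 1
        if pos > len(seq):
            raise MotifError(f"contact offset {offset} beyond protein end")
        residue = seq[pos - 1]
        (satisfied if residue in allowed else violated).append((offset, residue))
    w_position = None
    w_follower = None
    lo = hit.end  # 0-based index of first residue after the hit
    hi = min(len(seq) - 1, hit.end + spec.w_max_distance)
    for i in range(lo, hi):
        if seq[i] == "W" and seq[i + 1] in spec.hydrophobic:
            w_position = i + 1
            w_follower = seq[i + 1]
            break
    return ContactReport(
        satisfied=tuple(satisfied),
        violated=tuple(violated),
        w_position=w_position,
        w_follower=w_follower,
    )


def write_hits_tsv(hits: Iterable[MotifHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tpattern\tstart\tend\tmatched\tscore\tin_region\n")
        for h in hits:
            score = "inf" if math.isinf(h.score) else f"{h.score:.4f}"
            fh.write(
                f"{h.protein_id}\t{h.pattern_name}\t{h.start}\t{h.end}\t"
                f"{h.matched}\t{score}\t{int(h.in_region)}\n"
            )


def load_motif_config(path: str | Path) -> dict:
    """Load a YAML motif configuration.

    Schema::

        patterns:
          - {name: CtBP_strict, pattern: "P[ILMV]D[ILMV]S"}
        pssms:
          - {name: CtBP_relaxed, instances: [PVDLS, ...], pseudocount: 0.5,
             width: 5, threshold: null, leave_one_out: false}
        contact_specs:
          - {name: SBD, contacts: [[3, ILMV], [5, FILMV]],
             w_max_distance: 20, hydrophobic: AFILMV}
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    patterns = [
        compile_pattern(p["pattern"], name=p.get("name"))
        for p in raw.get("patterns", [])
    ]
    pssms = []
    for p in raw.get("pssms", []):
        instances = [str(s) for s in p["instances"]]
        width = p.get("width")
        if width:
            instances = [s[:width] for s in instances]
        pssm = build_pssm(
            instances,
            pseudocount=p.get("pseudocount", 0.5),
            name=p.get("name", "pssm"),
            leave_one_out=bool(p.get("leave_one_out", False)),
        )
        if p.get("threshold") is not None:
            pssm = Pssm(
                name=pssm.name,
                scores=pssm.scores,
                background=pssm.background,
                pseudocount=pssm.pseudocount,
                threshold=float(p["threshold"]),
                training_instances=pssm.training_instances,
                training_ids=pssm.training_ids,
            )
        pssms.append(pssm)
    contact_specs = [
        ContactSpec(
            name=c.get("name", "contacts"),
            contacts=tuple(
                (int(off), frozenset(str(allowed))) for off, allowed in c.get("contacts", [])
            ),
            w_max_distance=int(c.get("w_max_distance", 20)),
            hydrophobic=frozenset(str(c.get("hydrophobic", "".join(sorted(HYDROPHOBIC))))),
        )
        for c in raw.get("contact_specs", [])
    ]
    return {"patterns": patterns, "pssms": pssms, "contact_specs": contact_specs}
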