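"""Binary-character parsimony on species trees: Fitch and Dollo variants.

Characters are presence/absence states over tree leaves with ``?`` for
missing data (a missing leaf contributes the full state set).  Minimum change
counts are computed by dynamic programming over per-node state costs, which
reduces to Fitch's set rule on strictly bifurcating trees and remains exact
on polytomies.  Branches are identified by the leaf set below them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

MISSING = "?"
_VALID_STATES = {"0", "1", MISSING}


class CharacterError(ValueError):
    pass


@dataclass(frozen=True)
class Event:
    """A state change on the branch above the node spanning ``clade``."""

    clade: frozenset[str]
    kind: str  # "gain" | "loss"

    def __post_init__(self) -> None:
        if self.kind not in ("gain", "loss"):
            raise CharacterError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class Reconstruction:
    character: str
    method: str  # "fitch" | "dollo"
    min_changes: int
    node_states: Mapping[frozenset[str], int]
    events: tuple[Event, ...]
    unique: bool = True


@dataclass(frozen=True)
class CharacterMatrix:
    """Species-by-character binary states with explicit missing data."""

    species: tuple[str, ...]
    characters: tuple[str, ...]
    states: Mapping[tuple[str, str], str]

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise CharacterError("duplicate species rows")
        for key, value in self.states.items():
            if value not in _VALID_STATES:
                raise CharacterError(f"invalid state {value!r} at {key}")

    def column(self, character: str) -> dict[str, str]:
        if character not in self.characters:
            raise CharacterError(f"character {character!r} not in matrix")
        return {sp: self.states[(sp, character)] for sp in self.species}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("species\t" + "\t".join(self.characters) + "\n")
            for sp in self.species:
                row = "\t".join(self.states[(sp, c)] for c in self.characters)
                fh.write(f"{sp}\t{row}\n")


def read_character_matrix(path: str | Path) -> CharacterMatrix:
    """Read a TSV matrix (species rows, character columns, states 0/1/?)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna(MISSING)
    if df.columns[0] != "species":
        df = df.rename(columns={df.columns[0]: "species"})
    characters = tuple(df.columns[1:])
    species = tuple(df["species"])
    states = {}
    for _, row in df.iterrows():
        for c in characters:
            states[(row["species"], c)] = str(row[c])
    return CharacterMatrix(species=species, characters=characters, states=states)


def load_tree(path: str | Path) -> dendropy.Tree:
    """Load a rooted newick tree; leaf labels must be unique."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise CharacterError("duplicate leaf labels in tree")
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return tree


def _clade(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def _normalize(states: Mapping[str, object]) -> dict[str, str]:
    out = {}
    for sp, value in states.items():
        s = MISSING if value is None else str(value)
        if s not in _VALID_STATES:
            raise CharacterError(f"invalid state {value!r} for {sp}")
        out[sp] = s
    return out


def _check_leaves(tree: dendropy.Tree, states: Mapping[str, str]) -> None:
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = set(states) - leaves
    if unknown:
        raise CharacterError(f"species not on tree: {sorted(unknown)}")


def fitch_parsimony(
    tree: dendropy.Tree, states: Mapping[str, object], character: str = "character"
) -> Reconstruction:
    """Minimum-change reconstruction of one binary character.

    Missing (``?`` or absent) leaves are unconstrained.  One most-parsimonious
    reconstruction is materialized, preferring state 0 at the root and the
    parental state along branches when tied; ``unique=False`` flags that
    alternative assignments exist.
    """
    states = _normalize(states)
    _check_leaves(tree, states)
    scored = {sp for sp, s in states.items() if s != MISSING}
    if len(scored) < 2:
        raise CharacterError("need at least 2 scored leaves")

    inf = float("inf")
    cost: dict[dendropy.Node, list[float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states.get(node.taxon.label, MISSING)
            if s == MISSING:
                cost[node] = [0.0, 0.0]
            else:
                cost[node] = [0.0, inf] if s == "0" else [inf, 0.0]
        else:
            c0 = c1 = 0.0
            for child in node.child_nodes():
                cc = cost[child]
                c0 += min(cc[0], cc[1] + 1)
                c1 += min(cc[1], cc[0] + 1)
            cost[node] = [c0, c1]

    root = tree.seed_node
    min_changes = int(min(cost[root]))
    unique = True
    assignment: dict[dendropy.Node, int] = {}
    if cost[root][0] == cost[root][1]:
        unique = False
    assignment[root] = 0 if cost[root][0] <= cost[root][1] else 1
    events: list[Event] = []
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = assignment[node.parent_node]
        keep = cost[node][parent_state]
        flip = cost[node][1 - parent_state] + 1
        if keep == flip:
            unique = False
        state = parent_state if keep <= flip else 1 - parent_state
        assignment[node] = state
        if state != parent_state:
            events.append(
                Event(clade=_clade(node), kind="gain" if state == 1 else "loss")
            )
    node_states = {_clade(n): s for n, s in assignment.items()}
    return Reconstruction(
        character=character,
        method="fitch",
        min_changes=min_changes,
        node_states=node_states,
        events=tuple(events),
        unique=unique,
    )


def dollo_parsimony(
    tree: dendropy.Tree, states: Mapping[str, object], character: str = "character"
) -> Reconstruction:
    """Single-gain reconstruction: one gain plus the minimum number of losses.

    The gain is placed on the stem of the smallest clade containing every
    state-1 leaf; each maximal subtree within that clade whose scored leaves
    are all 0 receives one loss.
    """
    states = _normalize(states)
    _check_leaves(tree, states)
    ones = [sp for sp, s in states.items() if s == "1"]
    if not ones:
        raise CharacterError("Dollo parsimony needs at least one state-1 leaf")

    taxa = [tree.taxon_namespace.get_taxon(sp) for sp in ones]
    if len(ones) == 1:
        mrca = next(
            leaf for leaf in tree.leaf_node_iter() if leaf.taxon.label == ones[0]
        )
    else:
        mrca = tree.mrca(taxa=taxa)

    # all_zero: node has >= 1 scored descendant leaf, all in state 0
    n_scored: dict[dendropy.Node, int] = {}
    all_zero: dict[dendropy.Node, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states.get(node.taxon.label, MISSING)
            n_scored[node] = int(s != MISSING)
            all_zero[node] = s == "0"
        else:
            children = node.child_nodes()
            n_scored[node] = sum(n_scored[c] for c in children)
            all_zero[node] = n_scored[node] > 0 and all(
                all_zero[c] or n_scored[c] == 0 for c in children
            )

    loss_nodes: list[dendropy.Node] = []

    def collect(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            if all_zero[child]:
                loss_nodes.append(child)
            else:
                collect(child)

    collect(mrca)
    events = [Event(clade=_clade(mrca), kind="gain")]
    events.extend(Event(clade=_clade(n), kind="loss") for n in loss_nodes)

    lost_under = set()
    for n in loss_nodes:
        lost_under.add(n)
        lost_under.update(n.preorder_iter())
    inside = set(mrca.preorder_iter())
    node_states = {}
    for node in tree.preorder_node_iter():
        node_states[_clade(node)] = int(node in inside and node not in lost_under)
    return Reconstruction(
        character=character,
        method="dollo",
        min_changes=1 + len(loss_nodes),
        node_states=node_states,
        events=tuple(events),
        unique=True,
    )


def hybrid_species(
    matrix: CharacterMatrix,
    required: Sequence[str] = ("Hairless", "SuH_CtBP", "SuH_Gro"),
) -> list[str]:
    """Species scored 1 for every required character (adaptor protein plus
    both ancestral recruitment motifs retained)."""
    for character in required:
        if character not in matrix.characters:
            raise CharacterError(f"required character {character!r} missing")
    return [
        sp
        for sp in matrix.species
        if all(matrix.states[(sp, c)] == "1" for c in required)
    ]


def render_ascii(tree: dendropy.Tree, node_states: Mapping[frozenset[str], int]) -> str:
    """Plain-text tree with per-node reconstructed states."""
    lines: list[str] = []

    def walk(node: dendropy.Node, depth: int) -> None:
        state = node_states.get(_clade(node), "?")
        label = node.taxon.label if node.is_leaf() else "*"
        lines.append("  " * depth + f"{label} [{state}]")
        for child in node.child_nodes():
            walk(child, depth + 1)

    walk(tree.seed_node, 0)
    return "\n".join(lines)
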