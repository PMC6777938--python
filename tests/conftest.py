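import random

import pytest

from corecruit.seqio import GeneModel, reverse_complement


@pytest.fixture
def toy_scaffold():
    # 24 nt; CDS 1-9 + 13-21 (two exons, 3 nt intron, 3 nt tail)
    # exon1 encodes MGR, exon2 encodes SV + stop
    return {"scf": "ATGGGTCGCGTTAGCGTGTAACCC"}


@pytest.fixture
def toy_gene_plus():
    return GeneModel(
        gene_id="toy+", scaffold="scf", strand="+", exons=((1, 9), (13, 21))
    )


def mirror_dataset(models, scaffolds):
    """Reverse-complement every scaffold and flip all gene models."""
    flipped_scaffolds = {k: reverse_complement(v) for k, v in scaffolds.items()}
    flipped = []
    for m in models:
        L = len(scaffolds[m.scaffold])
        exons = tuple((L - e + 1, L - s + 1) for s, e in m.exons)
        flipped.append(
            GeneModel(
                gene_id=m.gene_id,
                scaffold=m.scaffold,
                strand="-" if m.strand == "+" else "+",
                exons=exons,
                protein_id=m.protein_id,
                family=m.family,
            )
        )
    return flipped, flipped_scaffolds


def random_binary_tree(rng: random.Random, n_leaves: int, polytomy_p: float = 0.0):
    """Random (optionally multifurcating) rooted tree as a newick string."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        k = 2
        if polytomy_p and len(nodes) > 2 and rng.random() < polytomy_p:
            k = 3
        picked = [nodes.pop(rng.randrange(len(nodes))) for _ in range(k)]
        nodes.append("(" + ",".join(picked) + ")")
    return nodes[0] + ";"
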