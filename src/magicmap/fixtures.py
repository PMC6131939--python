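"""Deterministic scenario fixtures shared by the pipeline, tests and CLI.

The analysis scenario needs a gene model around the causal coordinate, a
target CDS of the documented length for silencing design, and a small
synthetic transcriptome to scan against.  None of these reproduce real
cotton sequence; they are structurally faithful stand-ins.
"""

from __future__ import annotations

import numpy as np

from magicmap.effects import GeneModel
from magicmap.genmap import CAUSAL_CHROM, CAUSAL_POS

CAUSAL_GENE_ID = "GeneD10.1401"
TARGET_CDS_LENGTH = 1562  # yields 1542 overlapping 21-mers
_BASES = np.array(list("ACGT"))


def causal_gene_model() -> GeneModel:
    """Five-exon plus-strand gene with the causal position inside exon 3.

    Exon lengths 200/200/200/200/100 (900 bp CDS, a codon multiple); the
    causal insertion point 28,455,988 falls in the third exon.
    """
    exons = [
        (28_455_000, 28_455_199),
        (28_455_300, 28_455_499),
        (28_455_900, 28_456_099),
        (28_456_200, 28_456_399),
        (28_456_500, 28_456_599),
    ]
    g = GeneModel(CAUSAL_GENE_ID, CAUSAL_CHROM, "+", exons)
    assert g.exons[2][0] <= CAUSAL_POS <= g.exons[2][1]
    return g


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def target_cds(seed: int = 20160105) -> str:
    """Deterministic silencing-target CDS of the documented length."""
    rng = np.random.default_rng(seed)
    return random_sequence(TARGET_CDS_LENGTH, rng)


def toy_transcriptome(
    target_id: str = CAUSAL_GENE_ID,
    n_other: int = 20,
    seed: int = 20160105,
    paralog_identity: float = 0.92,
) -> dict[str, str]:
    """Target CDS plus unrelated transcripts and one diverged paralog.

    The paralog shares most of the target sequence (point-mutated to the
    given identity), giving the scan a realistic off-target-rich region.
    """
    rng = np.random.default_rng(seed)
    cds = random_sequence(TARGET_CDS_LENGTH, rng)
    db = {target_id: cds}
    for i in range(n_other):
        db[f"TX{i + 1:03d}"] = random_sequence(int(rng.integers(600, 2000)), rng)
    paralog = list(cds)
    n_mut = int(round((1 - paralog_identity) * len(paralog)))
    for pos in rng.choice(len(paralog), size=n_mut, replace=False):
        current = paralog[pos]
        choices = [b for b in "ACGT" if b != current]
        paralog[pos] = choices[int(rng.integers(3))]
    db["PARALOG1"] = "".join(paralog)
    return db
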