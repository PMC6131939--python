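"""Variant effect classification against gene models.

Handles the two coding-effect questions the analysis needs: where a variant
falls relative to a gene's exon structure (with frameshift / in-frame
distinction for indels), and whether a homeologous region carries a
frame-disrupting indel relative to a functional coding sequence
(pseudogene detection by global alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio import Align
from Bio.Seq import Seq

# effect categories
INTERGENIC = "intergenic"
INTRONIC = "intronic"
EXONIC_SUBSTITUTION = "exonic_substitution"
EXONIC_INFRAME = "exonic_inframe"
EXONIC_FRAMESHIFT = "exonic_frameshift"
BOUNDARY_SPANNING = "boundary_spanning"


@dataclass
class GeneModel:
    """A CDS gene model: ordered exon intervals, 1-based closed coordinates.

    Exons are stored sorted in genome order; transcript order follows the
    strand (reversed for minus-strand genes).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in exons:
            if a > b:
                raise ValueError(f"malformed exon ({a},{b})")
        for (_, b0), (a1, _) in zip(exons, exons[1:]):
            if a1 <= b0:
                raise ValueError("exons overlap")
        self.exons = exons
        if self.cds_length < 3:
            raise ValueError("total CDS length must be >= 3")

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def transcript_exons(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def exon_ordinal(self, genome_exon_index: int) -> int:
        """1-based exon number in transcript orientation."""
        if self.strand == "+":
            return genome_exon_index + 1
        return len(self.exons) - genome_exon_index

    def cds_offset(self, pos: int) -> int:
        """0-based CDS offset of an exonic genomic position."""
        offset = 0
        for a, b in self.transcript_exons:
            if a <= pos <= b:
                return offset + (pos - a if self.strand == "+" else b - pos)
            offset += b - a + 1
        raise ValueError(f"position {pos} is not exonic in {self.gene_id}")


@dataclass
class Variant:
    """A VCF-style variant: 1-based position, anchored ref/alt strings."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        for a in (self.ref, self.alt):
            if set(a.upper()) - set("ACGTN"):
                raise ValueError(f"invalid allele {a!r}")

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    def normalized(self) -> "Variant":
        """Minimal representation: trim shared suffix, then shared prefix.

        Equivalent to VCF left-trimming for anchored indels; the position is
        advanced past any trimmed prefix bases.
        """
        ref, alt, pos = self.ref.upper(), self.alt.upper(), self.pos
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        return Variant(self.chrom, pos, ref, alt)


@dataclass
class VariantEffect:
    category: str
    exon_ordinal: Optional[int] = None
    cds_offset: Optional[int] = None
    codon: Optional[int] = None

    def __post_init__(self) -> None:
        exonic = self.category in (EXONIC_SUBSTITUTION, EXONIC_INFRAME, EXONIC_FRAMESHIFT)
        if exonic != (self.exon_ordinal is not None):
            raise ValueError("exon ordinal must be set iff category is exonic")


def _locate(gene: GeneModel, pos: int) -> tuple[str, int | None]:
    """('exon', genome-order exon index) / ('intron', None) / ('outside', None)."""
    lo, hi = gene.span
    if pos < lo or pos > hi:
        return "outside", None
    for i, (a, b) in enumerate(gene.exons):
        if a <= pos <= b:
            return "exon", i
    return "intron", None


def classify_variant_effect(variant: Variant, gene: GeneModel) -> VariantEffect:
    """Classify a variant against one gene model.

    Indels use the anchored-VCF convention: an insertion sits between
    ``pos`` and ``pos + 1``; a deletion removes ``pos + 1 .. pos + len - 1``.
    Events overlapping an exon-intron boundary are reported as
    ``boundary_spanning`` rather than silently assigned to either side.
    """
    v = variant.normalized()
    if v.chrom != gene.chrom:
        return VariantEffect(INTERGENIC)

    if len(v.ref) == len(v.alt) == 1:  # SNV
        where, i = _locate(gene, v.pos)
        if where == "outside":
            return VariantEffect(INTERGENIC)
        if where == "intron":
            return VariantEffect(INTRONIC)
        off = gene.cds_offset(v.pos)
        return VariantEffect(EXONIC_SUBSTITUTION, gene.exon_ordinal(i), off, off // 3 + 1)

    if len(v.ref) == 1 and len(v.alt) > 1:  # insertion after anchor base v.pos
        affected = [v.pos, v.pos + 1]
    elif len(v.alt) == 1 and len(v.ref) > 1:  # deletion of v.pos+1 .. v.pos+len(ref)-1
        affected = list(range(v.pos + 1, v.pos + len(v.ref)))
    else:  # complex substitution block
        affected = list(range(v.pos, v.pos + len(v.ref)))

    located = [_locate(gene, p) for p in affected]
    wheres = {w for w, _ in located}
    if wheres == {"outside"}:
        return VariantEffect(INTERGENIC)
    if wheres == {"intron"}:
        return VariantEffect(INTRONIC)
    exon_idx = {i for w, i in located if w == "exon"}
    if wheres != {"exon"} or len(exon_idx) != 1:
        return VariantEffect(BOUNDARY_SPANNING)

    i = exon_idx.pop()
    # anchor the CDS offset at the transcript-wise first affected base
    anchor = min(affected) if gene.strand == "+" else max(affected)
    off = gene.cds_offset(anchor)
    if v.indel_length == 0:
        cat = EXONIC_SUBSTITUTION
    elif v.indel_length % 3 == 0:
        cat = EXONIC_INFRAME
    else:
        cat = EXONIC_FRAMESHIFT
    return VariantEffect(cat, gene.exon_ordinal(i), off, off // 3 + 1)


# ---------------------------------------------------------------------------
# pseudogene detection by global alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignmentGap:
    """A gap in the pairwise alignment, in query coordinates (0-based)."""

    query_offset: int
    length: int
    kind: str  # "insertion" (extra bases in subject) or "deletion" (missing in subject)


@dataclass
class PseudogeneReport:
    homologous: bool
    identity: float
    gaps: list[AlignmentGap] = field(default_factory=list)
    net_indel: int = 0
    frameshift: bool = False
    score: float = 0.0


def detect_pseudogene(
    cds_query: str,
    region_subject: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    identity_floor: float = 0.6,
) -> PseudogeneReport:
    """Globally align a subject region to a functional CDS and report gaps.

    The subject is declared a pseudogenizing frameshift when the net indel
    length (subject minus query) is not a multiple of 3.  Subjects below
    ``identity_floor`` fractional identity are reported as not homologous
    and never called frameshifted.
    """
    q = str(Seq(cds_query).upper())
    s = str(Seq(region_subject).upper())
    if not q or not s:
        raise ValueError("sequences must be non-empty")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(q, s)[0]

    qa, sa = str(aln[0]), str(aln[1])
    n_cols = len(qa)
    matches = sum(1 for a, b in zip(qa, sa) if a == b and a != "-")
    identity = matches / n_cols if n_cols else 0.0

    gaps: list[AlignmentGap] = []
    qoff = 0
    col = 0
    while col < n_cols:
        if qa[col] == "-":  # extra bases in subject
            start = col
            while col < n_cols and qa[col] == "-":
                col += 1
            gaps.append(AlignmentGap(qoff, col - start, "insertion"))
        elif sa[col] == "-":  # bases missing from subject
            start = col
            while col < n_cols and sa[col] == "-":
                col += 1
            gaps.append(AlignmentGap(qoff, col - start, "deletion"))
            qoff += col - start
        else:
            qoff += 1
            col += 1

    if identity < identity_floor:
        return PseudogeneReport(False, identity, [], 0, False, float(aln.score))

    net = len(s) - len(q)
    return PseudogeneReport(True, identity, gaps, net, net % 3 != 0, float(aln.score))
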