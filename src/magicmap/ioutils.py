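"""File I/O helpers: FASTA, GFF3 gene models, phenotype and expression TSVs.

All writers are deterministic (no timestamps) so identical runs produce
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from magicmap.coexpression import RAW_COLUMNS
from magicmap.effects import GeneModel
from magicmap.popsim import PhenotypeTable

# ------------------------------------------------------------------ FASTA


def write_fasta(records: dict[str, str], path: str | Path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ------------------------------------------------------------------ GFF3


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Gene models as GFF3 (gene + mRNA + CDS features, 1-based closed)."""
    lines = ["##gff-version 3"]
    for g in genes:
        lo, hi = g.span
        lines.append(
            f"{g.chrom}\tmagicmap\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
        mrna = f"{g.gene_id}.1"
        lines.append(
            f"{g.chrom}\tmagicmap\tmRNA\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
            f"ID={mrna};Parent={g.gene_id}"
        )
        # CDS phase of the first transcript-order exon is the model's phase
        tx_exons = g.transcript_exons
        phase = g.cds_phase
        phases: dict[tuple[int, int], int] = {}
        for a, b in tx_exons:
            phases[(a, b)] = phase
            phase = (3 - ((b - a + 1 - phase) % 3)) % 3
        for a, b in g.exons:
            lines.append(
                f"{g.chrom}\tmagicmap\tCDS\t{a}\t{b}\t.\t{g.strand}\t{phases[(a, b)]}\t"
                f"ID=cds.{mrna};Parent={mrna}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse GFF3 CDS features grouped by gene into :class:`GeneModel`."""
    genes: dict[str, dict] = {}
    parent_gene: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        chrom, _, ftype, start, end, _, strand, phase, attrs = fields
        attr = dict(
            kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
        )
        if ftype == "gene":
            genes[attr["ID"]] = {
                "chrom": chrom, "strand": strand, "exons": [], "phase": 0,
            }
        elif ftype == "mRNA":
            parent_gene[attr["ID"]] = attr.get("Parent", attr["ID"])
        elif ftype == "CDS":
            gid = parent_gene.get(attr.get("Parent", ""), attr.get("Parent", ""))
            rec = genes.setdefault(
                gid, {"chrom": chrom, "strand": strand, "exons": [], "phase": 0}
            )
            rec["exons"].append((int(start), int(end)))
    out = []
    for gid, rec in genes.items():
        if rec["exons"]:
            out.append(
                GeneModel(gid, rec["chrom"], rec["strand"], rec["exons"], rec["phase"])
            )
    return out


# ------------------------------------------------------------------ TSVs


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(table.labels.items()), columns=["sample", "phenotype"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path, penetrance: float = 1.0) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return PhenotypeTable(dict(zip(df["sample"], df["phenotype"])), penetrance)


def write_expression(raw: pd.DataFrame, path: str | Path) -> None:
    raw[RAW_COLUMNS].to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(RAW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns {sorted(missing)}")
    return df
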