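"""Shared genotype-matrix container with VCF emission/ingestion.

Call codes: 0 hom-ref, 1 het, 2 hom-alt, -1 missing.  Sites are rows,
samples columns; every cell carries a read depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
_GT_CODES = {v: k for k, v in _GT_STRINGS.items()}
_GT_CODES["1/0"] = HET


@dataclass
class GenotypeMatrix:
    """sites x samples call matrix over {hom_ref, het, hom_alt, missing}."""

    sites: pd.DataFrame  # columns: chrom, pos, ref, alt
    samples: list[str]
    calls: np.ndarray  # int8 (n_sites, n_samples)
    depth: np.ndarray  # int32 (n_sites, n_samples)
    sample_class: dict[str, str] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        ns, nm = len(self.sites), len(self.samples)
        if self.calls.shape != (ns, nm) or self.depth.shape != (ns, nm):
            raise ValueError("calls/depth shape must be (n_sites, n_samples)")
        if not set(np.unique(self.calls)) <= {HOM_REF, HET, HOM_ALT, MISSING}:
            raise ValueError("invalid call codes")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"positions not sorted within {chrom}")
        for s in self.sample_class:
            if s not in self.samples:
                raise ValueError(f"class given for unknown sample {s!r}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError as exc:
            raise KeyError(f"unknown sample {sample!r}") from exc

    def samples_of_class(self, cls: str) -> list[str]:
        return [s for s in self.samples if self.sample_class.get(s) == cls]

    def site_index(self, chrom: str, pos: int) -> int:
        hit = self.sites.index[(self.sites["chrom"] == chrom) & (self.sites["pos"] == pos)]
        if len(hit) != 1:
            raise KeyError(f"no unique site at {chrom}:{pos}")
        return int(self.sites.index.get_indexer(hit)[0])

    def subset_region(self, chrom: str, start: int, end: int) -> "GenotypeMatrix":
        """Rows with chrom match and start <= pos <= end (1-based closed)."""
        mask = (
            (self.sites["chrom"] == chrom)
            & (self.sites["pos"] >= start)
            & (self.sites["pos"] <= end)
        ).to_numpy()
        return GenotypeMatrix(
            self.sites.loc[mask].reset_index(drop=True),
            list(self.samples),
            self.calls[mask],
            self.depth[mask],
            dict(self.sample_class),
            self.seed,
        )

    # ------------------------------------------------------------------ VCF

    def to_vcf(self, path: str | Path) -> None:
        """Write VCF 4.2 with GT:DP, missing genotypes as "./.".

        Sample classes and the simulation seed are recorded in the header so
        a round trip preserves them.  Output is byte-deterministic.
        """
        lines = [
            "##fileformat=VCFv4.2",
            "##source=magicmap",
        ]
        if self.seed is not None:
            lines.append(f"##magicmap_seed={self.seed}")
        for s in self.samples:
            cls = self.sample_class.get(s, "unknown")
            lines.append(f"##SAMPLE=<ID={s},Class={cls}>")
        for chrom in self.sites["chrom"].unique():
            lines.append(f"##contig=<ID={chrom}>")
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">')
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(self.samples)
        )
        rows = self.sites.itertuples(index=True)
        for row in rows:
            cells = "\t".join(
                f"{_GT_STRINGS[int(c)]}:{int(d)}"
                for c, d in zip(self.calls[row.Index], self.depth[row.Index])
            )
            lines.append(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT:DP\t{cells}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_vcf(cls, path: str | Path) -> "GenotypeMatrix":
        """Read a GT:DP VCF written by :meth:`to_vcf` (or compatible)."""
        import pysam

        vcf = pysam.VariantFile(str(path))
        samples = list(vcf.header.samples)
        sample_class: dict[str, str] = {}
        seed = None
        for rec in vcf.header.records:
            text = str(rec)
            if text.startswith("##magicmap_seed="):
                seed = int(text.split("=", 1)[1])
            elif text.startswith("##SAMPLE=<"):
                inner = text.strip()[len("##SAMPLE=<") : -1]
                kv = dict(p.split("=", 1) for p in inner.split(","))
                if "ID" in kv and "Class" in kv:
                    sample_class[kv["ID"]] = kv["Class"]

        site_rows = []
        call_rows = []
        depth_rows = []
        for rec in vcf:
            site_rows.append((rec.chrom, rec.pos, rec.ref, rec.alts[0]))
            crow = np.empty(len(samples), dtype=np.int8)
            drow = np.zeros(len(samples), dtype=np.int32)
            for j, s in enumerate(samples):
                sm = rec.samples[s]
                gt = sm.get("GT")
                if gt is None or gt[0] is None:
                    crow[j] = MISSING
                else:
                    crow[j] = int(gt[0]) + int(gt[1] if len(gt) > 1 and gt[1] is not None else gt[0])
                dp = sm.get("DP")
                drow[j] = 0 if dp is None else int(dp)
            call_rows.append(crow)
            depth_rows.append(drow)
        vcf.close()
        sites = pd.DataFrame(site_rows, columns=["chrom", "pos", "ref", "alt"])
        calls = np.vstack(call_rows) if call_rows else np.empty((0, len(samples)), np.int8)
        depth = np.vstack(depth_rows) if depth_rows else np.empty((0, len(samples)), np.int32)
        return cls(sites, samples, calls, depth, sample_class, seed)
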