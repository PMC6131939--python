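"""Phenotype-concordance variant filtering and marker checks.

The discovery filter keeps a site when the designated sensitive parent is
homozygous for the alternate allele, every other parent is homozygous
reference, every sensitive line is homozygous alternate, and (optionally) no
tolerant line is homozygous alternate.  "Permissive" mode lets missing
calls satisfy any rule (needed at shallow coverage, where depth-0 cells are
common); "strict" mode requires every relevant call to be present.
Heterozygous calls in inbred lines always disqualify a site: a sensitive
heterozygote contradicts a recessive causal model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from magicmap.genotypes import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix
from magicmap.popsim import SENSITIVE, TOLERANT, PhenotypeTable

PERMISSIVE = "permissive"
STRICT = "strict"


@dataclass
class FilterConfig:
    mode: str = PERMISSIVE
    region: Optional[tuple[str, int, int]] = None  # (chrom, start, end), 1-based closed
    require_tolerant_exclusion: bool = True

    def __post_init__(self) -> None:
        if self.mode not in (PERMISSIVE, STRICT):
            raise ValueError(f"mode must be {PERMISSIVE!r} or {STRICT!r}")
        if self.region is not None:
            chrom, start, end = self.region
            if start > end or start < 1:
                raise ValueError(f"malformed region {self.region}")


@dataclass
class CandidateSet:
    """Sites passing every active rule, with per-site evidence tallies."""

    table: pd.DataFrame  # chrom, pos, ref, alt, n_sensitive_hom_alt, n_missing, n_tolerant_hom_alt
    config: FilterConfig
    sensitive_parent: str

    def __len__(self) -> int:
        return len(self.table)

    def positions(self) -> list[tuple[str, int]]:
        return list(zip(self.table["chrom"], self.table["pos"]))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_bed(self, path) -> None:
        bed = pd.DataFrame(
            {
                "chrom": self.table["chrom"],
                "start": self.table["pos"] - 1,
                "end": self.table["pos"],
            }
        )
        bed.to_csv(path, sep="\t", index=False, header=False)


def _split_samples(
    matrix: GenotypeMatrix, phenotypes: PhenotypeTable, sensitive_parent: str
) -> tuple[list[int], list[int], list[int]]:
    """Column indices of (other parents, sensitive lines, tolerant lines)."""
    if sensitive_parent not in matrix.samples:
        raise ValueError(f"sensitive parent {sensitive_parent!r} not in matrix")
    parents = [
        s for s in matrix.samples if matrix.sample_class.get(s) == "parent"
    ]
    other_parents = [matrix.sample_index(s) for s in parents if s != sensitive_parent]
    non_parents = [s for s in matrix.samples if matrix.sample_class.get(s) != "parent"]
    sensitive = [
        matrix.sample_index(s)
        for s in non_parents
        if phenotypes.labels.get(s) == SENSITIVE
    ]
    tolerant = [
        matrix.sample_index(s)
        for s in non_parents
        if phenotypes.labels.get(s) == TOLERANT
    ]
    if not sensitive:
        raise ValueError("no sensitive non-parent samples: filter is undefined")
    return other_parents, sensitive, tolerant


def concordance_filter(
    matrix: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    sensitive_parent: str,
    config: FilterConfig | None = None,
) -> CandidateSet:
    """Sites whose alternate allele is unique to the sensitive parent and
    shared by every sensitive line."""
    config = config or FilterConfig()
    work = matrix
    if config.region is not None:
        work = matrix.subset_region(*config.region)
    other_parents, sensitive, tolerant = _split_samples(work, phenotypes, sensitive_parent)
    sp = work.sample_index(sensitive_parent)

    calls = work.calls
    missing_ok = config.mode == PERMISSIVE

    # (a) sensitive parent hom-alt
    ok = calls[:, sp] == HOM_ALT
    # (b) every other parent hom-ref
    if other_parents:
        op = calls[:, other_parents]
        rule_b = op == HOM_REF
        if missing_ok:
            rule_b |= op == MISSING
        ok &= rule_b.all(axis=1)
    # (c) every sensitive line hom-alt (het always disqualifies)
    sens = calls[:, sensitive]
    rule_c = sens == HOM_ALT
    if missing_ok:
        rule_c |= sens == MISSING
    ok &= rule_c.all(axis=1)
    # (d) no tolerant line hom-alt
    if config.require_tolerant_exclusion and tolerant:
        tol = calls[:, tolerant]
        rule_d = tol != HOM_ALT
        if not missing_ok:
            rule_d &= tol != MISSING
        ok &= rule_d.all(axis=1)

    idx = np.flatnonzero(ok)
    focus_cols = [sp] + other_parents + sensitive + tolerant
    table = work.sites.iloc[idx].reset_index(drop=True).copy()
    table["n_sensitive_hom_alt"] = (sens[idx] == HOM_ALT).sum(axis=1)
    table["n_missing"] = (calls[np.ix_(idx, focus_cols)] == MISSING).sum(axis=1)
    if tolerant:
        table["n_tolerant_hom_alt"] = (calls[np.ix_(idx, tolerant)] == HOM_ALT).sum(axis=1)
    else:
        table["n_tolerant_hom_alt"] = 0
    return CandidateSet(table, config, sensitive_parent)


# ---------------------------------------------------------------------------
# marker concordance
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceReport:
    """Genotype x phenotype tallies at one marker."""

    counts: pd.DataFrame  # index: genotype class, columns: phenotype
    n_discordant: int
    n_missing: int
    n_total: int


_CALL_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}


def marker_concordance(
    calls: np.ndarray,
    sample_ids: list[str],
    phenotypes: PhenotypeTable,
    model: str = "recessive_sensitive",
) -> ConcordanceReport:
    """Count discordant genotype-phenotype pairs at one site.

    Discordant: sensitive but not hom-alt, or tolerant but hom-alt.  Missing
    genotypes are tallied separately, never as discordant.  The
    ``dominant_tolerant`` model is the same rule seen from the tolerant
    allele's side and is accepted as an alias.
    """
    if model not in ("recessive_sensitive", "dominant_tolerant"):
        raise ValueError(f"unknown concordance model {model!r}")
    calls = np.asarray(calls)
    if len(calls) != len(sample_ids):
        raise ValueError("calls and sample_ids length mismatch")
    labels = [phenotypes.labels[s] for s in sample_ids]

    cells = pd.DataFrame(
        0,
        index=["hom_ref", "het", "hom_alt", "missing"],
        columns=[TOLERANT, SENSITIVE],
    )
    n_disc = 0
    n_miss = 0
    for c, lab in zip(calls, labels):
        cells.loc[_CALL_NAMES[int(c)], lab] += 1
        if c == MISSING:
            n_miss += 1
        elif lab == SENSITIVE and c != HOM_ALT:
            n_disc += 1
        elif lab == TOLERANT and c == HOM_ALT:
            n_disc += 1
    return ConcordanceReport(cells, n_disc, n_miss, len(calls))


# ---------------------------------------------------------------------------
# cultivar panel screen
# ---------------------------------------------------------------------------

MUTANT = "mutant"
WILD_TYPE = "wild-type"
HETEROGENEOUS = "heterogeneous"


def screen_panel(
    calls: np.ndarray,
    sample_ids: list[str],
    cultivar_of: dict[str, str],
) -> dict[str, str]:
    """Classify each cultivar pool at one site.

    ``mutant`` when every informative call is hom-alt, ``wild-type`` when all
    are hom-ref, otherwise ``heterogeneous`` (a het call or a mix — the
    signature of a pooled-DNA sample segregating for the allele).
    """
    calls = np.asarray(calls)
    pools: dict[str, list[int]] = {}
    for c, s in zip(calls, sample_ids):
        cult = cultivar_of.get(s)
        if cult is None:
            raise ValueError(f"sample {s!r} not assigned to a cultivar")
        pools.setdefault(cult, []).append(int(c))
    if not pools:
        raise ValueError("empty cultivar pool")

    status: dict[str, str] = {}
    for cult, cc in pools.items():
        informative = [c for c in cc if c != MISSING]
        if not informative:
            raise ValueError(f"cultivar {cult!r} has no informative calls")
        if all(c == HOM_ALT for c in informative):
            status[cult] = MUTANT
        elif all(c == HOM_REF for c in informative):
            status[cult] = WILD_TYPE
        else:
            status[cult] = HETEROGENEOUS
    return status
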