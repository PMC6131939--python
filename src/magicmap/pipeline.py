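"""End-to-end driver: simulate -> observe -> filter -> annotate -> segtest.

Everything is driven by one :class:`RunConfig`; all randomness flows from
its single seed, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from magicmap import observe, popsim
from magicmap.concordance import FilterConfig, concordance_filter, marker_concordance
from magicmap.effects import Variant, classify_variant_effect
from magicmap.fixtures import causal_gene_model
from magicmap.genmap import CAUSAL_CHROM, CAUSAL_POS, GeneticMap
from magicmap.ioutils import write_gff3, write_phenotypes
from magicmap.segregation import chi_square_segregation

logger = logging.getLogger("magicmap")


@dataclass
class RunConfig:
    seed: int = 0
    n_founders: int = 11
    n_sites: int = 1000
    n_rils: int = 550
    n_f2: int = 2145
    n_random_mating_cycles: int = 5
    n_selfing_generations: int = 6
    parent_depth: float = 20.0
    ril_depth: float = 3.0
    error_rate: float = 0.001
    allele_freq: float = 0.3
    penetrance: float = 1.0
    filter_mode: str = "permissive"
    require_tolerant_exclusion: bool = True
    outdir: str = "magicmap_run"

    def validate(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.n_rils < 1:
            raise ValueError("n_rils must be >= 1")
        if self.n_f2 < 1:
            raise ValueError("n_f2 must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.filter_mode not in ("permissive", "strict"):
            raise ValueError(f"unknown filter mode {self.filter_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunReport:
    config: RunConfig
    n_sensitive_rils: int
    n_candidates: int
    causal_in_candidates: bool
    causal_effect: str
    causal_exon: int | None
    f2_counts: dict
    f2_chi_square: float
    f2_verdict: str
    f2_discordant: int
    files: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def _stage(name: str, **counts) -> None:
    detail = ", ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("[%s] %s", name, detail)


def run_pipeline(config: RunConfig) -> RunReport:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")

    rng = np.random.default_rng(config.seed)

    # stage 1: founders ---------------------------------------------------
    gmap = GeneticMap.default(config.n_sites)
    panel = popsim.simulate_founders(
        config.n_founders,
        gmap.n_sites,
        gmap,
        CAUSAL_CHROM,
        CAUSAL_POS,
        causal_founder=0,
        allele_freq=config.allele_freq,
        seed=rng,
    )
    sensitive_parent = panel.founder_ids[panel.causal_founder]
    _stage("simulate_founders", founders=panel.n_founders, sites=panel.n_sites)

    # stage 2: MAGIC RILs + phenotypes ------------------------------------
    design = popsim.BreedingDesign(
        scheme="half_diallel_magic",
        n_random_mating_cycles=config.n_random_mating_cycles,
        n_selfing_generations=config.n_selfing_generations,
        n_lines=config.n_rils,
    )
    rils = popsim.run_magic(panel, design, seed=rng)
    phenotypes = popsim.assign_phenotypes(
        rils, panel, penetrance=config.penetrance, seed=rng
    )
    n_sens = len(phenotypes.sensitive_ids())
    _stage("run_magic", rils=len(rils), sensitive=n_sens)

    # stage 3: observation ------------------------------------------------
    cov = observe.CoverageModel(
        {"parent": config.parent_depth, "RIL": config.ril_depth}, config.error_rate
    )
    founder_inds = [panel.founder_individual(i) for i in range(panel.n_founders)]
    classes = {ind.ind_id: "parent" for ind in founder_inds}
    classes.update({ind.ind_id: "RIL" for ind in rils})
    matrix = observe.observe_genotypes(
        founder_inds + rils, panel, cov, classes, seed=rng
    )
    matrix.seed = config.seed
    vcf_path = outdir / "magic_genotypes.vcf"
    matrix.to_vcf(vcf_path)
    pheno_path = outdir / "phenotypes.tsv"
    write_phenotypes(phenotypes, pheno_path)
    _stage("observe_genotypes", sites=matrix.n_sites, samples=matrix.n_samples)

    # stage 4: concordance filter -----------------------------------------
    if n_sens == 0:
        raise RuntimeError(
            "no sensitive RILs in this draw; rerun with another seed "
            "(the sensitive class is an emergent outcome of the breeding scheme)"
        )
    fconf = FilterConfig(
        mode=config.filter_mode,
        require_tolerant_exclusion=config.require_tolerant_exclusion,
    )
    candidates = concordance_filter(matrix, phenotypes, sensitive_parent, fconf)
    cand_path = outdir / "candidates.tsv"
    candidates.to_tsv(cand_path)
    candidates.to_bed(outdir / "candidates.bed")
    causal_in = (CAUSAL_CHROM, CAUSAL_POS) in candidates.positions()
    _stage("concordance_filter", candidates=len(candidates), causal_retained=causal_in)

    # stage 5: effect annotation ------------------------------------------
    gene = causal_gene_model()
    write_gff3([gene], outdir / "gene_models.gff3")
    causal_variant = Variant(
        CAUSAL_CHROM, CAUSAL_POS,
        panel.ref[panel.causal_site], panel.alt[panel.causal_site],
    )
    effect = classify_variant_effect(causal_variant, gene)
    effect_rows = ["chrom\tpos\tref\talt\tcategory\texon\tcodon"]
    for row in candidates.table.itertuples(index=False):
        eff = classify_variant_effect(Variant(row.chrom, row.pos, row.ref, row.alt), gene)
        effect_rows.append(
            f"{row.chrom}\t{row.pos}\t{row.ref}\t{row.alt}\t{eff.category}"
            f"\t{eff.exon_ordinal or ''}\t{eff.codon or ''}"
        )
    (outdir / "effects.tsv").write_text("\n".join(effect_rows) + "\n")
    _stage("annotate", causal_effect=effect.category)

    # stage 6: F2 segregation + marker concordance ------------------------
    f2 = popsim.run_f2(panel, panel.causal_founder, 1, config.n_f2, seed=rng)
    f2_pheno = popsim.assign_phenotypes(f2, panel, penetrance=config.penetrance, seed=rng)
    n_f2_sens = len(f2_pheno.sensitive_ids())
    seg = chi_square_segregation(
        (config.n_f2 - n_f2_sens, n_f2_sens), (3, 1)
    )
    # full-coverage genotypes: allele dosage codes coincide with call codes
    f2_calls = np.array(
        [ind.genotype_at(panel, panel.causal_site) for ind in f2], dtype=np.int8
    )
    report6 = marker_concordance(f2_calls, [ind.ind_id for ind in f2], f2_pheno)
    _stage(
        "segregation",
        tolerant=config.n_f2 - n_f2_sens,
        sensitive=n_f2_sens,
        chi_square=round(seg.statistic, 3),
        discordant=report6.n_discordant,
    )

    report = RunReport(
        config=config,
        n_sensitive_rils=n_sens,
        n_candidates=len(candidates),
        causal_in_candidates=causal_in,
        causal_effect=effect.category,
        causal_exon=effect.exon_ordinal,
        f2_counts={"tolerant": config.n_f2 - n_f2_sens, "sensitive": n_f2_sens},
        f2_chi_square=round(seg.statistic, 6),
        f2_verdict=seg.verdict,
        f2_discordant=report6.n_discordant,
        files={
            "vcf": str(vcf_path),
            "phenotypes": str(pheno_path),
            "candidates": str(cand_path),
        },
    )
    (outdir / "report.json").write_text(report.to_json())
    summary = (
        f"seed={config.seed} rils={config.n_rils} sensitive={n_sens} "
        f"candidates={len(candidates)} causal_retained={causal_in} "
        f"causal_effect={effect.category} f2_chi2={seg.statistic:.4f} ({seg.verdict}) "
        f"f2_discordant={report6.n_discordant}\n"
    )
    (outdir / "summary.txt").write_text(summary)
    return report
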