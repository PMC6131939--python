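"""Low-coverage genotype observation.

Per site and sample: depth ``d ~ Poisson(lambda)``; each read samples one of
the two true alleles and is flipped with error probability ``e``; the call
is missing at ``d = 0``, heterozygous when both alleles are observed, and
otherwise the homozygote of the single observed allele.  A naive caller on
purpose: robustness of the downstream filter to shallow-coverage miscalls is
the property under study, not the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from magicmap.genotypes import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix
from magicmap.popsim import FounderPanel, Individual


@dataclass
class CoverageModel:
    """Mean sequencing depth per sample class plus a per-read error rate."""

    depth_by_class: dict[str, float] = field(
        default_factory=lambda: {"parent": 20.0, "RIL": 3.0}
    )
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if any(lam < 0 for lam in self.depth_by_class.values()):
            raise ValueError("mean depth must be >= 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error rate must be in [0, 0.5)")

    def depth_for(self, cls: str) -> float:
        try:
            return self.depth_by_class[cls]
        except KeyError as exc:
            raise KeyError(f"no coverage set for sample class {cls!r}") from exc


def true_genotype_matrix(
    population: list[Individual],
    panel: FounderPanel,
    classes: dict[str, str] | str = "RIL",
) -> tuple[pd.DataFrame, list[str], np.ndarray, dict[str, str]]:
    """True allele-dosage matrix (n_sites, n_samples) plus site/sample metadata."""
    samples = [ind.ind_id for ind in population]
    if isinstance(classes, str):
        class_map = {s: classes for s in samples}
    else:
        class_map = dict(classes)
    geno = np.column_stack([ind.genotypes(panel) for ind in population])
    sites = pd.DataFrame(panel.genetic_map.site_table(), columns=["chrom", "pos"])
    sites["ref"] = panel.ref if panel.ref else "A"
    sites["alt"] = panel.alt if panel.alt else "T"
    return sites, samples, geno, class_map


def observe_genotypes(
    population: list[Individual],
    panel: FounderPanel,
    model: CoverageModel,
    classes: dict[str, str] | str = "RIL",
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Observe a population's genotypes under the Poisson coverage model."""
    rng = np.random.default_rng(seed)
    sites, samples, geno, class_map = true_genotype_matrix(population, panel, classes)

    lam = np.array([model.depth_for(class_map[s]) for s in samples])
    n_sites, n_samples = geno.shape
    depth = rng.poisson(np.broadcast_to(lam, (n_sites, n_samples)))

    # probability a read shows the alternate allele, by true genotype
    e = model.error_rate
    p_alt = np.array([e, 0.5, 1.0 - e])[geno]
    alt_reads = rng.binomial(depth, p_alt)

    calls = np.full(geno.shape, MISSING, dtype=np.int8)
    covered = depth > 0
    calls[covered & (alt_reads == 0)] = HOM_REF
    calls[covered & (alt_reads == depth)] = HOM_ALT
    calls[covered & (alt_reads > 0) & (alt_reads < depth)] = HET

    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return GenotypeMatrix(
        sites, samples, calls, depth.astype(np.int32), class_map,
        int(seed_val) if seed_val is not None else None,
    )
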