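"""Population simulation: founders, meiosis and the breeding schemes.

Individuals are diploid mosaics of founder segments.  Crossovers follow a
Poisson model with no interference (Haldane mapping), crossover positions
uniform on the genetic map.  The two schemes provided are the eleven-parent
half-diallel MAGIC design (random-mating cycles followed by single-seed
descent selfing) and a biparental F2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from magicmap.genmap import GeneticMap

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# founder panel
# ---------------------------------------------------------------------------


@dataclass
class FounderPanel:
    """Inbred founder haplotypes over the map's sites.

    ``alleles`` is (n_sites, n_founders) over {0, 1}; founders are fully
    inbred so one allele per founder suffices.  Exactly one founder carries
    the planted causal allele.
    """

    genetic_map: GeneticMap
    alleles: np.ndarray
    founder_ids: list[str]
    causal_site: int
    causal_founder: int
    ref: list[str] = field(default_factory=list)
    alt: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        n_sites, n_founders = self.alleles.shape
        if n_sites != self.genetic_map.n_sites:
            raise ValueError("allele matrix rows must match map sites")
        if n_founders != len(self.founder_ids):
            raise ValueError("allele matrix columns must match founder ids")
        if not set(np.unique(self.alleles)) <= {0, 1}:
            raise ValueError("alleles must be biallelic {0,1}")
        carriers = np.flatnonzero(self.alleles[self.causal_site] == 1)
        if carriers.tolist() != [self.causal_founder]:
            raise ValueError("causal allele must be carried by exactly the causal founder")

    @property
    def n_founders(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    def founder_individual(self, founder: int, ind_id: str | None = None) -> "Individual":
        """A fully inbred individual whose genome is one founder throughout."""
        h = Haplotype.uniform(self.genetic_map, founder)
        return Individual(ind_id or self.founder_ids[founder], h, h.copy())


def simulate_founders(
    n_founders: int,
    n_sites: int,
    genetic_map: GeneticMap,
    causal_chrom: str,
    causal_pos: int,
    causal_founder: int = 0,
    allele_freq: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> FounderPanel:
    """Draw a founder panel with one planted causal site.

    Non-causal alternate alleles are drawn per founder as independent
    Bernoulli(``allele_freq``); the causal alternate allele is fixed to the
    single causal founder.  Deterministic under ``seed``.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not 0 < allele_freq < 1:
        raise ValueError("allele_freq must be in (0,1)")
    if genetic_map.n_sites != n_sites:
        raise ValueError(
            f"map carries {genetic_map.n_sites} sites but n_sites={n_sites} requested"
        )
    try:
        causal_idx = genetic_map.site_index(causal_chrom, causal_pos)
    except KeyError as exc:
        raise ValueError(f"causal site {causal_chrom}:{causal_pos} not on map") from exc
    if not 0 <= causal_founder < n_founders:
        raise ValueError("causal founder index out of range")

    rng = np.random.default_rng(seed)
    alleles = (rng.random((n_sites, n_founders)) < allele_freq).astype(np.int8)
    alleles[causal_idx] = 0
    alleles[causal_idx, causal_founder] = 1

    # REF/ALT strings: SNVs everywhere except the causal site, which is a
    # 1-bp anchored insertion (ref "T", alt "TA": an extra adenine).
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    ref = _BASES[ref_idx].tolist()
    alt = _BASES[alt_idx].tolist()
    ref[causal_idx] = "T"
    alt[causal_idx] = "TA"

    founder_ids = [f"P{i + 1:02d}" for i in range(n_founders)]
    return FounderPanel(genetic_map, alleles, founder_ids, causal_idx, causal_founder, ref, alt)


# ---------------------------------------------------------------------------
# haplotypes and individuals
# ---------------------------------------------------------------------------


class Haplotype:
    """One gamete: founder-of-origin segments tiling every chromosome.

    Per chromosome the segments are stored as sorted inclusive segment end
    coordinates plus founder origins; segment *i* covers
    ``(ends[i-1], ends[i]]`` with ``ends[-1] == chromosome length``.
    """

    __slots__ = ("genetic_map", "segments")

    def __init__(self, genetic_map: GeneticMap, segments: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.genetic_map = genetic_map
        self.segments = segments

    @classmethod
    def uniform(cls, genetic_map: GeneticMap, founder: int) -> "Haplotype":
        segs = {
            c.name: (
                np.array([c.length_bp], dtype=np.float64),
                np.array([founder], dtype=np.int32),
            )
            for c in genetic_map.chromosomes
        }
        return cls(genetic_map, segs)

    def copy(self) -> "Haplotype":
        return Haplotype(
            self.genetic_map,
            {c: (e.copy(), o.copy()) for c, (e, o) in self.segments.items()},
        )

    def origin_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Founder-of-origin for (sorted or unsorted) physical positions."""
        ends, origins = self.segments[chrom]
        idx = np.searchsorted(ends, np.asarray(positions, dtype=np.float64), side="left")
        return origins[idx]

    def site_origins(self) -> np.ndarray:
        """Founder-of-origin at every map site, in global site order."""
        parts = [
            self.origin_at(c.name, self.genetic_map.sites[c.name])
            for c in self.genetic_map.chromosomes
        ]
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int32)

    def alleles(self, panel: FounderPanel) -> np.ndarray:
        origins = self.site_origins()
        return panel.alleles[np.arange(panel.n_sites), origins]

    def validate(self) -> None:
        for c in self.genetic_map.chromosomes:
            ends, origins = self.segments[c.name]
            if len(ends) != len(origins) or len(ends) == 0:
                raise AssertionError(f"malformed segments on {c.name}")
            if ends[-1] != c.length_bp:
                raise AssertionError(f"segments do not tile chromosome {c.name}")
            if np.any(np.diff(ends) <= 0):
                raise AssertionError(f"segment ends not increasing on {c.name}")


@dataclass
class Individual:
    """A diploid individual: two haplotypes over the same map."""

    ind_id: str
    hap1: Haplotype
    hap2: Haplotype

    def genotypes(self, panel: FounderPanel) -> np.ndarray:
        """Allele-dosage genotype (0/1/2 copies of the alternate) per site."""
        return (self.hap1.alleles(panel) + self.hap2.alleles(panel)).astype(np.int8)

    def genotype_at(self, panel: FounderPanel, site: int) -> int:
        chrom, pos = panel.genetic_map.site_at(site)
        a1 = panel.alleles[site, int(self.hap1.origin_at(chrom, np.array([pos]))[0])]
        a2 = panel.alleles[site, int(self.hap2.origin_at(chrom, np.array([pos]))[0])]
        return int(a1 + a2)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def _splice(
    hap_a: Haplotype, hap_b: Haplotype, chrom_name: str, chrom_len: int,
    breaks: np.ndarray, start: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Merge two parental haplotypes along one chromosome.

    ``breaks`` are sorted crossover positions; the gamete copies ``hap_a``
    (start=0) or ``hap_b`` (start=1) first and switches at each break.
    """
    haps = (hap_a, hap_b)
    out_ends: list[float] = []
    out_orig: list[int] = []
    cur = start
    lo = 0.0
    for hi in list(breaks) + [float(chrom_len)]:
        if hi <= lo:
            cur ^= 1
            continue
        ends, origins = haps[cur].segments[chrom_name]
        j = int(np.searchsorted(ends, lo, side="right"))
        while j < len(ends) and ends[j] < hi:
            out_ends.append(float(ends[j]))
            out_orig.append(int(origins[j]))
            j += 1
        out_ends.append(float(hi))
        out_orig.append(int(origins[min(j, len(origins) - 1)]))
        lo = hi
        cur ^= 1
    # merge adjacent segments with identical origin
    ends_arr = np.array(out_ends)
    orig_arr = np.array(out_orig, dtype=np.int32)
    keep = np.ones(len(ends_arr), dtype=bool)
    keep[:-1] = orig_arr[:-1] != orig_arr[1:]
    return ends_arr[keep], orig_arr[keep]


def meiosis(parent: Individual, genetic_map: GeneticMap, rng: np.random.Generator) -> Haplotype:
    """One gamete from ``parent``.

    Crossover count per chromosome is Poisson with mean equal to the
    genetic length in Morgans; positions are uniform on the genetic map; no
    interference.  Equivalent to Haldane's map function between any two loci.
    """
    if not genetic_map.chromosomes:
        raise ValueError("empty genetic map")
    segments: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in genetic_map.chromosomes:
        n_xo = int(rng.poisson(c.length_cm / 100.0))
        if n_xo:
            cm = np.sort(rng.uniform(0.0, c.length_cm, size=n_xo))
            breaks = np.asarray(genetic_map.physical_pos(c.name, cm), dtype=np.float64)
        else:
            breaks = np.empty(0)
        start = int(rng.integers(2))
        segments[c.name] = _splice(parent.hap1, parent.hap2, c.name, c.length_bp, breaks, start)
    return Haplotype(genetic_map, segments)


def cross(
    mother: Individual, father: Individual, genetic_map: GeneticMap,
    rng: np.random.Generator, ind_id: str,
) -> Individual:
    return Individual(ind_id, meiosis(mother, genetic_map, rng), meiosis(father, genetic_map, rng))


def self_pollinate(
    parent: Individual, genetic_map: GeneticMap, rng: np.random.Generator, ind_id: str
) -> Individual:
    return Individual(ind_id, meiosis(parent, genetic_map, rng), meiosis(parent, genetic_map, rng))


# ---------------------------------------------------------------------------
# breeding designs
# ---------------------------------------------------------------------------


@dataclass
class BreedingDesign:
    """Parameters of a breeding scheme."""

    scheme: str = "half_diallel_magic"  # or "biparental_f2"
    n_random_mating_cycles: int = 5
    n_selfing_generations: int = 6
    n_lines: int = 550
    cycle_pop_size: int | None = None  # defaults to n_lines

    def __post_init__(self) -> None:
        if self.scheme not in ("half_diallel_magic", "biparental_f2"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if min(self.n_random_mating_cycles, self.n_selfing_generations, self.n_lines) < 0:
            raise ValueError("design counts must be non-negative")


def half_diallel(panel: FounderPanel) -> list[Individual]:
    """One F1 per unordered founder pair: no selfs, no reciprocals.

    Founders are inbred, so each F1 is simply (founder-i haplotype,
    founder-j haplotype).  n founders yield n(n-1)/2 families.
    """
    n = panel.n_founders
    if n < 2:
        raise ValueError("half-diallel requires at least 2 founders")
    families = []
    for i in range(n):
        for j in range(i + 1, n):
            families.append(
                Individual(
                    f"F1_{panel.founder_ids[i]}x{panel.founder_ids[j]}",
                    Haplotype.uniform(panel.genetic_map, i),
                    Haplotype.uniform(panel.genetic_map, j),
                )
            )
    return families


def run_magic(
    panel: FounderPanel,
    design: BreedingDesign,
    seed: int | np.random.Generator = 0,
    return_stages: bool = False,
):
    """Half-diallel F1s, random-mating cycles with bulked pollen, then SSD.

    Each random-mating cycle draws the seed parent from the current
    population and the pollen parent uniformly from the bulked pool over the
    whole population (so selfing occurs at rate 1/N).  Selfing proceeds by
    single-seed descent: one selfed offspring per line per generation.
    """
    if design.scheme != "half_diallel_magic":
        raise ValueError("run_magic requires scheme 'half_diallel_magic'")
    rng = np.random.default_rng(seed)
    gmap = panel.genetic_map

    pop = half_diallel(panel)
    n_target = design.cycle_pop_size or design.n_lines
    for cycle in range(1, design.n_random_mating_cycles + 1):
        mothers = rng.integers(len(pop), size=n_target)
        fathers = rng.integers(len(pop), size=n_target)  # bulked pollen, uniform
        pop = [
            cross(pop[m], pop[f], gmap, rng, f"C{cycle}_{k + 1:04d}")
            for k, (m, f) in enumerate(zip(mothers, fathers))
        ]

    if len(pop) >= design.n_lines:
        idx = rng.choice(len(pop), size=design.n_lines, replace=False)
    else:
        idx = rng.choice(len(pop), size=design.n_lines, replace=True)
    lines = [pop[i] for i in idx]
    pre_selfing = lines

    for g in range(1, design.n_selfing_generations + 1):
        lines = [
            self_pollinate(ind, gmap, rng, f"RIL{k + 1:04d}")
            for k, ind in enumerate(lines)
        ]
    rils = [
        Individual(f"RIL{k + 1:04d}", ind.hap1, ind.hap2) for k, ind in enumerate(lines)
    ]
    if return_stages:
        return {"pre_selfing": pre_selfing, "rils": rils}
    return rils


def run_f2(
    panel: FounderPanel,
    founder_a: int,
    founder_b: int,
    n: int,
    seed: int | np.random.Generator = 0,
) -> list[Individual]:
    """Biparental F2: self the (a x b) F1 ``n`` times."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if panel.alleles[panel.causal_site, founder_a] == panel.alleles[panel.causal_site, founder_b]:
        warnings.warn(
            "founders identical at the causal site: no segregation expected",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    gmap = panel.genetic_map
    f1 = Individual(
        "F1",
        Haplotype.uniform(gmap, founder_a),
        Haplotype.uniform(gmap, founder_b),
    )
    return [self_pollinate(f1, gmap, rng, f"F2_{k + 1:05d}") for k in range(n)]


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

TOLERANT = "tolerant"
SENSITIVE = "sensitive"


@dataclass
class PhenotypeTable:
    """Sample id -> {tolerant, sensitive} with the penetrance used."""

    labels: dict[str, str]
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {TOLERANT, SENSITIVE}
        if bad:
            raise ValueError(f"invalid phenotype labels: {bad}")

    def sensitive_ids(self) -> list[str]:
        return [s for s, l in self.labels.items() if l == SENSITIVE]

    def tolerant_ids(self) -> list[str]:
        return [s for s, l in self.labels.items() if l == TOLERANT]


def assign_phenotypes(
    population: list[Individual],
    panel: FounderPanel,
    model: str = "recessive_sensitive",
    penetrance: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> PhenotypeTable:
    """Sensitive iff homozygous for the causal allele (with penetrance)."""
    if model != "recessive_sensitive":
        raise ValueError(f"unknown phenotype model {model!r}")
    if not 0.0 <= penetrance <= 1.0:
        raise ValueError("penetrance must be in [0,1]")
    rng = np.random.default_rng(seed)
    labels = {}
    for ind in population:
        g = ind.genotype_at(panel, panel.causal_site)
        sensitive = g == 2 and (penetrance >= 1.0 or rng.random() < penetrance)
        labels[ind.ind_id] = SENSITIVE if sensitive else TOLERANT
    return PhenotypeTable(labels, penetrance)
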