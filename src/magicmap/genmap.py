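"""Genetic map: chromosomes with physical and genetic lengths plus marker sites.

The default map is a single 60 Mb / 100 cM chromosome named "D10" with
uniform recombination, which matches the scale of a cotton chromosome
without claiming any real map data.  Genetic positions are linearly
interpolated between the chromosome ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Fixture coordinates used throughout the test-bed scenario.
CAUSAL_CHROM = "D10"
CAUSAL_POS = 28_455_988
HOMEOLOG_CHROM = "A10"
HOMEOLOG_POS = 54_681_293

DEFAULT_CHROM_LENGTH_BP = 60_000_000
DEFAULT_CHROM_LENGTH_CM = 100.0


@dataclass(frozen=True)
class Chromosome:
    """A chromosome with a physical length (bp) and a genetic length (cM)."""

    name: str
    length_bp: int
    length_cm: float

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"chromosome {self.name}: length_bp must be >= 1")
        if self.length_cm < 0:
            raise ValueError(f"chromosome {self.name}: length_cm must be >= 0")


@dataclass
class GeneticMap:
    """Chromosomes plus per-chromosome sorted marker (site) positions.

    Site positions are 1-based physical coordinates.  Genetic positions are
    obtained by linear interpolation (uniform recombination along each
    chromosome), so they are non-decreasing in physical position by
    construction.
    """

    chromosomes: list[Chromosome]
    sites: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("map must contain at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, pos in self.sites.items():
            pos = np.asarray(pos, dtype=np.int64)
            chrom = self.chromosome(name)
            if pos.size and (pos.min() < 1 or pos.max() > chrom.length_bp):
                raise ValueError(f"site positions outside chromosome {name}")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"site positions not strictly increasing on {name}")
            self.sites[name] = pos
        for c in self.chromosomes:
            self.sites.setdefault(c.name, np.empty(0, dtype=np.int64))

    # -- chromosome lookup ------------------------------------------------

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    # -- site indexing ----------------------------------------------------

    @property
    def n_sites(self) -> int:
        return int(sum(len(self.sites[c.name]) for c in self.chromosomes))

    def site_table(self) -> list[tuple[str, int]]:
        """All sites as (chrom, pos) in map order."""
        out: list[tuple[str, int]] = []
        for c in self.chromosomes:
            out.extend((c.name, int(p)) for p in self.sites[c.name])
        return out

    def site_at(self, index: int) -> tuple[str, int]:
        """(chrom, pos) of the site with the given global index."""
        if index < 0:
            raise IndexError(index)
        offset = index
        for c in self.chromosomes:
            positions = self.sites[c.name]
            if offset < len(positions):
                return c.name, int(positions[offset])
            offset -= len(positions)
        raise IndexError(index)

    def site_index(self, chrom: str, pos: int) -> int:
        """Global index (over the concatenated site list) of a site."""
        offset = 0
        for c in self.chromosomes:
            positions = self.sites[c.name]
            if c.name == chrom:
                i = int(np.searchsorted(positions, pos))
                if i >= len(positions) or positions[i] != pos:
                    raise KeyError(f"no site at {chrom}:{pos}")
                return offset + i
            offset += len(positions)
        raise KeyError(f"unknown chromosome {chrom!r}")

    # -- genetic <-> physical ---------------------------------------------

    def genetic_pos(self, chrom: str, pos) -> np.ndarray:
        """Genetic position(s) in cM by linear interpolation."""
        c = self.chromosome(chrom)
        return np.asarray(pos, dtype=float) / c.length_bp * c.length_cm

    def physical_pos(self, chrom: str, cm) -> np.ndarray:
        """Inverse of :meth:`genetic_pos` (float bp coordinates)."""
        c = self.chromosome(chrom)
        if c.length_cm == 0:
            raise ValueError(f"chromosome {chrom} has zero genetic length")
        return np.asarray(cm, dtype=float) / c.length_cm * c.length_bp

    # -- constructors -----------------------------------------------------

    @classmethod
    def default(cls, n_sites: int = 0, *, include_causal_site: bool = True) -> "GeneticMap":
        """Single-chromosome default map with evenly spaced sites.

        When ``include_causal_site`` is set, the fixture coordinate
        D10:28,455,988 replaces the nearest evenly spaced site so the causal
        position is always representable.
        """
        chrom = Chromosome(CAUSAL_CHROM, DEFAULT_CHROM_LENGTH_BP, DEFAULT_CHROM_LENGTH_CM)
        if n_sites <= 0:
            return cls([chrom])
        step = chrom.length_bp / (n_sites + 1)
        positions = np.round(np.arange(1, n_sites + 1) * step).astype(np.int64)
        if include_causal_site:
            nearest = int(np.argmin(np.abs(positions - CAUSAL_POS)))
            positions[nearest] = CAUSAL_POS
        positions = np.unique(positions)
        return cls([chrom], {chrom.name: positions})
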