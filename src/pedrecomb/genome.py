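"""Genome layout: chromosome sizes, Z/PAR geometry, SNP density.

Coordinates are 0-based half-open internally; VCF positions (1-based)
are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    is_z: bool = False
    par: tuple[int, int] | None = None  # 0-based half-open, Z only

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r} has non-positive length")
        if self.par is not None:
            if not self.is_z:
                raise ValueError("PAR interval only allowed on the Z chromosome")
            lo, hi = self.par
            if not (0 <= lo < hi <= self.length):
                raise ValueError(f"PAR {self.par} outside chromosome {self.name!r}")

    def in_par(self, pos0: int) -> bool:
        """Whether a 0-based position lies in the pseudoautosomal region."""
        return self.par is not None and self.par[0] <= pos0 < self.par[1]


@dataclass
class GenomeLayout:
    """Chromosome set plus expected heterozygous-site density per bp."""

    chromosomes: list[Chromosome]
    snp_density: float = 1e-4

    def __post_init__(self) -> None:
        if self.snp_density < 0:
            raise ValueError("snp_density must be non-negative")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")

    def __iter__(self):
        return iter(self.chromosomes)

    def get(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def autosomes(self) -> list[Chromosome]:
        return [c for c in self.chromosomes if not c.is_z]

    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)


def default_layout(snp_density: float = 1e-4) -> GenomeLayout:
    """Desk-scale genome: two autosomes and a Z with a 0.6 Mb PAR.

    Small enough that a full pedigree simulation plus event detection
    runs in seconds, while still exercising Z/PAR inheritance.
    """
    return GenomeLayout(
        chromosomes=[
            Chromosome("chr1", 20_000_000),
            Chromosome("chr2", 8_000_000),
            Chromosome("chrZ", 15_000_000, is_z=True, par=(0, 600_000)),
        ],
        snp_density=snp_density,
    )
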