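"""Genome layout for the maternal (*C. nouraguensis*) reference.

The maternal genome carries two haplotypes, NIC59 (``N``) and JU1825
(``J``), distinguishable at fixed SNP differences spaced a few hundred
base pairs apart.  The paternal genome comes from a second species,
*C. becei* (``B``), and maps to its own assembly.  Six holocentric
chromosomes: five autosomes plus the X.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


#: Maternal haplotype labels and the paternal-species label.
ORIGIN_N = "N"  # NIC59 maternal haplotype
ORIGIN_J = "J"  # JU1825 maternal haplotype
ORIGIN_B = "B"  # C. becei paternal origin


@dataclass(frozen=True)
class ChromosomeSpec:
    id: str
    length: int  # bp
    is_X: bool = False


@dataclass
class GenomeSpec:
    """Chromosome layout plus crossover- and marker-placement parameters.

    Parameters
    ----------
    chromosomes
        Five autosomes plus one X by default; lengths in bp.
    arm_fraction
        Fraction of each chromosome end treated as an "arm" (0, 0.5].
        Crossovers fall predominantly on arms in *Caenorhabditis*.
    p_center_crossover
        Probability that the single obligate crossover falls in the
        center (outside the two arms).
    snp_spacing
        Mean spacing in bp between informative fixed-difference SNPs.
    window_size
        Genotyping window in bp (50 kb).
    """

    chromosomes: list[ChromosomeSpec] = field(default_factory=lambda: _default_chromosomes())
    arm_fraction: float = 0.3
    p_center_crossover: float = 0.1
    snp_spacing: float = 217.0
    window_size: int = 50_000

    def __post_init__(self) -> None:
        if not 0.0 < self.arm_fraction <= 0.5:
            raise ValueError("arm_fraction must be in (0, 0.5]")
        if not 0.0 <= self.p_center_crossover <= 1.0:
            raise ValueError("p_center_crossover must be in [0, 1]")
        if self.snp_spacing <= 0 or self.window_size <= 0:
            raise ValueError("snp_spacing and window_size must be positive")
        if any(c.length <= 0 for c in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if sum(c.is_X for c in self.chromosomes) > 1:
            raise ValueError("at most one X chromosome")

    @property
    def n_autosomes(self) -> int:
        return sum(not c.is_X for c in self.chromosomes)

    @property
    def autosome_ids(self) -> list[str]:
        return [c.id for c in self.chromosomes if not c.is_X]

    @property
    def x_id(self) -> str | None:
        for c in self.chromosomes:
            if c.is_X:
                return c.id
        return None

    def chromosome(self, chrom: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.id == chrom:
                return c
        raise KeyError(f"unknown chromosome id: {chrom!r}")

    def length(self, chrom: str) -> int:
        return self.chromosome(chrom).length

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeSpec":
        d = dict(d)
        d["chromosomes"] = [ChromosomeSpec(**c) for c in d["chromosomes"]]
        return cls(**d)


def _default_chromosomes() -> list[ChromosomeSpec]:
    # Caenorhabditis-typical chromosome lengths (Mb scale).
    return [
        ChromosomeSpec("I", 15_000_000),
        ChromosomeSpec("II", 15_300_000),
        ChromosomeSpec("III", 13_800_000),
        ChromosomeSpec("IV", 17_500_000),
        ChromosomeSpec("V", 20_900_000),
        ChromosomeSpec("X", 17_700_000, is_X=True),
    ]


def default_genome() -> GenomeSpec:
    """The study-scale genome: five autosomes plus the X."""
    return GenomeSpec()


def scaled_genome(length: int = 8_000_000, n_autosomes: int = 5,
                  window_size: int = 50_000, snp_spacing: float = 217.0,
                  **kwargs) -> GenomeSpec:
    """A uniform-length genome for simulation studies at reduced scale."""
    chroms = [ChromosomeSpec(f"chr{i + 1}", length) for i in range(n_autosomes)]
    chroms.append(ChromosomeSpec("chrX", length, is_X=True))
    return GenomeSpec(chromosomes=chroms, window_size=window_size,
                      snp_spacing=snp_spacing, **kwargs)
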