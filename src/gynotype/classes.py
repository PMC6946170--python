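"""Chromosome genotype classes shared by the truth oracle and the data-driven classifier."""

from __future__ import annotations

from enum import Enum


class ChromosomeGenotype(str, Enum):
    """Chromatid-combination classes distinguishable from single-worm genotyping.

    A bivalent with one crossover yields six unordered chromatid pairs.
    Four produce unique genome-wide zygosity signatures (SISTERS_1,
    SISTERS_2, HOMOLOGS_1, HOMOLOGS_2); two collapse into the fully
    heterozygous HOMOLOGS_3 signature.  FULL_HOM_* covers genome-wide
    homozygosity (endoreplication, or two identical non-recombinant
    chromatids).  The remaining labels are data-driven auxiliary calls.
    """

    SISTERS_1 = "Sisters_1"            # homozygous-N body, heterozygous terminal arm
    SISTERS_2 = "Sisters_2"            # homozygous-J body, heterozygous terminal arm
    HOMOLOGS_1 = "Homologs_1"          # heterozygous body, homozygous-N terminal arm
    HOMOLOGS_2 = "Homologs_2"          # heterozygous body, homozygous-J terminal arm
    HOMOLOGS_3 = "Homologs_3"          # heterozygous across the entire chromosome
    FULL_HOM_N = "Full_hom_N"          # homozygous NIC59 everywhere
    FULL_HOM_J = "Full_hom_J"          # homozygous JU1825 everywhere
    HOMOLOGS_AMBIGUOUS = "Homologs_ambiguous"
    HEMIZYGOUS_X = "Hemizygous_X"
    TRIPLOID = "Triploid"
    AMBIGUOUS = "Ambiguous"


#: The five classes tallied against inheritance models, in canonical order.
DISTINGUISHABLE_CLASSES: tuple[ChromosomeGenotype, ...] = (
    ChromosomeGenotype.SISTERS_1,
    ChromosomeGenotype.SISTERS_2,
    ChromosomeGenotype.HOMOLOGS_1,
    ChromosomeGenotype.HOMOLOGS_2,
    ChromosomeGenotype.HOMOLOGS_3,
)
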