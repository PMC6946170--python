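# gynotype

Inheritance inference for an asexual (gynogenetic) *Caenorhabditis*
lineage: *C. nouraguensis* females crossed to *C. becei* males produce
rare fertile F1 that inherit a **diploid maternal genome and no
paternal DNA**. This package implements the genomic analysis that
establishes how such eggs arise — a modified female meiosis in which
two homologous chromatids are retained ("central-fusion" automixis) —
and how the paternal genome is lost, retained whole (triploid hybrids),
or retained in a subset of cells (diploid–triploid mosaics).

It is an analysis project: the computation lives in the package under
`src/gynotype/`, the numbered drivers under `analysis/` reproduce the
study's simulated analyses, and everything is exercised by the test
suite.

## The model

Each of the six holocentric chromosomes forms a bivalent with **one
obligate crossover biased towards a chromosome end** (arms = terminal
30% per end; center crossovers with probability 0.1). The four
chromatids are N1, N2 (NIC59 haplotype) and J1, J2 (JU1825 haplotype),
with N2/J1 the reciprocal recombinants; the dyad (co-segregating pair)
shares its haplotype along the long side of the crossover. An
inheritance mode decides what the oocyte keeps:

| mode | retained | polar bodies |
|---|---|---|
| canonical | 1 random chromatid | 2 |
| central fusion | 2 chromatids from *different* dyads | 1 (shared MII spindle, p = 0.5) or 2 |
| sister fusion | 1 whole dyad | 1 |
| apomixis | clone of mother (no recombination) | 0 |
| endoreplication | 1 chromatid duplicated | 2 |
| random two | any pair of the four | 1 or 2 |

A retained pair shows one of five distinguishable zygosity signatures:
`Sisters_1/2` (homozygous body, heterozygous terminal arm),
`Homologs_1/2` (heterozygous body, homozygous terminal arm), or
`Homologs_3` (heterozygous throughout). Enumerating the six pairs of a
bivalent gives the model frequencies

- any two chromatids: (1/6, 1/6, 1/6, 1/6, 1/3)
- homologous chromatids only: (0, 0, 1/4, 1/4, 1/2)
- sister chromatids only: (1/2, 1/2, 0, 0, 0)

Genotyping mirrors the study's computation: NIC59 allele frequency =
pooled NIC59 reads / total reads in 50-kb windows; change points by
circular binary segmentation (mean-shift arc statistic, permutation
p < 0.01, segments ≥ 3 windows); segment states HET ∈ [0.35, 0.65],
HOM ≥ 0.85 / ≤ 0.15 after contamination correction. Coverage against
both assemblies, normalized so maternal chromosome I ≡ 2 copies, yields
copy number, paternal cell fraction (mosaicism) and X content. Observed
class counts are tested against the model vectors with an exact
multinomial goodness-of-fit (probability ordering; Monte Carlo beyond
n = 60).

## Worked example

```sh
python analysis/01_simulate_cross.py
python analysis/02_genotype_cohort.py
python analysis/03_test_inheritance_models.py
python analysis/04_cytology_and_embryo_predictions.py
```

simulates 24 fertilizations under central-fusion automixis with a mix
of paternal fates (60% eliminated / 20% retained / 20% mosaic at 30×
whole-genome-amplified depth), genotypes them, and tests the class
counts. Output from a run:

```
zygote fates: {'fertile_viable': 15, 'sterile_viable': 4, 'dead': 5}
category: maternal_only 15, triploid_hybrid 5, mosaic_hybrid 4
observed autosome class counts ([Sisters_1, Sisters_2, Homologs_1,
  Homologs_2, Homologs_3]): [0, 0, 22, 29, 69] (n = 120)
  homolog_only   p = 0.1778 -> retained
  random_two     p = 1e-05  -> rejected
  sister_only    p = 0      -> rejected
  apomixis       p = 0      -> rejected
```

Fertile progeny are exactly the maternal-only diploids; no Sisters
classes appear, so only the homolog-only (central fusion) model
survives. The cytology driver prints the matching oocyte predictions:
6 DAPI-staining bodies for diploids vs 12 for triploids, one polar
body in half the oocytes, and a paternal-X inheritance fraction of
0.50 from XO fathers.

The same commands are available as a CLI (`gynotype simulate`,
`gynotype genotype`, `gynotype infer`) for running the pipeline on
externally supplied allele-depth (TSV/VCF-with-AD) and coverage (BED4)
tables.

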