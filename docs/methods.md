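# Methods

## The biological model

*C. nouraguensis* females (heterozygous for the NIC59 and JU1825
haplotypes, labelled N and J) are crossed to *C. becei* males (origin
B). Reproduction is gynogenetic: sperm is required to activate the egg
but its genome is usually eliminated. The package models the oocyte as
six independent bivalents (five autosomes + X). Each bivalent receives
exactly one crossover; no crossover interference or gene conversion is
modelled because only one exchange per homolog set occurs. Coordinates
are 0-based half-open, crossover positions integral.

**Crossover placement.** A two-component mixture: with probability
`1 - p_center_crossover` the position is uniform over the two arms
(each the terminal `arm_fraction` of the chromosome), otherwise uniform
over the center. Defaults `arm_fraction = 0.3`, `p_center_crossover =
0.1`: *Caenorhabditis* recombination is predominantly distal but not
absent from centers, and no quantitative map exists for this species
pair; both parameters are configurable.

**Dyads.** After the crossover, the two chromatids sharing a haplotype
along the *long* side of the crossover co-segregate at anaphase I.
This mirrors holocentric meiosis, where cohesion is retained on the
long arm, and reproduces the diagnostic sister signature: homozygosity
through the chromosome center with heterozygosity beyond the crossover
on one arm.

**Inheritance modes.** Canonical meiosis keeps one chromatid (two
polar bodies). Central-fusion automixis keeps two chromatids from
different dyads — uniformly one of the four such pairs — and expels
one polar body when the two half-bivalents share a meiosis-II spindle
(probability `p_shared_spindle`, default 0.5, matching the roughly
half-and-half polar-body counts seen in hybrid embryos) and two
otherwise. Sister fusion keeps one dyad (meiosis II fails: one polar
body). Apomixis clones the mother (no meiotic division: zero polar
bodies; represented as fresh non-recombinant N and J chromatids).
Endoreplication duplicates one random chromatid. `random_two` keeps
any of the six pairs and models unconstrained retention. Whether the
two half-bivalents segregate dependently after MI failure is unknown;
chromosomes are treated independently.

Two modelling conventions are ours: `Homologs_1` is the
heterozygous-body class with a homozygous-*NIC59* terminal segment
(`Homologs_2` the JU1825 analogue) — the labels are arbitrary up to
haplotype swap; and genome-wide homozygosity for a single haplotype is
reported as `Full_hom_N`/`Full_hom_J` (it arises from endoreplication,
or from two identical non-recombinant chromatids, and also covers the
"two non-recombinant JU1825 chromatids" reading of a fully homozygous
chromosome, which a single obligate-crossover bivalent cannot produce
as a sister pair). A duplicated *recombinant* chromatid is homozygous
everywhere but switches haplotype at the crossover; it matches no
single-crossover pair signature and is classified `Ambiguous`.

**Paternal fate and viability.** Sperm from XO fathers carries the X
with probability 0.5. The paternal complement is retained fully, not
at all (including after UV inactivation), in a fraction `f` of cells
(mosaic), or per-chromosome at random (partial). Fate rules: any
paternal X is lethal; an incomplete paternal set is lethal aneuploidy;
a haploid or autosomally aneuploid maternal complement is lethal; a
maternal-diploid egg is fertile when no paternal DNA persists and a
viable but sterile triploid/mosaic hybrid when the complete paternal
autosome set persists. X missegregation is a single probability
`p_X_loss` (default 0) producing XO males; no rate model is attempted.

**Cytology.** With one obligate crossover per homolog set, two
homologs per chromosome type form a bivalent and every additional
homolog remains a univalent: DAPI-staining bodies = `n` types at
ploidy 2 and `2n` at ploidy 3 (univalents add one body each).

## Sequencing observables

The pipeline starts downstream of alignment; no reads are simulated.
At SNPs placed with exponential spacing (mean 217 bp, the density of
high-quality fixed differences between the parental strains), the true
NIC59 fraction is the fraction of maternal copies carrying N.
Contamination from backcross sperm carryover shifts it to
`(1-c)·f + c·f_cont`; a symmetric per-read error rate (default 0.001)
flips alleles. Total depth is Poisson(`mean_depth`, default 30);
NIC59 counts are beta-binomial with intra-class correlation `rho`
(default 0.05) standing in for whole-genome-amplification jackpotting —
no noise measurements exist for this protocol, so `rho` is a package
choice validated by the end-to-end recovery properties. Window
coverage is proportional to copies per cell (maternal copies against
the *nouraguensis* assembly; `mosaic_fraction ×` paternal copies
against the *becei* assembly) with gamma multiplicative noise of the
same dispersion, plus a 0.15% cross-mapping floor on the *becei* side
(the observed 0.1–0.2% range).

## Genotyping

Window frequency is the pooled-count ratio (total N reads / total
reads per 50-kb window), not a mean of per-SNP frequencies; empty
windows are flagged missing, excluded from segmentation, and absorbed
into the enclosing segment. Contamination is estimated by locating
the heterozygous mode m of the window-frequency distribution (Gaussian
KDE on [0.2, 0.8], 601-point grid) and inverting the mixture,
`c = (0.5 - m)/(0.5 - f_cont)`, clipped to [0, 0.5).

**CBS.** For each region the best arc (i, j] maximizes the squared
mean-shift contrast `(S_j - S_i - k/n·S_n)² / (k(n-k))` — a monotone
transform of the two-sample t statistic at fixed variance, so the
permutation null calibrates it exactly. The split is accepted when the
permutation p-value (1000 permutations, curtailed early only when the
accept/reject decision is already determined) is below `alpha = 0.01`,
then recursion proceeds on the pieces; every segment keeps at least
`min_width = 3` windows; adjacent segments with means closer than
`merge_tol = 0.1` are merged. Ties in the arc search break to the
first (i, j) in scan order, making seeded runs bit-reproducible. The
reference algorithm's software defaults are not published for this
analysis, so these parameters are ours, validated by the recovery
properties. The O(n²)-per-permutation kernel is numba-compiled with a
numpy fallback.

**State bands.** After contamination correction, segment means map to
HET in [0.35, 0.65], HOM_N ≥ 0.85, HOM_J ≤ 0.15, else AMBIG — our
calibration of "approximately 0.5 / 1.0 / 0.0", configurable and
validated end-to-end.

## Karyotyping

The chromosome's collapsed state runs are matched to class signatures.
The body is the run containing the chromosome midpoint and the
terminal run is the end-touching remainder. A hard terminal-fraction
cutoff would misclassify the ~10% of chromosomes with center
crossovers whose "terminal" region approaches half the chromosome, and
would break the required equivalence with the chromatid-pair oracle,
so the midpoint rule is used instead. A terminal homozygous run
shorter than 2 windows is treated as amplification noise. Copy number
uses 10%-trimmed per-chromosome mean coverage (robust to WGA
jackpots), scaled so maternal chromosome I equals 2; maternal calls
round to {0..3}, paternal normalized coverage directly estimates the
mosaic cell fraction (flagged mosaic in (0.1, 0.9)). Individuals are
maternal-only when the *becei* read fraction is ≤ 1% (an order of
magnitude above the cross-mapping floor) and no paternal chromosome is
called; triploid vs mosaic hybrids split on the paternal cell
fraction.

## Inference

Model class probabilities are always derived by enumerating the
chromatid pairs the mode can retain — never hard-coded. The published
comparison of observed to expected class frequencies is
operationalized as an exact multinomial goodness-of-fit with
probability ordering (expected frequencies are model probabilities,
not a second observed margin, so a contingency-table test is not the
natural construction; p-values on real counts may therefore differ
from the originally printed ones, which are not reproduced here).
Exhaustive enumeration is used for n ≤ 60 (k = 5), seeded Monte Carlo
with 100,000 tables beyond; a populated zero-probability class forces
p = 0. Ambiguous, hemizygous-X and triploid chromosomes are excluded
from tallies. Maternal triploids are detected by copy number but not
decomposed into chromatid combinations (their dosage frequencies near
1/3 and 2/3 are reported descriptively only).

## Synthetic data: what it does and does not emulate

The generator reproduces the study's structure — two maternal
haplotypes at fixed differences every ~217 bp, six chromosomes, one
end-biased crossover per bivalent, WGA-like overdispersion, optional
backcross contamination, paternal reads mapping to a separate assembly
with a cross-mapping floor. It does not emulate reference bias,
mapping artefacts beyond that floor, scaffold fragmentation, copy
number variation, or locus-specific amplification failure; passing
tests show the pipeline's correctness under the modelled noise, not
robustness to every artefact of real single-worm libraries.

## Problem sizes and numerical choices

Simulation studies use six 8-Mb chromosomes (160 windows each) rather
than full-length (13–21 Mb) chromosomes: terminal-segment resolution
scales with arm length in windows, and 8 Mb keeps sub-resolution
crossovers (< 3 windows from a tip) below ~2% of chromosomes while
keeping 500-zygote studies quick. The model-discrimination study uses
55 single 5-Mb chromosomes per replicate, matching the study-scale
autosome tally. Class accuracy is compared against the exact
chromatid-pair truth; for the strict noise-free equivalence checks, a
change point within `min_width + 1` windows of a chromosome end sits
at the window-resolution boundary and may legitimately resolve to
either the exact or the window-coarsened class. All randomness flows
from one root seed through named substreams; every stage is
bit-reproducible given its seed.

## Known limitations

- The SNP-filter stage is exercised on constructed candidate tables;
  raw variant calling from pileups is out of scope.
- The coverage mask requiring control-sample depth applies only when
  real control tracks are supplied; simulated data skip it.
- Contamination estimation assumes a visible heterozygous mode; a
  genome with almost no heterozygous windows returns c = 0 with a
  warning.
- The ambiguity criteria (AMBIG bands, `Homologs_ambiguous`) are this
  package's; the original study excluded ambiguous individuals by
  manual criteria that are not fully specified.
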