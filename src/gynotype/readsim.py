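"""Noisy single-worm sequencing observables from a simulated zygote.

The pipeline starts downstream of alignment: per-SNP maternal allele
depths (NIC59 vs JU1825 read counts) and per-window mean coverage
against both species' assemblies.  Whole-genome amplification of single
worms produces strongly overdispersed depths, modeled as beta-binomial
allele counts and gamma-multiplicative coverage noise.  Backcross sperm
contamination shifts every observed allele frequency towards the
contaminant haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .genome import GenomeSpec, ORIGIN_N
from .meiosis import Zygote

#: Column layout of an allele-depth table.
DEPTH_COLUMNS = ["chrom", "pos", "depth_N", "depth_J"]
#: Column layout of a coverage table.
COVERAGE_COLUMNS = ["species", "chrom", "start", "end", "depth"]

SPECIES_MATERNAL = "nouraguensis"
SPECIES_PATERNAL = "becei"


@dataclass
class ReadModel:
    """Depth and noise model for whole-genome-amplified single-worm data.

    mean_depth
        Expected reads per SNP (and per-bp window coverage unit) for a
        diploid locus.
    overdispersion_rho
        Beta-binomial intra-class correlation; 0 reduces to binomial.
        WGA jackpotting motivates a nonzero default.
    error_rate
        Per-read probability that a read supports the wrong haplotype.
    contamination_c
        Fraction of reads derived from a contaminant individual
        (backcross sperm carryover), < 0.5.
    contaminant_origin
        Haplotype of the contaminant ("N" or "J").
    becei_noise_floor
        Fraction of reads cross-mapping to the paternal assembly even
        without paternal DNA (0.1-0.2% observed; default 0.15%).
    """

    mean_depth: float = 30.0
    overdispersion_rho: float = 0.05
    error_rate: float = 0.001
    contamination_c: float = 0.0
    contaminant_origin: str = "J"
    becei_noise_floor: float = 0.0015

    def __post_init__(self) -> None:
        if not 0.0 <= self.overdispersion_rho < 1.0:
            raise ValueError("overdispersion_rho must be in [0, 1)")
        if not 0.0 <= self.contamination_c < 0.5:
            raise ValueError("contamination_c must be in [0, 0.5)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def snp_positions(length: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Exponentially spaced SNP positions in [0, length)."""
    n_expected = int(length / spacing * 1.3) + 10
    gaps = rng.exponential(spacing, size=n_expected)
    pos = np.cumsum(gaps)
    while pos[-1] < length:  # rare under the 1.3x headroom
        extra = np.cumsum(rng.exponential(spacing, size=n_expected)) + pos[-1]
        pos = np.concatenate([pos, extra])
    pos = pos[pos < length]
    return np.unique(pos.astype(np.int64))


def _beta_binomial(n: np.ndarray, f: np.ndarray, rho: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Beta-binomial draws with mean fraction f and intra-class correlation rho."""
    f = np.clip(f, 0.0, 1.0)
    if rho <= 0.0:
        return rng.binomial(n, f)
    conc = (1.0 - rho) / rho
    a, b = f * conc, (1.0 - f) * conc
    p = np.where(f <= 0.0, 0.0, np.where(f >= 1.0, 1.0, rng.beta(np.maximum(a, 1e-12),
                                                                 np.maximum(b, 1e-12))))
    return rng.binomial(n, p)


def simulate_allele_depths(zygote: Zygote, spec: GenomeSpec, model: ReadModel,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Per-SNP NIC59/JU1825 read counts for every maternal chromosome.

    At each SNP the true NIC59 fraction is (copies with origin N) /
    (total maternal copies); contamination and read error shift it to
    the observed fraction, and depths are drawn beta-binomially.
    """
    c = model.contamination_c
    f_cont = 1.0 if model.contaminant_origin == ORIGIN_N else 0.0
    e = model.error_rate
    frames = []
    for chrom_spec in spec.chromosomes:
        chrom = chrom_spec.id
        copies = zygote.maternal.get(chrom, [])
        if not copies:
            raise ValueError(f"zygote has no maternal copy of {chrom}")
        pos = snp_positions(chrom_spec.length, spec.snp_spacing, rng)
        n_is_N = np.zeros(len(pos))
        for ct in copies:
            n_is_N += (ct.origins_at(pos) == ORIGIN_N)
        f_true = n_is_N / len(copies)
        f_obs = (1.0 - c) * f_true + c * f_cont
        f_obs = f_obs * (1.0 - 2.0 * e) + e
        depth = rng.poisson(model.mean_depth, size=len(pos))
        depth_n = _beta_binomial(depth, f_obs, model.overdispersion_rho, rng)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "depth_N": depth_n, "depth_J": depth - depth_n,
        }))
    return pd.concat(frames, ignore_index=True)


def window_starts(length: int, window_size: int) -> np.ndarray:
    return np.arange(0, length, window_size, dtype=np.int64)


def simulate_coverage(zygote: Zygote, spec: GenomeSpec, model: ReadModel,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Mean depth in tiling windows against both assemblies.

    Window depth is proportional to locus copy number averaged over
    cells: the maternal copy count against the *C. nouraguensis*
    reference, and mosaic_fraction x paternal copies against the
    *C. becei* reference (plus a small cross-mapping floor), with a
    mean depth of ``mean_depth`` for two copies in all cells.
    """
    rho = model.overdispersion_rho
    rows = []
    for chrom_spec in spec.chromosomes:
        chrom = chrom_spec.id
        starts = window_starts(chrom_spec.length, spec.window_size)
        ends = np.minimum(starts + spec.window_size, chrom_spec.length)
        mat_copies = zygote.maternal_copies(chrom)
        pat_copies = 1 if chrom in zygote.paternal else 0
        for species, copies_per_cell in (
            (SPECIES_MATERNAL, float(mat_copies)),
            (SPECIES_PATERNAL, zygote.mosaic_fraction * pat_copies),
        ):
            expected = model.mean_depth * copies_per_cell / 2.0
            if species == SPECIES_PATERNAL:
                expected = expected + model.mean_depth * model.becei_noise_floor
            depth = np.full(len(starts), expected)
            if rho > 0 and expected > 0:
                depth = depth * rng.gamma(1.0 / rho, rho, size=len(starts))
            rows.append(pd.DataFrame({
                "species": species, "chrom": chrom,
                "start": starts, "end": ends, "depth": depth,
            }))
    return pd.concat(rows, ignore_index=True)
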