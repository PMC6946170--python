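"""Chromosome-class calls, copy number, mosaicism, and individual category.

Each chromosome's ordered segment states are matched against the
zygosity signatures of the chromatid-combination classes; per-chromosome
coverage against both assemblies, normalized so the maternal reference
chromosome sits at two copies, yields integer copy number for maternal
chromosomes and a cell-fraction estimate for paternal ones (a paternal
chromosome present in one copy in every cell normalizes to 1.0, so the
normalized value directly estimates the mosaic fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import trim_mean

from .classes import ChromosomeGenotype
from .genome import GenomeSpec
from .genotyping import Segment
from .readsim import SPECIES_MATERNAL, SPECIES_PATERNAL


# ---------------------------------------------------------------------------
# per-chromosome genotype classification
# ---------------------------------------------------------------------------

def _collapse_state_runs(segments: list[Segment]) -> list[tuple[int, int, str, int]]:
    """Merge adjacent same-state segments into (start, end, state, n_windows) runs."""
    runs: list[list] = []
    for seg in segments:
        if runs and runs[-1][2] == seg.state:
            runs[-1][1] = seg.end
            runs[-1][3] += seg.n_windows
        else:
            runs.append([seg.start, seg.end, seg.state, seg.n_windows])
    return [tuple(r) for r in runs]


def _drop_short_terminal_hom(runs: list, min_windows: int) -> list:
    """Noise guard: a terminal HOM run shorter than min_windows is absorbed."""
    runs = [list(r) for r in runs]
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for pick, neigh in ((0, 1), (-1, -2)):
            if len(runs) > 1 and runs[pick][2] in ("HOM_N", "HOM_J") \
                    and runs[pick][3] < min_windows:
                lo = min(runs[pick][0], runs[neigh][0])
                hi = max(runs[pick][1], runs[neigh][1])
                runs[neigh][0], runs[neigh][1] = lo, hi
                runs[neigh][3] += runs[pick][3]
                runs.pop(0 if pick == 0 else len(runs) - 1)
                changed = True
                break
    # re-collapse in case absorption created equal neighbours
    out: list[list] = []
    for r in runs:
        if out and out[-1][2] == r[2]:
            out[-1][1] = r[1]
            out[-1][3] += r[3]
        else:
            out.append(list(r))
    return [tuple(r) for r in out]


_TWO_RUN_CLASSES = {
    ("HET", "HOM_N"): ChromosomeGenotype.HOMOLOGS_1,
    ("HET", "HOM_J"): ChromosomeGenotype.HOMOLOGS_2,
    ("HOM_N", "HET"): ChromosomeGenotype.SISTERS_1,
    ("HOM_J", "HET"): ChromosomeGenotype.SISTERS_2,
    ("HET", "AMBIG"): ChromosomeGenotype.HOMOLOGS_AMBIGUOUS,
}


def classify_chromosome(segments: list[Segment], copy_number: int = 2,
                        min_terminal_windows: int = 2) -> ChromosomeGenotype:
    """Map a chromosome's ordered segment states to a genotype class.

    The body is the state run containing the chromosome midpoint and the
    terminal run is the end-touching remainder, mirroring a single
    end-biased crossover.  Copy-number anomalies (1 or 3) take priority
    over zygosity patterns; terminal homozygous runs shorter than
    ``min_terminal_windows`` are treated as noise.
    """
    if not segments:
        raise ValueError("empty segment list")
    if copy_number == 1:
        return ChromosomeGenotype.HEMIZYGOUS_X
    if copy_number >= 3:
        return ChromosomeGenotype.TRIPLOID

    runs = _collapse_state_runs(segments)
    runs = _drop_short_terminal_hom(runs, min_terminal_windows)

    if len(runs) == 1:
        return {
            "HET": ChromosomeGenotype.HOMOLOGS_3,
            "HOM_N": ChromosomeGenotype.FULL_HOM_N,
            "HOM_J": ChromosomeGenotype.FULL_HOM_J,
        }.get(runs[0][2], ChromosomeGenotype.AMBIGUOUS)

    if len(runs) == 2:
        mid = (segments[0].start + segments[-1].end) / 2
        body, term = (runs[0], runs[1]) if runs[0][0] <= mid < runs[0][1] else (runs[1], runs[0])
        return _TWO_RUN_CLASSES.get((body[2], term[2]), ChromosomeGenotype.AMBIGUOUS)

    if len(runs) == 3:
        mid = (segments[0].start + segments[-1].end) / 2
        a, b, c = runs
        if b[0] <= mid < b[1] and b[2] == "HET" and a[2] == "AMBIG" and c[2] == "AMBIG":
            return ChromosomeGenotype.HOMOLOGS_AMBIGUOUS
    return ChromosomeGenotype.AMBIGUOUS


# ---------------------------------------------------------------------------
# coverage-based copy number and mosaicism
# ---------------------------------------------------------------------------

@dataclass
class CopyNumberCall:
    chrom: str
    species: str
    normalized: float       # coverage scaled so the reference chromosome = 2
    copy_number: int        # nearest of {0, 1, 2, 3}
    mosaic_fraction: float | None = None  # paternal chromosomes only
    is_mosaic: bool = False


def normalize_and_call_copy_number(coverage: pd.DataFrame,
                                   ref_chrom: str | None = None,
                                   trim: float = 0.1,
                                   mosaic_band: tuple[float, float] = (0.1, 0.9),
                                   ) -> list[CopyNumberCall]:
    """Normalize window coverage and call per-chromosome copy number.

    All coverages are scaled so the maternal reference chromosome
    (chromosome I by default) equals two copies.  A trimmed mean per
    chromosome resists amplification jackpots.  For paternal
    chromosomes the normalized value estimates the fraction of cells
    carrying that chromosome, flagged mosaic inside ``mosaic_band``.
    """
    mat = coverage[coverage["species"] == SPECIES_MATERNAL]
    if mat.empty:
        raise ValueError("no maternal-reference coverage windows")
    if ref_chrom is None:
        ref_chrom = sorted(mat["chrom"].unique())[0]
    ref = mat.loc[mat["chrom"] == ref_chrom, "depth"]
    if ref.empty:
        raise ValueError(f"reference chromosome {ref_chrom!r} missing from coverage")
    scale = 2.0 / trim_mean(ref, trim)

    calls: list[CopyNumberCall] = []
    for (species, chrom), sub in coverage.groupby(["species", "chrom"], sort=True):
        norm = float(trim_mean(sub["depth"], trim) * scale)
        cn = int(np.clip(np.rint(norm), 0, 3))
        if species == SPECIES_PATERNAL:
            f = float(np.clip(norm, 0.0, 1.0))
            calls.append(CopyNumberCall(chrom, species, norm, cn, mosaic_fraction=f,
                                        is_mosaic=mosaic_band[0] < f < mosaic_band[1]))
        else:
            calls.append(CopyNumberCall(chrom, species, norm, cn))
    return calls


def becei_read_fraction(coverage: pd.DataFrame) -> float:
    """Fraction of sequenced bases mapping to the paternal assembly."""
    size = (coverage["end"] - coverage["start"])
    mass = coverage["depth"] * size
    total = mass.sum()
    pat = mass[coverage["species"] == SPECIES_PATERNAL].sum()
    return float(pat / total) if total > 0 else 0.0


# ---------------------------------------------------------------------------
# individual-level category
# ---------------------------------------------------------------------------

class IndividualCategory:
    MATERNAL_ONLY = "maternal_only"
    TRIPLOID_HYBRID = "triploid_hybrid"
    MOSAIC_HYBRID = "mosaic_hybrid"
    AMBIGUOUS = "ambiguous"


@dataclass
class IndividualSummary:
    genotypes: dict[str, ChromosomeGenotype]
    copy_calls: list[CopyNumberCall]
    becei_fraction: float
    category: str
    paternal_x_present: bool
    maternal_x_copies: int
    notes: dict = field(default_factory=dict)


def classify_individual(genotypes: dict[str, ChromosomeGenotype],
                        copy_calls: list[CopyNumberCall],
                        becei_fraction: float,
                        spec: GenomeSpec,
                        maternal_only_threshold: float = 0.01,
                        mosaic_band: tuple[float, float] = (0.1, 0.9),
                        ) -> IndividualSummary:
    """Individual-level category from becei read fraction and paternal coverage.

    MATERNAL_ONLY: paternal read fraction at the cross-mapping floor and
    no paternal chromosome called present.  TRIPLOID_HYBRID: complete
    paternal autosome set in essentially all cells.  MOSAIC_HYBRID:
    complete set at an intermediate cell fraction.
    """
    pat = {c.chrom: c for c in copy_calls if c.species == SPECIES_PATERNAL}
    mat = {c.chrom: c for c in copy_calls if c.species == SPECIES_MATERNAL}
    x_id = spec.x_id
    pat_x = pat.get(x_id) if x_id else None
    paternal_x_present = bool(pat_x and pat_x.mosaic_fraction is not None
                              and pat_x.mosaic_fraction >= mosaic_band[0])
    maternal_x_copies = mat[x_id].copy_number if (x_id and x_id in mat) else 0

    auto_f = [pat[c].mosaic_fraction for c in spec.autosome_ids if c in pat]
    complete = len(auto_f) == len(spec.autosome_ids)
    if becei_fraction <= maternal_only_threshold and \
            all((c.copy_number == 0) for c in pat.values()):
        category = IndividualCategory.MATERNAL_ONLY
    elif complete and all(f >= mosaic_band[1] for f in auto_f):
        category = IndividualCategory.TRIPLOID_HYBRID
    elif complete and all(mosaic_band[0] < f < mosaic_band[1] for f in auto_f):
        category = IndividualCategory.MOSAIC_HYBRID
    else:
        category = IndividualCategory.AMBIGUOUS

    return IndividualSummary(genotypes=genotypes, copy_calls=copy_calls,
                             becei_fraction=becei_fraction, category=category,
                             paternal_x_present=paternal_x_present,
                             maternal_x_copies=maternal_x_copies)
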