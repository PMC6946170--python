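"""Single-worm genotyping: SNP filtering, windowed allele frequencies,
contamination correction, CBS segmentation, and segment state calls.

The observable is the NIC59 allele frequency: pooled NIC59 read counts
divided by total informative reads in 50-kb windows.  A frequency near
0.5 indicates heterozygosity (NIC59/JU1825), near 1.0 homozygous NIC59,
near 0.0 homozygous JU1825.  Change points between haplotype blocks are
located by circular binary segmentation with a permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from ._cbs_kernel import batch_max_stats, max_arc_stat
from .genome import GenomeSpec, ORIGIN_N
from .readsim import window_starts


# ---------------------------------------------------------------------------
# SNP filtering
# ---------------------------------------------------------------------------

@dataclass
class SnpFilterConfig:
    """Thresholds selecting high-quality fixed differences between strains.

    Defaults follow standard practice for ancestry-informative marker
    selection in inbred nematode strains: a minimum variant quality,
    near-fixation of opposite alleles in the two parental strains,
    control read depth within the library's typical range, and zero
    depth in the other-species control (to exclude cross-mapping sites).
    """

    min_qual: float = 100.0
    max_minor_freq: float = 0.05
    min_major_freq: float = 0.95
    control_depth_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"depth_nic59_control": (5, 50),
                                 "depth_ju1825_control": (5, 50)})
    other_species_depth_cols: tuple[str, ...] = ("depth_becei_control",)
    max_other_species_depth: float = 0.0
    freq_cols: tuple[str, str] = ("nonref_freq_nic59", "nonref_freq_ju1825")
    qual_col: str = "qual"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_minor_freq < self.min_major_freq <= 1.0:
            raise ValueError("need 0 <= max_minor_freq < min_major_freq <= 1")


def filter_snps(candidates: pd.DataFrame,
                config: SnpFilterConfig | None = None) -> tuple[pd.DataFrame, dict[str, int]]:
    """Retain candidate SNPs passing every filter; report per-criterion removals.

    A fixed difference requires one strain's non-reference frequency
    below ``max_minor_freq`` and the other's above ``min_major_freq``
    (in either orientation).
    """
    config = config or SnpFilterConfig()
    required = [config.qual_col, *config.freq_cols,
                *config.control_depth_ranges, *config.other_species_depth_cols]
    missing = [c for c in required if c not in candidates.columns]
    if missing:
        raise KeyError(f"candidate table missing required column(s): {missing}")

    removed: dict[str, int] = {}
    keep = candidates[config.qual_col] >= config.min_qual
    removed["quality"] = int((~keep).sum())

    fa, fb = (candidates[c] for c in config.freq_cols)
    fixed = ((fa < config.max_minor_freq) & (fb > config.min_major_freq)) | \
            ((fb < config.max_minor_freq) & (fa > config.min_major_freq))
    removed["not_fixed_difference"] = int((~fixed).sum())
    keep &= fixed

    for col, (lo, hi) in config.control_depth_ranges.items():
        ok = candidates[col].between(lo, hi)
        removed[f"depth_range:{col}"] = int((~ok).sum())
        keep &= ok

    for col in config.other_species_depth_cols:
        ok = candidates[col] <= config.max_other_species_depth
        removed[f"other_species:{col}"] = int((~ok).sum())
        keep &= ok

    return candidates.loc[keep].reset_index(drop=True), removed


# ---------------------------------------------------------------------------
# windowed allele frequencies
# ---------------------------------------------------------------------------

WINDOW_COLUMNS = ["chrom", "start", "end", "depth_N", "depth_J", "n_snps", "freq"]


def window_allele_freq(depths: pd.DataFrame, spec: GenomeSpec) -> pd.DataFrame:
    """Pooled NIC59 allele frequency in tiling windows.

    The frequency is total NIC59 reads over total reads in the window
    (a pooled-count ratio, not a mean of per-SNP frequencies); windows
    without reads get NaN and are flagged by zero depth.
    """
    frames = []
    for chrom_spec in spec.chromosomes:
        chrom = chrom_spec.id
        starts = window_starts(chrom_spec.length, spec.window_size)
        sub = depths[depths["chrom"] == chrom]
        idx = np.clip(sub["pos"].to_numpy() // spec.window_size, 0, len(starts) - 1)
        dn = np.bincount(idx, weights=sub["depth_N"], minlength=len(starts))
        dj = np.bincount(idx, weights=sub["depth_J"], minlength=len(starts))
        ns = np.bincount(idx, minlength=len(starts))
        total = dn + dj
        with np.errstate(invalid="ignore"):
            freq = np.where(total > 0, dn / np.where(total > 0, total, 1), np.nan)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts,
            "end": np.minimum(starts + spec.window_size, chrom_spec.length),
            "depth_N": dn.astype(np.int64), "depth_J": dj.astype(np.int64),
            "n_snps": ns.astype(np.int64), "freq": freq,
        }))
    return pd.concat(frames, ignore_index=True)


def apply_coverage_mask(windows: pd.DataFrame, control_coverage: pd.DataFrame,
                        min_control_depth: float = 8.0) -> pd.DataFrame:
    """Mask windows lacking adequate control-sample coverage (real-data mode).

    Windows whose control depth falls below ``min_control_depth`` are
    flagged missing (freq = NaN) so segmentation skips unreliable
    regions; simulated data have uniform coverage and skip this step.
    ``control_coverage`` needs columns chrom/start/depth aligned to the
    same window grid.
    """
    out = windows.copy()
    ctrl = control_coverage.set_index(["chrom", "start"])["depth"]
    key = pd.MultiIndex.from_frame(out[["chrom", "start"]])
    depth = ctrl.reindex(key).to_numpy()
    bad = ~(depth >= min_control_depth)  # NaN (no control window) also masks
    out.loc[bad, "freq"] = np.nan
    return out


def estimate_contamination(windows: pd.DataFrame, contaminant_origin: str = "J",
                           min_windows: int = 50) -> float:
    """Estimate the contaminant read fraction from the heterozygous mode.

    Backcross contamination shifts the heterozygous window-frequency
    mode m away from 0.5; inverting the mixture gives
    c = (0.5 - m) / (0.5 - f_cont), with f_cont = 1 for a NIC59
    contaminant and 0 for a JU1825 one.  The mode is located by a
    Gaussian kernel density over frequencies in [0.2, 0.8].
    """
    freqs = windows["freq"].dropna().to_numpy()
    if len(freqs) < min_windows:
        raise ValueError(f"need at least {min_windows} non-missing windows")
    het = freqs[(freqs >= 0.2) & (freqs <= 0.8)]
    if len(het) < 10 or np.ptp(het) < 1e-12:
        if len(het) == 0:
            warnings.warn("no heterozygous mode found; assuming no contamination")
            return 0.0
        mode = float(np.median(het))
    else:
        kde = gaussian_kde(het)
        grid = np.linspace(0.2, 0.8, 601)
        mode = float(grid[np.argmax(kde(grid))])
    f_cont = 1.0 if contaminant_origin == ORIGIN_N else 0.0
    c = (0.5 - mode) / (0.5 - f_cont)
    return float(np.clip(c, 0.0, 0.5 - 1e-9))


# ---------------------------------------------------------------------------
# circular binary segmentation
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """A contiguous run of windows with one mean allele frequency."""

    chrom: str
    start_w: int          # window index, half-open interval [start_w, end_w)
    end_w: int
    start: int            # bp
    end: int
    mean_freq: float
    n_windows: int
    state: str | None = None  # HOM_N / HET / HOM_J / AMBIG


@dataclass
class CbsParams:
    alpha: float = 0.01
    min_width: int = 3
    n_perm: int = 1000
    merge_tol: float = 0.1
    perm_block: int = 100


def _perm_significant(x: np.ndarray, observed_stat: float, params: CbsParams,
                      rng: np.random.Generator) -> tuple[bool, float]:
    """Permutation p-value for the best arc, with a curtailed scan.

    Permutations run in blocks; once the exceedance count is high
    enough that p >= alpha is guaranteed, remaining blocks are skipped
    (the accept/reject decision is unchanged by curtailment).
    """
    max_exceed = int(np.floor(params.alpha * (1 + params.n_perm))) - 1
    exceed = 0
    done = 0
    while done < params.n_perm:
        b = min(params.perm_block, params.n_perm - done)
        perms = rng.permuted(np.tile(x, (b, 1)), axis=1)
        stats = batch_max_stats(perms, params.min_width)
        exceed += int(np.sum(stats >= observed_stat * (1 - 1e-12)))
        done += b
        if exceed > max_exceed:
            return False, (1 + exceed) / (1 + done)
    return exceed <= max_exceed, (1 + exceed) / (1 + params.n_perm)


def _segment_recursive(x: np.ndarray, lo: int, hi: int, params: CbsParams,
                       rng: np.random.Generator, bounds: list[int]) -> None:
    n = hi - lo
    if n < 2 * params.min_width:
        return
    stat, i, j = max_arc_stat(x[lo:hi], params.min_width)
    if stat < 0:
        return
    significant, _ = _perm_significant(x[lo:hi], stat, params, rng)
    if not significant:
        return
    cuts = [lo + i, lo + j]
    pieces = sorted({lo, hi, *[c for c in cuts if lo < c < hi]})
    for a, b in zip(pieces[:-1], pieces[1:]):
        if lo < a:
            bounds.append(a)
        _segment_recursive(x, a, b, params, rng, bounds)


def segment_values(x: np.ndarray, params: CbsParams,
                   rng: np.random.Generator) -> list[int]:
    """CBS breakpoints (indices into x, excluding 0 and n), sorted."""
    bounds: list[int] = []
    _segment_recursive(np.asarray(x, dtype=np.float64), 0, len(x), params, rng, bounds)
    return sorted(set(bounds))


def _merge_close_segments(x: np.ndarray, bounds: list[int], merge_tol: float) -> list[int]:
    edges = [0, *bounds, len(x)]
    changed = True
    while changed and len(edges) > 2:
        changed = False
        means = [float(np.mean(x[a:b])) for a, b in zip(edges[:-1], edges[1:])]
        for k in range(len(means) - 1):
            if abs(means[k] - means[k + 1]) < merge_tol:
                edges.pop(k + 1)
                changed = True
                break
    return edges[1:-1]


def segment_cbs(windows: pd.DataFrame, params: CbsParams | None = None,
                seed: int = 0) -> list[Segment]:
    """Segment one chromosome's windowed allele frequencies.

    Windows with no reads are excluded from the change-point search and
    absorbed into the enclosing segment afterwards.  Deterministic for
    a fixed seed.
    """
    params = params or CbsParams()
    chroms = windows["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("segment_cbs expects windows from a single chromosome")
    chrom = chroms[0]
    windows = windows.sort_values("start").reset_index(drop=True)
    valid = windows["freq"].notna().to_numpy()
    x = windows["freq"].to_numpy()[valid]
    n_all = len(windows)
    if len(x) == 0:
        seg = Segment(chrom, 0, n_all, int(windows["start"].iloc[0]),
                      int(windows["end"].iloc[-1]), np.nan, n_all, "AMBIG")
        return [seg]
    rng = np.random.default_rng(seed)
    bounds = segment_values(x, params, rng)
    bounds = _merge_close_segments(x, bounds, params.merge_tol)

    # map value-index boundaries back to window indices
    valid_idx = np.flatnonzero(valid)
    win_bounds = [0, *[int(valid_idx[b]) for b in bounds], n_all]
    segments = []
    for a, b in zip(win_bounds[:-1], win_bounds[1:]):
        sub = windows.iloc[a:b]
        mean_freq = float(sub["freq"].mean())  # nan-safe mean over non-missing
        segments.append(Segment(chrom, a, b, int(sub["start"].iloc[0]),
                                int(sub["end"].iloc[-1]), mean_freq, b - a))
    return segments


# ---------------------------------------------------------------------------
# segment state calls
# ---------------------------------------------------------------------------

@dataclass
class StateBands:
    """Allele-frequency bands mapping segment means to zygosity states."""

    het_low: float = 0.35
    het_high: float = 0.65
    hom_n_min: float = 0.85
    hom_j_max: float = 0.15


def correct_frequency(f: float, c: float, contaminant_origin: str = "J") -> float:
    """Invert the contamination mixture: f_true = (f - c * f_cont) / (1 - c)."""
    f_cont = 1.0 if contaminant_origin == ORIGIN_N else 0.0
    return (f - c * f_cont) / (1.0 - c)


def call_segment_states(segments: list[Segment], bands: StateBands | None = None,
                        c: float = 0.0, contaminant_origin: str = "J") -> list[Segment]:
    """Assign HOM_N / HET / HOM_J / AMBIG to each segment mean.

    Means are contamination-corrected first; a segment with no reads
    stays AMBIG.
    """
    bands = bands or StateBands()
    for seg in segments:
        if np.isnan(seg.mean_freq):
            seg.state = "AMBIG"
            continue
        f = correct_frequency(seg.mean_freq, c, contaminant_origin)
        eps = 1e-9  # guard band edges against float round-off
        if bands.het_low - eps <= f <= bands.het_high + eps:
            seg.state = "HET"
        elif f >= bands.hom_n_min - eps:
            seg.state = "HOM_N"
        elif f <= bands.hom_j_max + eps:
            seg.state = "HOM_J"
        else:
            seg.state = "AMBIG"
    return segments


def genotype_chromosome(windows: pd.DataFrame, params: CbsParams | None = None,
                        bands: StateBands | None = None, c: float = 0.0,
                        contaminant_origin: str = "J", seed: int = 0) -> list[Segment]:
    """Segment one chromosome and call segment states."""
    segments = segment_cbs(windows, params, seed=seed)
    return call_segment_states(segments, bands, c, contaminant_origin)
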