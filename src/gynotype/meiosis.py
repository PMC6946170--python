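"""Forward simulation of modified female meiosis and paternal-genome fate.

Models the asexual (gynogenetic) reproduction of *C. nouraguensis*
females crossed to *C. becei* males: each bivalent receives one
crossover biased towards a chromosome end; the oocyte then retains
chromatids according to an inheritance mode (canonical meiosis,
central-fusion automixis, sister fusion, apomixis, endoreplication, or
unconstrained two-chromatid retention), and the paternal genome is
either inherited, eliminated, or retained in a subset of cells.
Cytological observables (polar bodies, DAPI-staining bodies) and zygote
fate follow from the retained complement.

Coordinates are 0-based half-open; crossover positions are integer bp.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .classes import ChromosomeGenotype
from .genome import GenomeSpec, ORIGIN_B, ORIGIN_J, ORIGIN_N


# ---------------------------------------------------------------------------
# chromatids and bivalents
# ---------------------------------------------------------------------------

@dataclass
class Chromatid:
    """One chromosome copy as an ordered list of haplotype blocks.

    ``blocks`` is a list of ``(start, end, origin)`` tuples tiling
    ``[0, length)`` with no gaps or overlaps; adjacent blocks differ in
    origin.  Maternal chromatids carry origins ``N``/``J``; paternal
    chromatids carry ``B`` only.
    """

    chrom: str
    blocks: list[tuple[int, int, str]]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("chromatid needs at least one block")
        self.blocks = _normalize_blocks(self.blocks)

    @property
    def length(self) -> int:
        return self.blocks[-1][1]

    def origin_at(self, pos: int) -> str:
        for start, end, origin in self.blocks:
            if start <= pos < end:
                return origin
        raise IndexError(f"position {pos} outside [0, {self.length})")

    def origins_at(self, positions: np.ndarray) -> np.ndarray:
        """Vectorized origin lookup for sorted or unsorted positions."""
        starts = np.array([b[0] for b in self.blocks])
        labels = np.array([b[2] for b in self.blocks])
        idx = np.searchsorted(starts, positions, side="right") - 1
        if np.any(idx < 0) or np.any(positions >= self.length):
            raise IndexError("positions outside chromatid")
        return labels[idx]

    def origin_length(self, origin: str) -> int:
        return sum(e - s for s, e, o in self.blocks if o == origin)


def _normalize_blocks(blocks: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    out: list[tuple[int, int, str]] = []
    prev_end = 0
    for start, end, origin in blocks:
        if start != prev_end:
            raise ValueError("blocks must tile the chromosome without gaps")
        if end <= start:
            raise ValueError("empty or inverted block")
        if out and out[-1][2] == origin:
            out[-1] = (out[-1][0], end, origin)
        else:
            out.append((int(start), int(end), origin))
        prev_end = end
    return out


def uniform_chromatid(chrom: str, length: int, origin: str) -> Chromatid:
    return Chromatid(chrom, [(0, length, origin)])


def recombinant_chromatid(chrom: str, length: int, left: str, right: str,
                          crossover: int) -> Chromatid:
    return Chromatid(chrom, [(0, crossover, left), (crossover, length, right)])


@dataclass
class Bivalent:
    """The four chromatids of one paired homolog set after a single crossover.

    ``N1``/``J2`` are the non-recombinant N and J chromatids; ``N2``/``J1``
    are the reciprocal recombinants (N2 is N left of the crossover, J1 is
    J left of it).  A dyad is the pair of chromatids that co-segregate at
    anaphase I; its two members are identical along the long side of the
    crossover, where sister-chromatid cohesion is retained.
    """

    chrom: str
    length: int
    crossover_pos: int
    chromatids: dict[str, Chromatid]
    dyads: tuple[tuple[str, str], tuple[str, str]]

    PAIR_KEYS = (("N1", "N2"), ("N1", "J1"), ("N1", "J2"),
                 ("N2", "J1"), ("N2", "J2"), ("J1", "J2"))

    def pair(self, a: str, b: str) -> tuple[Chromatid, Chromatid]:
        return self.chromatids[a], self.chromatids[b]

    def all_pairs(self) -> list[tuple[str, str]]:
        """The six unordered chromatid pairs."""
        return list(self.PAIR_KEYS)

    def homologous_pairs(self) -> list[tuple[str, str]]:
        """The four pairs whose members come from different dyads."""
        (a1, a2), (b1, b2) = self.dyads
        return [(a1, b1), (a1, b2), (a2, b1), (a2, b2)]


def draw_crossover_position(spec: GenomeSpec, chrom: str, rng: np.random.Generator) -> int:
    """Draw the single obligate crossover, biased towards the chromosome ends.

    With probability ``1 - p_center_crossover`` the position is uniform
    over the two arm regions; otherwise uniform over the center.  The
    returned position lies in ``[1, L - 1]`` so both sides are non-empty.
    """
    L = spec.length(chrom)
    arm = int(round(spec.arm_fraction * L))
    if rng.random() < spec.p_center_crossover and arm < L - arm:
        pos = int(rng.integers(arm, L - arm))
    else:
        # choose one of the two arms, then a uniform position within it
        offset = int(rng.integers(0, arm))
        pos = offset if rng.random() < 0.5 else L - arm + offset
    return int(np.clip(pos, 1, L - 1))


def make_bivalent(spec: GenomeSpec, chrom: str, rng: np.random.Generator) -> Bivalent:
    """Form a bivalent: four chromatids with one reciprocal exchange.

    Dyad assignment pairs each non-recombinant chromatid with the
    recombinant sharing its haplotype on the long side of the crossover,
    mirroring holocentric meiosis-I cohesion along the long arm.
    """
    L = spec.length(chrom)
    c = draw_crossover_position(spec, chrom, rng)
    chromatids = {
        "N1": uniform_chromatid(chrom, L, ORIGIN_N),
        "J2": uniform_chromatid(chrom, L, ORIGIN_J),
        "N2": recombinant_chromatid(chrom, L, ORIGIN_N, ORIGIN_J, c),
        "J1": recombinant_chromatid(chrom, L, ORIGIN_J, ORIGIN_N, c),
    }
    if c <= L - c:
        # long side is [c, L): J1 is N there, N2 is J there
        dyads = (("N1", "J1"), ("J2", "N2"))
    else:
        dyads = (("N1", "N2"), ("J2", "J1"))
    return Bivalent(chrom, L, c, chromatids, dyads)


# ---------------------------------------------------------------------------
# inheritance modes and chromatid selection
# ---------------------------------------------------------------------------

class MaternalMode(str, Enum):
    CANONICAL = "canonical"              # one random chromatid, two polar bodies
    CENTRAL_FUSION = "central_fusion"    # two chromatids from different dyads
    SISTER_FUSION = "sister_fusion"      # one whole dyad (sister pair)
    APOMIXIS = "apomixis"                # mitosis-like: clone of the mother
    ENDOREPLICATION = "endoreplication"  # one chromatid duplicated
    RANDOM_TWO = "random_two"            # any unordered pair of the four


class PaternalFateKind(str, Enum):
    FULL = "full"
    NONE = "none"
    MOSAIC = "mosaic"
    PARTIAL = "partial"
    UV_DESTROYED = "uv_destroyed"


@dataclass
class PaternalFate:
    """What happens to the sperm-delivered *C. becei* genome.

    ``include_X`` models XO fathers: the sperm carries the paternal X
    with probability 0.5 when left unresolved (``None``).  ``MOSAIC``
    retains the full paternal complement in a fraction
    ``mosaic_fraction`` of cells; ``PARTIAL`` retains each paternal
    chromosome independently with probability ``p_retain``.
    """

    kind: PaternalFateKind
    mosaic_fraction: float | None = None
    include_X: bool | None = None
    p_retain: float = 0.5

    def __post_init__(self) -> None:
        if self.kind is PaternalFateKind.MOSAIC:
            if self.mosaic_fraction is None or not 0.0 < self.mosaic_fraction < 1.0:
                raise ValueError("MOSAIC requires mosaic_fraction in (0, 1)")


class ZygoteFate(str, Enum):
    FERTILE_VIABLE = "fertile_viable"
    STERILE_VIABLE = "sterile_viable"
    DEAD = "dead"


@dataclass
class Zygote:
    """Retained maternal chromatids per chromosome plus the paternal complement."""

    maternal: dict[str, list[Chromatid]]
    paternal: list[str]                  # retained paternal chromosome ids
    paternal_kind: PaternalFateKind
    mosaic_fraction: float               # fraction of cells with paternal DNA
    polar_bodies: int
    mode: MaternalMode
    fate: ZygoteFate | None = None
    fate_reason: str = ""

    def maternal_copies(self, chrom: str) -> int:
        return len(self.maternal.get(chrom, []))

    def has_paternal_x(self, spec: GenomeSpec) -> bool:
        return spec.x_id is not None and spec.x_id in self.paternal


def select_maternal_chromatids(
    bivalent: Bivalent,
    mode: MaternalMode,
    rng: np.random.Generator,
    p_shared_spindle: float = 0.5,
) -> tuple[list[Chromatid], int]:
    """Retain oocyte chromatids from one bivalent under an inheritance mode.

    Returns the retained chromatids and the polar-body count implied by
    the mode.  Central fusion (meiosis-I failure) yields one polar body
    when the two half-bivalents share a meiosis-II spindle (probability
    ``p_shared_spindle``) and two otherwise; sister fusion (meiosis-II
    failure) yields one; apomixis skips the meiotic divisions entirely.
    """
    cts = bivalent.chromatids
    if mode is MaternalMode.CANONICAL:
        key = _choice(rng, list(cts))
        return [cts[key]], 2
    if mode is MaternalMode.CENTRAL_FUSION:
        a, b = _choice(rng, bivalent.homologous_pairs())
        pb = 1 if rng.random() < p_shared_spindle else 2
        return [cts[a], cts[b]], pb
    if mode is MaternalMode.SISTER_FUSION:
        a, b = _choice(rng, list(bivalent.dyads))
        return [cts[a], cts[b]], 1
    if mode is MaternalMode.APOMIXIS:
        # no recombination, no division: the egg is a clone of the mother
        L = bivalent.length
        return [uniform_chromatid(bivalent.chrom, L, ORIGIN_N),
                uniform_chromatid(bivalent.chrom, L, ORIGIN_J)], 0
    if mode is MaternalMode.ENDOREPLICATION:
        key = _choice(rng, list(cts))
        return [cts[key], _copy.deepcopy(cts[key])], 2
    if mode is MaternalMode.RANDOM_TWO:
        a, b = _choice(rng, bivalent.all_pairs())
        pb = 1 if rng.random() < p_shared_spindle else 2
        return [cts[a], cts[b]], pb
    raise ValueError(f"unknown mode {mode!r}")


def _choice(rng: np.random.Generator, items: list):
    return items[int(rng.integers(len(items)))]


# ---------------------------------------------------------------------------
# truth classifier (noise-free oracle)
# ---------------------------------------------------------------------------

def zygosity_intervals(pair: tuple[Chromatid, Chromatid]) -> list[tuple[int, int, str]]:
    """Partition the chromosome into HOM_N / HET / HOM_J zygosity runs."""
    a, b = pair
    if a.chrom != b.chrom or a.length != b.length:
        raise ValueError("chromatids come from different chromosomes")
    bounds = sorted({s for s, _, _ in a.blocks} | {s for s, _, _ in b.blocks}
                    | {a.length})
    runs: list[tuple[int, int, str]] = []
    for start, end in zip(bounds[:-1], bounds[1:]):
        oa, ob = a.origin_at(start), b.origin_at(start)
        state = ("HOM_" + oa) if oa == ob else "HET"
        if runs and runs[-1][2] == state:
            runs[-1] = (runs[-1][0], end, state)
        else:
            runs.append((start, end, state))
    return runs


def classify_pair_truth(pair: tuple[Chromatid, Chromatid],
                        min_terminal_bp: int = 0) -> ChromosomeGenotype:
    """Classify a maternal chromatid pair into its genotype class.

    This is the noise-free oracle: the zygosity pattern implied directly
    by the two chromatids.  The "body" is the run containing the
    chromosome midpoint; a terminal run shorter than ``min_terminal_bp``
    is treated as unresolvable and merged into the body (used to compare
    against window-resolution genotyping).
    """
    runs = zygosity_intervals(pair)
    length = pair[0].length
    if min_terminal_bp > 0 and len(runs) > 1:
        runs = _drop_short_terminal_runs(runs, min_terminal_bp)
    if len(runs) == 1:
        state = runs[0][2]
        return {
            "HET": ChromosomeGenotype.HOMOLOGS_3,
            "HOM_N": ChromosomeGenotype.FULL_HOM_N,
            "HOM_J": ChromosomeGenotype.FULL_HOM_J,
        }[state]
    if len(runs) == 2:
        mid = length / 2
        body, term = (runs[0], runs[1]) if runs[0][0] <= mid < runs[0][1] else (runs[1], runs[0])
        key = (body[2], term[2])
        mapping = {
            ("HET", "HOM_N"): ChromosomeGenotype.HOMOLOGS_1,
            ("HET", "HOM_J"): ChromosomeGenotype.HOMOLOGS_2,
            ("HOM_N", "HET"): ChromosomeGenotype.SISTERS_1,
            ("HOM_J", "HET"): ChromosomeGenotype.SISTERS_2,
        }
        return mapping.get(key, ChromosomeGenotype.AMBIGUOUS)
    return ChromosomeGenotype.AMBIGUOUS


def _drop_short_terminal_runs(runs: list[tuple[int, int, str]],
                              min_bp: int) -> list[tuple[int, int, str]]:
    runs = list(runs)
    changed = True
    while changed and len(runs) > 1:
        changed = False
        if runs[0][1] - runs[0][0] < min_bp:
            runs[1] = (runs[0][0], runs[1][1], runs[1][2])
            runs.pop(0)
            changed = True
        if len(runs) > 1 and runs[-1][1] - runs[-1][0] < min_bp:
            runs[-2] = (runs[-2][0], runs[-1][1], runs[-2][2])
            runs.pop()
            changed = True
    return runs


# ---------------------------------------------------------------------------
# zygote assembly and fate
# ---------------------------------------------------------------------------

def _polar_body_count(mode: MaternalMode, rng: np.random.Generator,
                      p_shared_spindle: float) -> int:
    if mode is MaternalMode.APOMIXIS:
        return 0
    if mode is MaternalMode.SISTER_FUSION:
        return 1
    if mode in (MaternalMode.CENTRAL_FUSION, MaternalMode.RANDOM_TWO):
        return 1 if rng.random() < p_shared_spindle else 2
    return 2


def simulate_zygote(
    spec: GenomeSpec,
    mode: MaternalMode,
    paternal: PaternalFate,
    rng: np.random.Generator,
    p_X_loss: float = 0.0,
    p_shared_spindle: float = 0.5,
) -> Zygote:
    """Simulate one fertilization: chromatid retention per chromosome,
    X missegregation, paternal-genome fate, polar bodies, and viability.

    Chromatid selection is independent across chromosomes; the polar-body
    count is a single per-oocyte observable drawn from the mode's rule.
    """
    maternal: dict[str, list[Chromatid]] = {}
    for c in spec.chromosomes:
        bivalent = make_bivalent(spec, c.id, rng)
        retained, _ = select_maternal_chromatids(bivalent, mode, rng, p_shared_spindle)
        if c.is_X and len(retained) > 1 and rng.random() < p_X_loss:
            retained = [retained[int(rng.integers(len(retained)))]]
        maternal[c.id] = retained
    polar_bodies = _polar_body_count(mode, rng, p_shared_spindle)

    include_X = paternal.include_X
    if include_X is None:
        include_X = bool(rng.random() < 0.5)
    sperm_set = list(spec.autosome_ids)
    if include_X and spec.x_id is not None:
        sperm_set.append(spec.x_id)

    kind = paternal.kind
    if kind in (PaternalFateKind.NONE, PaternalFateKind.UV_DESTROYED):
        retained_pat: list[str] = []
        mosaic = 0.0
    elif kind is PaternalFateKind.FULL:
        retained_pat = sperm_set
        mosaic = 1.0
    elif kind is PaternalFateKind.MOSAIC:
        retained_pat = sperm_set
        mosaic = float(paternal.mosaic_fraction)
    elif kind is PaternalFateKind.PARTIAL:
        retained_pat = [ch for ch in sperm_set if rng.random() < paternal.p_retain]
        mosaic = 1.0 if retained_pat else 0.0
    else:
        raise ValueError(f"unknown paternal fate {kind!r}")

    zygote = Zygote(maternal=maternal, paternal=retained_pat, paternal_kind=kind,
                    mosaic_fraction=mosaic, polar_bodies=polar_bodies, mode=mode)
    zygote.fate, zygote.fate_reason = zygote_fate(zygote, spec)
    return zygote


def zygote_fate(zygote: Zygote, spec: GenomeSpec) -> tuple[ZygoteFate, str]:
    """Viability and fertility from the retained chromosome complement.

    The paternal X is lethal to hybrids; an incomplete paternal set is
    aneuploid and lethal; a haploid or aneuploid maternal complement is
    lethal.  A maternal-diploid egg is fertile when no paternal DNA
    persists, and a viable but sterile (triploid or diploid-triploid
    mosaic) hybrid when the complete paternal autosome set persists in
    some fraction of cells.
    """
    if zygote.has_paternal_x(spec):
        return ZygoteFate.DEAD, "paternal X-chromosome toxicity"
    pat_autosomes = [c for c in zygote.paternal if c != spec.x_id]
    complete_paternal = set(pat_autosomes) == set(spec.autosome_ids)
    if zygote.paternal and not complete_paternal:
        return ZygoteFate.DEAD, "partial paternal complement (aneuploid)"
    copies = {c.id: zygote.maternal_copies(c.id) for c in spec.chromosomes}
    if all(n <= 1 for n in copies.values()):
        return ZygoteFate.DEAD, "haploid maternal complement"
    bad = [cid for cid in spec.autosome_ids if copies[cid] != 2]
    if bad:
        return ZygoteFate.DEAD, f"maternal aneuploidy on {','.join(bad)}"
    if not zygote.paternal:
        reason = "gynogenetic maternal diploid"
        if spec.x_id is not None and copies.get(spec.x_id, 0) == 1:
            reason += " (XO male)"
        return ZygoteFate.FERTILE_VIABLE, reason
    label = "triploid hybrid" if zygote.mosaic_fraction >= 1.0 else "diploid-triploid mosaic hybrid"
    return ZygoteFate.STERILE_VIABLE, label


def count_dapi_bodies(ploidy: int, n_chrom_types: int = 6) -> int:
    """DAPI-staining bodies in a mature oocyte.

    With one obligate crossover per homolog set, two homologs per
    chromosome type form one bivalent and every extra homolog remains a
    univalent: diploids show ``n`` bodies, triploids ``2n``.
    """
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    if ploidy == 1:
        return n_chrom_types
    return n_chrom_types + n_chrom_types * (ploidy - 2)
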