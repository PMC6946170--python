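"""Inheritance-model tests on chromosome-genotype counts.

Each inheritance mode implies a probability vector over the five
distinguishable chromatid-combination classes, obtained by enumerating
the chromatid pairs the mode can retain from a single-crossover
bivalent.  Observed class counts are compared to a model by an exact
multinomial goodness-of-fit test (probability ordering: the p-value is
the total probability of tables no more probable than the observed
one), with a Monte Carlo fallback for large counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.stats import multinomial

from .classes import ChromosomeGenotype, DISTINGUISHABLE_CLASSES
from .genome import GenomeSpec
from .meiosis import (MaternalMode, PaternalFate, classify_pair_truth,
                      simulate_zygote)


class InheritanceModel(str, Enum):
    RANDOM_TWO = "random_two"        # any two of the four chromatids
    HOMOLOG_ONLY = "homolog_only"    # central-fusion automixis
    SISTER_ONLY = "sister_only"      # sister (terminal) fusion
    APOMIXIS = "apomixis"
    ENDOREPLICATION = "endoreplication"


def _reference_bivalent(length: int = 1_000_000, crossover: int = 200_000):
    """A deterministic single-crossover bivalent for pair enumeration."""
    from .genome import ORIGIN_J, ORIGIN_N
    from .meiosis import Bivalent, recombinant_chromatid, uniform_chromatid

    chromatids = {
        "N1": uniform_chromatid("ref", length, ORIGIN_N),
        "J2": uniform_chromatid("ref", length, ORIGIN_J),
        "N2": recombinant_chromatid("ref", length, ORIGIN_N, ORIGIN_J, crossover),
        "J1": recombinant_chromatid("ref", length, ORIGIN_J, ORIGIN_N, crossover),
    }
    # arm crossover in the left arm: cohesion (dyad identity) follows the
    # shared haplotype along the long right side
    return Bivalent("ref", length, crossover, chromatids,
                    (("N1", "J1"), ("J2", "N2")))


def expected_class_frequencies(model: InheritanceModel) -> dict[ChromosomeGenotype, float]:
    """Class probabilities implied by an inheritance model, by enumeration.

    The probabilities come from classifying every chromatid pair the
    model can retain from a reference bivalent, never from a hard-coded
    table.  Crossover position does not affect the class, only which
    side of the chromosome carries the terminal signature.
    """
    biv = _reference_bivalent()
    if model is InheritanceModel.RANDOM_TWO:
        pairs = biv.all_pairs()
    elif model is InheritanceModel.HOMOLOG_ONLY:
        pairs = biv.homologous_pairs()
    elif model is InheritanceModel.SISTER_ONLY:
        pairs = list(biv.dyads)
    elif model is InheritanceModel.APOMIXIS:
        pairs = [("N1", "J2")]  # two non-recombinant homologs = clone
    elif model is InheritanceModel.ENDOREPLICATION:
        pairs = [(k, k) for k in biv.chromatids]
    else:
        raise ValueError(f"unknown model {model!r}")

    freqs: dict[ChromosomeGenotype, float] = {}
    w = 1.0 / len(pairs)
    for a, b in pairs:
        cls = classify_pair_truth((biv.chromatids[a], biv.chromatids[b]))
        freqs[cls] = freqs.get(cls, 0.0) + w
    return freqs


def model_probability_vector(model: InheritanceModel) -> np.ndarray:
    """Probabilities over the five distinguishable classes, canonical order."""
    freqs = expected_class_frequencies(model)
    return np.array([freqs.get(c, 0.0) for c in DISTINGUISHABLE_CLASSES])


# ---------------------------------------------------------------------------
# exact multinomial goodness-of-fit
# ---------------------------------------------------------------------------

@dataclass
class GoFResult:
    observed: np.ndarray
    expected_probs: np.ndarray
    llr: float                       # log-likelihood-ratio statistic G
    p_value: float
    method: str                      # "exact" or "monte_carlo"
    seed: int | None = None
    model: str | None = None


def _log_likelihood_ratio(obs: np.ndarray, probs: np.ndarray) -> float:
    n = obs.sum()
    nz = obs > 0
    if np.any(nz & (probs <= 0)):
        return np.inf
    return float(2.0 * np.sum(obs[nz] * np.log(obs[nz] / (n * probs[nz]))))


def _compositions(n: int, k: int) -> np.ndarray:
    """All k-part compositions of n (stars and bars), as an array."""
    out = np.empty((0, k), dtype=np.int64)
    rows = []
    for bars in itertools.combinations(range(n + k - 1), k - 1):
        prev = -1
        row = []
        for b in (*bars, n + k - 1):
            row.append(b - prev - 1)
            prev = b
        rows.append(row)
    if rows:
        out = np.array(rows, dtype=np.int64)
    return out


_ENUM_CACHE: dict[tuple, np.ndarray] = {}


def _enumerated_logpmf(n: int, probs: np.ndarray) -> np.ndarray:
    """Log-probabilities of every outcome table, cached per (n, probs)."""
    key = (n, tuple(np.round(probs, 12)))
    if key not in _ENUM_CACHE:
        tables = _compositions(n, len(probs))
        _ENUM_CACHE[key] = multinomial(n, probs).logpmf(tables)
        if len(_ENUM_CACHE) > 32:
            _ENUM_CACHE.pop(next(iter(_ENUM_CACHE)))
    return _ENUM_CACHE[key]


def goodness_of_fit(observed, probs, max_exact_n: int = 60,
                    n_mc: int = 100_000, seed: int = 0,
                    model: str | None = None) -> GoFResult:
    """Exact multinomial goodness-of-fit by probability ordering.

    The p-value sums the probabilities of all outcome tables whose
    multinomial probability does not exceed the observed table's.  For
    n <= max_exact_n the sum runs over the full enumeration; beyond
    that, n_mc seeded Monte Carlo tables estimate it.  An observed
    count in a zero-probability category forces p = 0.
    """
    obs = np.asarray(observed, dtype=np.int64)
    probs = np.asarray(probs, dtype=float)
    if np.any(obs < 0):
        raise ValueError("negative counts")
    if obs.sum() < 1:
        raise ValueError("need at least one observation")
    probs = probs / probs.sum()
    n, k = int(obs.sum()), len(obs)
    llr = _log_likelihood_ratio(obs, probs)

    if np.any((obs > 0) & (probs <= 0.0)):
        return GoFResult(obs, probs, llr, 0.0, "exact", seed, model)

    dist = multinomial(n, probs)
    logp_obs = dist.logpmf(obs)
    tol = 1e-9
    if n <= max_exact_n:
        logp = _enumerated_logpmf(n, probs)
        mask = logp <= logp_obs + tol
        p = float(np.exp(logp[mask & np.isfinite(logp)]).sum())
        return GoFResult(obs, probs, llr, min(p, 1.0), "exact", seed, model)

    rng = np.random.default_rng(seed)
    samples = rng.multinomial(n, probs, size=n_mc)
    logp = dist.logpmf(samples)
    hits = int(np.sum(logp <= logp_obs + tol))
    p = (1 + hits) / (1 + n_mc)
    return GoFResult(obs, probs, llr, float(p), "monte_carlo", seed, model)


def compare_models(observed, models: list[InheritanceModel], **kwargs) -> list[GoFResult]:
    """Goodness-of-fit of one observed count vector against several models."""
    return [goodness_of_fit(observed, model_probability_vector(m), model=m.value, **kwargs)
            for m in models]


# ---------------------------------------------------------------------------
# embryo marker predictions
# ---------------------------------------------------------------------------

@dataclass
class MarkerPrediction:
    frac_heterozygous: float      # heterozygous N/J at the marker
    frac_paternal_x: float        # zygotes carrying the paternal X
    frac_maternal_only: float     # zygotes with no paternal DNA
    n_sim: int
    counts: dict = field(default_factory=dict)


_MODE_FOR_MODEL = {
    InheritanceModel.RANDOM_TWO: MaternalMode.RANDOM_TWO,
    InheritanceModel.HOMOLOG_ONLY: MaternalMode.CENTRAL_FUSION,
    InheritanceModel.SISTER_ONLY: MaternalMode.SISTER_FUSION,
    InheritanceModel.APOMIXIS: MaternalMode.APOMIXIS,
    InheritanceModel.ENDOREPLICATION: MaternalMode.ENDOREPLICATION,
}


def predict_embryo_markers(model: InheritanceModel, spec: GenomeSpec,
                           marker_chrom: str, marker_pos: int,
                           paternal: PaternalFate, n_sim: int = 10_000,
                           seed: int = 0) -> MarkerPrediction:
    """Forward-simulate zygotes and tally marker genotypes.

    Predicts the fraction of embryos heterozygous NIC59/JU1825 at a
    strain marker, the fraction inheriting the paternal X (0.5 for XO
    fathers), and the fraction without any paternal DNA.
    """
    L = spec.length(marker_chrom)
    if not 0 <= marker_pos < L:
        raise ValueError("marker outside chromosome")
    mode = _MODE_FOR_MODEL[model]
    rng = np.random.default_rng(seed)
    het = pat_x = mat_only = 0
    for _ in range(n_sim):
        z = simulate_zygote(spec, mode, paternal, rng)
        copies = z.maternal[marker_chrom]
        origins = {ct.origin_at(marker_pos) for ct in copies}
        het += (len(origins) > 1)
        pat_x += z.has_paternal_x(spec)
        mat_only += (not z.paternal)
    return MarkerPrediction(het / n_sim, pat_x / n_sim, mat_only / n_sim, n_sim,
                            counts={"heterozygous": het, "paternal_x": pat_x,
                                    "maternal_only": mat_only})
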