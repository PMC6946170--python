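"""Reproducible end-to-end runs: simulate -> genotype -> infer.

A single RunConfig drives everything; all randomness flows from one
root seed through named substreams so each stage is independently
reproducible.  Every output directory gets a JSON manifest carrying the
configuration hash, and downstream stages refuse inputs whose hashes
disagree.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .classes import ChromosomeGenotype, DISTINGUISHABLE_CLASSES
from .genome import GenomeSpec
from .genotyping import (CbsParams, StateBands, estimate_contamination,
                         genotype_chromosome, window_allele_freq)
from .inference import InheritanceModel, compare_models
from .karyotype import (becei_read_fraction, classify_chromosome,
                        classify_individual, normalize_and_call_copy_number)
from .meiosis import (MaternalMode, PaternalFate, PaternalFateKind,
                      simulate_zygote)
from .readsim import (ReadModel, SPECIES_MATERNAL, simulate_allele_depths,
                      simulate_coverage)

# substream indices: one child seed sequence per pipeline stage
_STAGE_SIM, _STAGE_GENO, _STAGE_INFER = 0, 1, 2


@dataclass
class RunConfig:
    seed: int = 0
    n_individuals: int = 10
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    mode_mix: dict[str, float] = field(
        default_factory=lambda: {MaternalMode.CENTRAL_FUSION.value: 1.0})
    paternal_mix: dict[str, float] = field(
        default_factory=lambda: {PaternalFateKind.NONE.value: 1.0})
    mosaic_fraction: float = 0.5          # used when paternal_mix draws MOSAIC
    p_X_loss: float = 0.0
    p_shared_spindle: float = 0.5
    read_model: ReadModel = field(default_factory=ReadModel)
    cbs: CbsParams = field(default_factory=CbsParams)
    bands: StateBands = field(default_factory=StateBands)
    estimate_contamination: bool = True
    models: list[str] = field(default_factory=lambda: [
        InheritanceModel.HOMOLOG_ONLY.value, InheritanceModel.RANDOM_TWO.value,
        InheritanceModel.SISTER_ONLY.value])

    def __post_init__(self) -> None:
        for mix in (self.mode_mix, self.paternal_mix):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("probability mix must sum to 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("genome"), dict):
            d["genome"] = GenomeSpec.from_dict(d["genome"])
        for key, typ in (("read_model", ReadModel), ("cbs", CbsParams),
                         ("bands", StateBands)):
            if isinstance(d.get(key), dict):
                d[key] = typ(**d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(gio.read_json(path))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _draw_from_mix(mix: dict[str, float], rng: np.random.Generator) -> str:
    keys = sorted(mix)
    probs = np.array([mix[k] for k in keys])
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def _stage_rng(config: RunConfig, stage: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(config.seed).spawn(3)[stage]


# ---------------------------------------------------------------------------
# stage 1: simulate
# ---------------------------------------------------------------------------

def cmd_simulate(config: RunConfig, out_dir: str | Path) -> dict:
    """Simulate a cohort; write truth tracks, allele depths, and coverage.

    Returns the manifest (also written to ``manifest.json``).
    Byte-identical outputs for identical configurations.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    ss = _stage_rng(config, _STAGE_SIM)
    individuals = []
    for i, child in enumerate(ss.spawn(config.n_individuals)):
        rng = np.random.default_rng(child)
        mode = MaternalMode(_draw_from_mix(config.mode_mix, rng))
        kind = PaternalFateKind(_draw_from_mix(config.paternal_mix, rng))
        fate = PaternalFate(kind, mosaic_fraction=(
            config.mosaic_fraction if kind is PaternalFateKind.MOSAIC else None))
        zygote = simulate_zygote(config.genome, mode, fate, rng,
                                 p_X_loss=config.p_X_loss,
                                 p_shared_spindle=config.p_shared_spindle)
        depths = simulate_allele_depths(zygote, config.genome, config.read_model, rng)
        coverage = simulate_coverage(zygote, config.genome, config.read_model, rng)

        name = f"ind_{i:03d}"
        gio.write_truth_bed(zygote, out / f"{name}.truth.bed")
        gio.write_depths_tsv(depths, out / f"{name}.depths.tsv")
        gio.write_depths_vcf(depths, out / f"{name}.depths.vcf", sample=name)
        gio.write_coverage_bed(coverage, out / f"{name}.cov.nouraguensis.bed",
                               out / f"{name}.cov.becei.bed")
        sidecar = {
            "individual": name, "mode": mode.value, "paternal_fate": kind.value,
            "zygote_fate": zygote.fate.value, "fate_reason": zygote.fate_reason,
            "polar_bodies": zygote.polar_bodies,
            "mosaic_fraction": zygote.mosaic_fraction,
            "paternal_chromosomes": zygote.paternal,
            "seed": config.seed, "config_hash": chash,
        }
        gio.write_json(sidecar, out / f"{name}.json")
        individuals.append(sidecar)

    manifest = {"config_hash": chash, "config": config.to_dict(),
                "n_individuals": config.n_individuals,
                "individuals": individuals}
    gio.write_json(manifest, out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stage 2: genotype + karyotype
# ---------------------------------------------------------------------------

def genotype_individual(depths: pd.DataFrame, coverage: pd.DataFrame,
                        config: RunConfig, seed: int | None = None) -> dict:
    """Windows, segments, per-chromosome classes and individual summary."""
    spec = config.genome
    seed = config.seed if seed is None else seed
    windows = window_allele_freq(depths, spec)
    c_hat = 0.0
    if config.estimate_contamination:
        try:
            c_hat = estimate_contamination(
                windows, config.read_model.contaminant_origin)
        except ValueError:
            c_hat = 0.0
    copy_calls = normalize_and_call_copy_number(coverage)
    cn_by_chrom = {c.chrom: c.copy_number for c in copy_calls
                   if c.species == SPECIES_MATERNAL}

    all_segments = []
    genotypes: dict[str, ChromosomeGenotype] = {}
    for ci, chrom_spec in enumerate(spec.chromosomes):
        wsub = windows[windows["chrom"] == chrom_spec.id]
        segs = genotype_chromosome(
            wsub, config.cbs, config.bands, c_hat,
            config.read_model.contaminant_origin,
            seed=(seed * 31 + ci) % (2**31))
        genotypes[chrom_spec.id] = classify_chromosome(
            segs, cn_by_chrom.get(chrom_spec.id, 2))
        all_segments.extend(segs)

    frac = becei_read_fraction(coverage)
    summary = classify_individual(genotypes, copy_calls, frac, spec)
    return {"windows": windows, "segments": all_segments,
            "contamination": c_hat, "genotypes": genotypes,
            "copy_calls": copy_calls, "summary": summary}


def cmd_genotype(depths_path: str | Path, cov_maternal: str | Path,
                 cov_paternal: str | Path, config: RunConfig,
                 out_dir: str | Path, expect_hash: str | None = None) -> dict:
    """Genotype one individual from files; write windows, segments, summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    depths_path = Path(depths_path)
    sidecar = depths_path.with_suffix("").with_suffix(".json")
    if expect_hash is not None and sidecar.exists():
        found = gio.read_json(sidecar).get("config_hash")
        if found != expect_hash:
            raise ValueError(
                f"config hash mismatch: inputs carry {found}, run expects {expect_hash}")
    if depths_path.suffix == ".vcf":
        depths = gio.read_depths_vcf(depths_path)
    else:
        depths = gio.read_depths_tsv(depths_path)
    coverage = gio.read_coverage_bed(cov_maternal, cov_paternal)
    result = genotype_individual(depths, coverage, config)

    name = depths_path.name.split(".")[0]
    result["windows"].to_csv(out / f"{name}.windows.tsv", sep="\t", index=False)
    gio.write_segments_bed(result["segments"], out / f"{name}.segments.bed")
    summary = result["summary"]
    cn = {(c.species, c.chrom): c for c in result["copy_calls"]}
    karyo_rows = []
    for chrom, cls in result["genotypes"].items():
        mat = cn.get((SPECIES_MATERNAL, chrom))
        pat = cn.get(("becei", chrom))
        karyo_rows.append({
            "chrom": chrom, "class": cls.value,
            "maternal_copy_number": mat.copy_number if mat else "",
            "paternal_mosaic_fraction": (round(pat.mosaic_fraction, 4)
                                         if pat and pat.mosaic_fraction is not None
                                         else "")})
    pd.DataFrame(karyo_rows).to_csv(out / f"{name}.karyotype.tsv",
                                    sep="\t", index=False)
    gio.write_json({
        "individual": name,
        "genotypes": {k: v.value for k, v in result["genotypes"].items()},
        "copy_calls": [dataclasses.asdict(c) for c in result["copy_calls"]],
        "becei_fraction": summary.becei_fraction,
        "category": summary.category,
        "paternal_x_present": summary.paternal_x_present,
        "maternal_x_copies": summary.maternal_x_copies,
        "contamination_estimate": result["contamination"],
        "config_hash": config.config_hash(),
        "thresholds": {"cbs": dataclasses.asdict(config.cbs),
                       "bands": dataclasses.asdict(config.bands)},
    }, out / f"{name}.summary.json")
    return result


# ---------------------------------------------------------------------------
# stage 3: inference
# ---------------------------------------------------------------------------

def tally_classes(genotypes_list: list[dict[str, ChromosomeGenotype]],
                  spec: GenomeSpec) -> np.ndarray:
    """Count distinguishable classes over individuals' autosomes.

    Hemizygous X, triploid, and ambiguous chromosomes are excluded from
    the tally, as are X chromosomes.
    """
    counts = {c: 0 for c in DISTINGUISHABLE_CLASSES}
    for genotypes in genotypes_list:
        for chrom, cls in genotypes.items():
            if chrom == spec.x_id:
                continue
            if cls in counts:
                counts[cls] += 1
    return np.array([counts[c] for c in DISTINGUISHABLE_CLASSES])


def cmd_infer(counts, models: list[str], out_path: str | Path | None = None,
              seed: int = 0, **kwargs) -> list:
    """Goodness-of-fit of observed class counts against inheritance models."""
    results = compare_models(np.asarray(counts),
                             [InheritanceModel(m) for m in models],
                             seed=seed, **kwargs)
    if out_path is not None:
        gio.write_json({
            "classes": [c.value for c in DISTINGUISHABLE_CLASSES],
            "observed": list(map(int, np.asarray(counts))),
            "results": [{
                "model": r.model, "p_value": r.p_value, "llr": r.llr,
                "method": r.method,
                "expected_probs": r.expected_probs,
            } for r in results],
        }, out_path)
    return results


def simulate_class_counts(mode: MaternalMode, n_chromosomes: int, seed: int,
                          length: int = 5_000_000,
                          read_model: ReadModel | None = None,
                          cbs: CbsParams | None = None,
                          bands: StateBands | None = None) -> np.ndarray:
    """Run n chromosomes through meiosis + sequencing + genotyping; tally classes.

    Each chromosome is an independent bivalent under ``mode``; its
    retained pair is sequenced, windowed, segmented, and classified.
    Chromosomes falling outside the five distinguishable classes
    (ambiguous calls) are excluded from the tally.
    """
    from .genome import ChromosomeSpec

    spec = GenomeSpec(chromosomes=[ChromosomeSpec("chr1", length)])
    read_model = read_model or ReadModel()
    counts = {c: 0 for c in DISTINGUISHABLE_CLASSES}
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_chromosomes):
        rng = np.random.default_rng(child)
        zygote = simulate_zygote(spec, mode,
                                 PaternalFate(PaternalFateKind.NONE, include_X=False),
                                 rng)
        depths = simulate_allele_depths(zygote, spec, read_model, rng)
        windows = window_allele_freq(depths, spec)
        segs = genotype_chromosome(windows, cbs, bands,
                                   seed=int(rng.integers(2**31)))
        cls = classify_chromosome(segs, 2)
        if cls in counts:
            counts[cls] += 1
    return np.array([counts[c] for c in DISTINGUISHABLE_CLASSES])


def read_class_counts(path: str | Path) -> np.ndarray:
    """Read a class-count TSV with columns ``class`` and ``count``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("class", "count"):
        if col not in df.columns:
            raise gio.FormatError(f"{path}: missing column {col!r}")
    lut = dict(zip(df["class"], df["count"]))
    return np.array([int(lut.get(c.value, 0)) for c in DISTINGUISHABLE_CLASSES])
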