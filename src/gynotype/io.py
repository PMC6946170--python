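"""Readers and writers for the pipeline's plain-text formats.

Allele depths travel as TSV or as VCF with a per-sample AD field
(REF encodes the NIC59 allele, ALT the JU1825 allele); coverage as
BED4 (one file per reference species); segments as BED; run metadata
as JSON sidecars carrying the configuration hash.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotyping import Segment
from .readsim import COVERAGE_COLUMNS, DEPTH_COLUMNS


class FormatError(ValueError):
    """Malformed input file, with file and line context."""


# ---------------------------------------------------------------------------
# allele depths: TSV and VCF(AD)
# ---------------------------------------------------------------------------

def write_depths_tsv(depths: pd.DataFrame, path: str | Path) -> None:
    depths.to_csv(path, sep="\t", index=False, columns=DEPTH_COLUMNS)


def read_depths_tsv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in DEPTH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df[DEPTH_COLUMNS]


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=gynotype
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depths: NIC59 (REF), JU1825 (ALT)">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_depths_vcf(depths: pd.DataFrame, path: str | Path,
                     sample: str = "worm") -> None:
    """Write allele depths as a plain VCF with an AD-carrying sample column.

    Fixed differences are encoded with placeholder bases: REF is the
    NIC59 allele, ALT the JU1825 allele.  Positions are converted to
    VCF's 1-based convention.
    """
    contigs = "".join(
        f"##contig=<ID={c}>\n" for c in pd.unique(depths["chrom"]))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs, sample=sample))
        for row in depths.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos + 1}\t.\tA\tT\t.\tPASS\t.\t"
                     f"GT:AD\t./.:{row.depth_N},{row.depth_J}\n")


def read_depths_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF with AD back into an allele-depth table (0-based positions)."""
    _validate_vcf_structure(path)
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        ad = v.format("AD")
        if ad is None:
            raise FormatError(f"{path}: record {v.CHROM}:{v.POS} lacks AD")
        rows.append((v.CHROM, v.POS - 1, int(ad[0][0]), int(ad[0][1])))
    return pd.DataFrame(rows, columns=DEPTH_COLUMNS)


def _validate_vcf_structure(path: str | Path) -> None:
    """Cheap structural scan so malformed lines are reported by number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            nfields = len(line.rstrip("\n").split("\t"))
            if nfields < 10:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 10 tab-separated "
                    f"fields, found {nfields}")


# ---------------------------------------------------------------------------
# coverage: BED4 per species
# ---------------------------------------------------------------------------

def write_coverage_bed(coverage: pd.DataFrame, path_maternal: str | Path,
                       path_paternal: str | Path) -> None:
    from .readsim import SPECIES_MATERNAL, SPECIES_PATERNAL

    for species, path in ((SPECIES_MATERNAL, path_maternal),
                          (SPECIES_PATERNAL, path_paternal)):
        sub = coverage[coverage["species"] == species]
        sub[["chrom", "start", "end", "depth"]].to_csv(
            path, sep="\t", index=False, header=False,
            float_format="%.6g")


def read_coverage_bed(path_maternal: str | Path,
                      path_paternal: str | Path) -> pd.DataFrame:
    from .readsim import SPECIES_MATERNAL, SPECIES_PATERNAL

    frames = []
    for species, path in ((SPECIES_MATERNAL, path_maternal),
                          (SPECIES_PATERNAL, path_paternal)):
        try:
            df = pd.read_csv(path, sep="\t", header=None,
                             names=["chrom", "start", "end", "depth"])
        except Exception as exc:
            raise FormatError(f"{path}: cannot parse BED4 ({exc})") from exc
        if df[["start", "end", "depth"]].isna().any().any():
            bad = int(df[["start", "end", "depth"]].isna().any(axis=1).idxmax()) + 1
            raise FormatError(f"{path}: line {bad}: non-numeric BED4 fields")
        df.insert(0, "species", species)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)[COVERAGE_COLUMNS]


# ---------------------------------------------------------------------------
# segments and truth tracks
# ---------------------------------------------------------------------------

def write_segments_bed(segments: list[Segment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            mean = "NA" if np.isnan(s.mean_freq) else f"{s.mean_freq:.4f}"
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{mean}\t{s.state}\n")


def read_segments_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "mean_freq", "state"],
                     na_values=["NA"])
    return df


def write_truth_bed(zygote, path: str | Path) -> None:
    """Zygote truth as a BED-like haplotype track (one line per block union)."""
    with open(path, "w") as fh:
        for chrom, copies in zygote.maternal.items():
            bounds = sorted({b[0] for ct in copies for b in ct.blocks}
                            | {copies[0].length})
            for start, end in zip(bounds[:-1], bounds[1:]):
                origins = "\t".join(ct.origin_at(start) for ct in copies)
                fh.write(f"{chrom}\t{start}\t{end}\t{origins}\n")


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "value"):
        return o.value
    raise TypeError(f"not JSON serializable: {type(o)}")
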