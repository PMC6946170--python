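#!/usr/bin/env python
"""Model predictions for the cytological and embryo-marker observations.

Computes the DAPI-staining body counts expected for diploid and triploid
oocytes, the polar-body distribution under meiosis-I failure, the
fraction of embryos inheriting the paternal X from XO fathers, and the
heterozygosity of a central strain marker under competing inheritance
modes."""

import json
from pathlib import Path

import numpy as np

from gynotype import (GenomeSpec, InheritanceModel, MaternalMode,
                      PaternalFate, PaternalFateKind, count_dapi_bodies,
                      make_bivalent, predict_embryo_markers, scaled_genome,
                      select_maternal_chromatids)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = {}
    out["dapi_bodies_diploid"] = count_dapi_bodies(2, 6)
    out["dapi_bodies_triploid"] = count_dapi_bodies(3, 6)
    print(f"cytology: diploid oocytes show {out['dapi_bodies_diploid']} "
          f"DAPI bodies, triploid {out['dapi_bodies_triploid']}")

    spec = scaled_genome(8_000_000)
    rng = np.random.default_rng(11)
    biv = make_bivalent(spec, "chr1", rng)
    n = 10_000
    one_pb = sum(select_maternal_chromatids(
        biv, MaternalMode.CENTRAL_FUSION, rng, p_shared_spindle=0.5)[1] == 1
        for _ in range(n))
    out["frac_one_polar_body_central_fusion"] = one_pb / n
    print(f"polar bodies: central fusion yields one polar body in "
          f"{one_pb / n:.3f} of oocytes (shared-spindle probability 0.5)")

    pred = predict_embryo_markers(InheritanceModel.HOMOLOG_ONLY, spec, "chr1",
                                  spec.length("chr1") // 2,
                                  PaternalFate(PaternalFateKind.FULL),
                                  n_sim=10_000, seed=11)
    out["frac_paternal_x"] = pred.frac_paternal_x
    out["frac_central_marker_het_homolog_only"] = pred.frac_heterozygous
    print(f"embryo markers: {pred.frac_paternal_x:.3f} of fertilizations carry "
          f"the paternal X (XO fathers); central marker heterozygous in "
          f"{pred.frac_heterozygous:.3f} under homolog-only inheritance")

    pred_sis = predict_embryo_markers(InheritanceModel.SISTER_ONLY, spec, "chr1",
                                      spec.length("chr1") // 2,
                                      PaternalFate(PaternalFateKind.NONE),
                                      n_sim=10_000, seed=12)
    out["frac_central_marker_het_sister_only"] = pred_sis.frac_heterozygous
    print(f"  under sister-only inheritance the central marker is heterozygous "
          f"in only {pred_sis.frac_heterozygous:.3f} of embryos")

    (OUT / "cytology_predictions.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
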