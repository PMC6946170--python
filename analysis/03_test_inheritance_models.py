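#!/usr/bin/env python
"""Test the cohort's chromosome-class counts against inheritance models.

Tallies the five distinguishable classes over the genotyped cohort's
autosomes (ambiguous, hemizygous-X and triploid chromosomes excluded)
and runs the exact multinomial goodness-of-fit against the candidate
inheritance modes.  Under central-fusion automixis the homolog-only
model should be retained and sister-only/apomixis rejected."""

import json
from pathlib import Path

import pandas as pd

from gynotype import (DISTINGUISHABLE_CLASSES, InheritanceModel, cmd_infer,
                      scaled_genome)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = pd.read_csv(OUT / "cohort_classes.tsv", sep="\t")
    spec = scaled_genome(8_000_000)
    auto = table[table["chrom"] != spec.x_id]
    counts = [int((auto["class"] == c.value).sum()) for c in DISTINGUISHABLE_CLASSES]
    print("observed autosome class counts "
          f"({[c.value for c in DISTINGUISHABLE_CLASSES]}): {counts} "
          f"(n = {sum(counts)}; {len(auto) - sum(counts)} excluded as ambiguous)")

    models = [m.value for m in (InheritanceModel.HOMOLOG_ONLY,
                                InheritanceModel.RANDOM_TWO,
                                InheritanceModel.SISTER_ONLY,
                                InheritanceModel.APOMIXIS)]
    results = cmd_infer(counts, models, OUT / "inheritance_gof.json", seed=1)
    for r in results:
        verdict = "retained" if r.p_value > 0.05 else "rejected"
        print(f"  {r.model:<14} p = {r.p_value:.4g} ({r.method}) -> {verdict}")


if __name__ == "__main__":
    main()
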