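"""Duration dispersion, kinship correlations and condition effect sizes.

Computes, per condition: the median and IDR/median of the pooled complete
durations, subsampled Spearman correlations (60 pairs × 100 repetitions)
for mother–daughter, sibling and granddaughter (cousin) pairs, and the
rz-score between the two conditions' duration distributions.

Outputs under results/: correlations.tsv, condition_summary.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import lineagemotifs as lm
from lineagemotifs.io import read_lineage_table
from lineagemotifs.stats import (RELATIONS, condition_summary, relation_pairs,
                                 subsampled_spearman)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    rng = np.random.default_rng(args.seed)

    forests = {
        cond: lm.build_forest(
            read_lineage_table(RESULTS / "data" / f"{cond}_lineages.csv"))
        for cond in ("null", "alt", "short")
    }

    rows = []
    for cond, forest in forests.items():
        for rel in RELATIONS:
            pairs = relation_pairs(forest, rel)
            if len(pairs) < 60:
                print(f"{cond}/{rel}: only {len(pairs)} pairs, skipped")
                continue
            rhos = subsampled_spearman(pairs, 60, 100, rng)
            rows.append({"condition": cond, "relation": rel,
                         "n_pairs": len(pairs),
                         "median_rho": float(np.median(rhos)),
                         "rho_q1": float(np.percentile(rhos, 25)),
                         "rho_q3": float(np.percentile(rhos, 75))})
            print(f"{cond}/{rel}: n={len(pairs)} pairs, "
                  f"median Spearman rho {np.median(rhos):+.3f}")
    pd.DataFrame(rows).to_csv(RESULTS / "correlations.tsv", sep="\t", index=False)

    durations = {cond: [c.duration for c in f.complete_cells()]
                 for cond, f in forests.items()}
    table = condition_summary(durations, reference="null")
    table.to_csv(RESULTS / "condition_summary.tsv", sep="\t")
    print(table.round(3))
    print("(rz near 1 between the null and reduced-variability conditions "
          "means their medians differ by about one MAD - a clear effect)")


if __name__ == "__main__":
    main()
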