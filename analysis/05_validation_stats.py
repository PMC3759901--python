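#!/usr/bin/env python
"""Validation-style statistics on simulated follow-up experiments.

Three analyses mirror how small-cohort filtering results are typically
verified: (1) an independent 12-patient single-tube PCR cohort for five
selected miRNAs, quantified relative to the housekeeping miRNA
hsa-miR-191-5p and tested with paired t-tests (α = 0.10 screen);
(2) cross-platform concordance of the card signals with a replicate
intensity measurement, summarized by Spearman's rho; (3) the heat-map
layout (row z-scores, single-linkage 1−Pearson clustering) of the
filtered features at baseline versus one month.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from maidflow import (
    PreprocessParams,
    cluster_heatmap,
    paired_t_table,
    read_matrix,
    relative_quantify,
    spearman_rho,
)
from maidflow.simulate import simulate_single_tube

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"
PARAMS = PreprocessParams()
FLOOR = PARAMS.floor_signal


def single_tube_validation() -> None:
    # five candidates: three planted down, one planted up, one null
    effects = {"val-miR-a": -1.2, "val-miR-b": -0.9, "val-miR-c": -0.8, "val-miR-d": 0.7, "val-miR-e": 0.0}
    ct = simulate_single_tube(list(effects), effects, n_patients=12, seed=101)
    rel = relative_quantify(ct, PARAMS)
    base_cols = [c for c, (_, t) in rel.design.sample_map.items() if t == "baseline"]
    m1_cols = [c for c, (_, t) in rel.design.sample_map.items() if t == "m1"]
    before = rel.values[base_cols]
    after = rel.values[m1_cols]
    before.columns = after.columns = [c.split("_")[0] for c in base_cols]
    table = paired_t_table(before, after, alpha=0.10)
    table.to_csv(ROOT / "validation_ttests.tsv", sep="\t")
    print("single-tube validation (12 patients, paired t-tests, α = 0.10):")
    print(table.drop(index="hsa-miR-191-5p").to_string())


def cross_platform_concordance() -> None:
    # replicate measurement of the filtered miRNAs on a second platform:
    # shared true signal, platform-specific noise and compression
    cards = read_matrix(DATA / "mirna_cards.norm.tsv", DATA / "mirna_cards.samples.csv", scale="linear")
    filtered = pd.read_csv(ROOT / "mirna_cards.filtered.csv")["feature"].tolist()
    rng = np.random.default_rng(7)
    cols = [
        cards.design.column_for(p, t)
        for p in cards.design.patients[:3]
        for t in ("baseline", "m1")
    ]
    card_log2 = np.log2(cards.values.loc[filtered, cols].clip(lower=FLOOR))
    # second platform: compressed measurement range, substantial noise
    replica = 0.6 * card_log2 + rng.normal(0, 1.3, card_log2.shape)
    rho = spearman_rho(card_log2.to_numpy().ravel(), replica.to_numpy().ravel())
    n_pairs = card_log2.size
    print(f"cross-platform concordance: Spearman rho = {rho:.3f} over {n_pairs} data pairs")
    with open(ROOT / "concordance.json", "w") as fh:
        json.dump({"spearman_rho": rho, "n_pairs": int(n_pairs)}, fh, indent=2)


def heatmap_layout() -> None:
    cards = read_matrix(DATA / "mirna_cards.norm.tsv", DATA / "mirna_cards.samples.csv", scale="linear")
    filtered = pd.read_csv(ROOT / "mirna_cards.filtered.csv")["feature"].tolist()
    cols = [c for c, (_, t) in cards.design.sample_map.items() if t in ("baseline", "m1")]
    sub = np.log2(cards.values.loc[sorted(set(filtered)), cols].clip(lower=FLOOR))
    layout = cluster_heatmap(sub)
    with open(ROOT / "heatmap_layout.json", "w") as fh:
        json.dump(
            {
                "row_order": layout.row_order,
                "column_order": layout.column_order,
                "constant_rows": layout.constant_rows,
            },
            fh,
            indent=2,
        )
    left, right = layout.column_subtrees()
    print(f"heat-map columns split into {sorted(left)} | {sorted(right)}")


def main() -> None:
    single_tube_validation()
    cross_platform_concordance()
    heatmap_layout()


if __name__ == "__main__":
    main()
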