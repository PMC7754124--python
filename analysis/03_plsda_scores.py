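#!/usr/bin/env python
"""PLS-DA score plots of the four class contrasts.

Fits a 2-component NIPALS PLS-DA per contrast (tumour vs non-tumour in
each arm, HCC vs MFCCC, and non-tumour arm vs non-tumour arm) and writes
the score tables plus a silhouette-based separation summary.  The last
contrast is the negative control: the two non-tumour groups carry no
class effect, so their silhouette should sit near zero while the tumour
contrasts separate clearly.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from pesiml.io import read_feature_matrix
from pesiml.plsda import plsda_fit, scores_table

ROOT = Path(__file__).resolve().parents[1]

CONTRASTS = {
    "hcc_vs_nt": lambda m: (m["cohort"] == "HCC_cohort", m["tissue_label"]),
    "mfccc_vs_nt": lambda m: (m["cohort"] == "MFCCC_cohort", m["tissue_label"]),
    "hcc_vs_mfccc": lambda m: (m["tissue_label"] != "NONTUMOUR", m["tissue_label"]),
    "nt_vs_nt": lambda m: (m["tissue_label"] == "NONTUMOUR", m["cohort"]),
}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--features", type=Path,
                    default=ROOT / "scratch" / "cohort" / "features.tsv")
    args = ap.parse_args()

    fm = read_feature_matrix(args.features)
    meta = fm.row_meta
    (ROOT / "results").mkdir(exist_ok=True)
    rows = []
    for name, pick in CONTRASTS.items():
        mask, label_col = pick(meta)
        mask = np.asarray(mask)
        labels = np.asarray(label_col)[mask]
        model = plsda_fit(fm.select(mask), labels=labels, n_components=2)
        tab = scores_table(model, 1, 2)
        tab.to_csv(ROOT / "results" / f"plsda_scores_{name}.tsv", sep="\t", index=False)
        sil = float(silhouette_score(model.T, labels))
        rows.append((name, sil, *(100 * model.explained_x_variance)))
        print(f"{name:14s} silhouette {sil:+.3f}  "
              f"explained X-var {100 * model.explained_x_variance[0]:.1f}% / "
              f"{100 * model.explained_x_variance[1]:.1f}%")
    pd.DataFrame(
        rows, columns=["contrast", "silhouette", "explained_pc1_pct", "explained_pc2_pct"]
    ).to_csv(ROOT / "results" / "plsda_separation.csv", index=False)


if __name__ == "__main__":
    main()
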