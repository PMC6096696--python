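#!/usr/bin/env python
"""Confront the observed medians with the three candidate models.

Computes per-pair predictions for CIE luminance contrast, CIEDE2000, raw
RGB-cube distance (and the colour-circle step distance), correlates each
with the normalised observer medians (Kendall tau-b and Pearson r, per
condition and pooled), and writes the 6x6 array plots and yellow-fiducial
hexagon weights for data and models.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pointillism import analysis as an, render_io
from pointillism.colour import DisplayCalibration

OUT = Path("results")


def main() -> None:
    cal = DisplayCalibration()
    norm = pd.read_csv(OUT / "responses_normalized.csv")

    comparison = an.compare_models(norm, cal)
    comparison.to_csv(OUT / "model_comparison.csv", index=False)
    pooled = comparison[comparison["condition"] == "pooled"]
    print("pooled correlations with observed medians:")
    print(pooled[["model", "kendall_tau", "pearson_r"]].round(3).to_string(index=False))

    observed = norm.groupby("pair")["normalized_contrast"].median().to_dict()
    panels = {"observed": observed}
    panels.update({m: an.model_predictions(m, cal) for m in an.MODEL_NAMES})
    matrix_rows = []
    for name, values in panels.items():
        pm = an.pair_matrix(values)
        render_io.write_image(OUT / f"matrix_{name}.png", np.kron(pm.grey, np.ones((32, 32))))
        for i, a in enumerate(pm.labels):
            for j, b in enumerate(pm.labels):
                matrix_rows.append({"panel": name, "row": a, "col": b, "value": pm.values[i, j]})
        w = an.hexagon_summary("Y", values)
        print(f"{name:>18} hexagon weights from Y: "
              + " ".join(f"{k}={v:.2f}" for k, v in w.items()))
    pd.DataFrame(matrix_rows).to_csv(OUT / "pair_matrices.csv", index=False)
    print(f"wrote model comparison, matrices and PNG panels under {OUT}/")


if __name__ == "__main__":
    main()
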