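#!/usr/bin/env python
"""Normalise observers and check inter-observer concordance.

Reads results/responses.csv (run 03 first), removes each observer's
idiosyncratic offset and slope against the cross-observer cell medians,
reports pairwise Kendall tau-b concordance, and writes per-pair quartile
summaries plus the fitted linear N_t/N_v distinctiveness model.
"""

from pathlib import Path

from pointillism import analysis as an, render_io
from pointillism.transitions import fit_distinctiveness

OUT = Path("results")


def main() -> None:
    table = render_io.read_responses(OUT / "responses.csv")
    norm = an.normalize_observers(table)
    norm.table.to_csv(OUT / "responses_normalized.csv", index=False)
    norm.observer_fits.to_csv(OUT / "observer_fits.csv")
    print("per-observer idiosyncrasies (raw responses vs cross-observer medians):")
    print(norm.observer_fits.round(3).to_string())

    conc = an.concordance(table)
    conc["masked"].round(3).to_csv(OUT / "concordance_tau.csv")
    print(f"\nmedian inter-observer Kendall tau (raw): {conc['median_tau']:.3f}")
    conc_n = an.concordance(norm.table, response_col="normalized_contrast")
    print(f"median inter-observer Kendall tau (normalised): {conc_n['median_tau']:.3f}")

    summary = an.summarize_pairs(norm.table)
    summary.to_csv(OUT / "pair_summary.csv", index=False)
    cls = (
        summary[summary["pair"] == "(all)"]
        .groupby("pair_class")[["q1", "median", "q3"]]
        .median()
        .round(3)
    )
    print("\nquartiles by pair class (normalised contrast):")
    print(cls.to_string())

    fit = fit_distinctiveness(norm.table, response_col="normalized_contrast")
    print(
        f"\nlinear model fit: D = {fit.a0:.3f} + {fit.a_t:.3f} N_t {fit.a_v:+.3f} N_v"
        f"  (median |resid| {fit.median_abs_error:.3f}, max {fit.max_abs_error:.3f})"
    )
    print(f"wrote normalised table, fits and summaries under {OUT}/")


if __name__ == "__main__":
    main()
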