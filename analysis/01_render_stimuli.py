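#!/usr/bin/env python
"""Render example bipartite pointillist stimuli.

One yellow-blue stimulus per condition (hard/soft edge x monochromatic/
polychromatic gamut) plus an achromatic reference at 50% nominal contrast.
Writes PNGs and per-dot metadata CSVs under results/stimuli/ and reports the
realised background coverage for each.
"""

from pathlib import Path

from pointillism import render_io, stimulus as st

OUT = Path("results/stimuli")
SEED = 20260901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    specs = {"achromatic_hard": st.StimulusSpec(pair=st.achromatic_means(0.5), seed=SEED)}
    for edge in ("hard", "soft"):
        for kind in ("monochromatic", "polychromatic"):
            specs[f"YB_{edge}_{kind}"] = st.StimulusSpec(
                pair=("Y", "B"), gamut=st.GamutSpec(kind=kind), edge_type=edge, seed=SEED
            )
    for name, spec in specs.items():
        image, layout, meta = st.render(spec)
        render_io.write_image(OUT / f"{name}.png", image)
        meta.to_csv(OUT / f"{name}_dots.csv", index=False)
        unc = st.uncovered_fraction(layout, spec.region)
        print(
            f"{name}: {len(meta)} dots, uncovered {unc:.3f} "
            f"(target {spec.uncovered_fraction}), wrote {OUT / name}.png"
        )


if __name__ == "__main__":
    main()
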