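#!/usr/bin/env python
"""Monochrome renderings of a polychromatic stimulus.

Renders one yellow-blue polychromatic stimulus and maps it to grey under
four tone mappings — straight luminance, the max rule, the yellow-blue hue
diameter, and a freestyle channel mixer — illustrating that equally valid
monochrome interpretations of the same chromatic texture differ radically.
"""

from pathlib import Path

from pointillism import render_io as io, stimulus as st
from pointillism.colour import CARDINAL_INDEX, DisplayCalibration

OUT = Path("results/grayscale")
SEED = 20260901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cal = DisplayCalibration()
    spec = st.StimulusSpec(
        pair=("Y", "B"), gamut=st.GamutSpec(kind="polychromatic"), edge_type="hard", seed=SEED
    )
    image, _, _ = st.render(spec, cal)
    io.write_image(OUT / "stimulus.png", image)
    mappings = {
        "luminance": io.ToneMapping("luminance"),
        "max_rule": io.ToneMapping("max_rule"),
        "hue_diameter_Y": io.ToneMapping("hue_diameter", axis_hue=float(CARDINAL_INDEX["Y"])),
        "channel_mixer": io.ToneMapping("channel_mixer", weights=(0.6, 0.1, 0.3)),
    }
    for name, tm in mappings.items():
        grey = io.to_grayscale(image, tm, cal)
        io.write_image(OUT / f"{name}.png", grey)
        print(f"{name}: grey range [{grey.min():.2f}, {grey.max():.2f}], "
              f"left/right mean {grey[:, :256].mean():.2f}/{grey[:, 256:].mean():.2f}")
    print(f"wrote renderings under {OUT}/")


if __name__ == "__main__":
    main()
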