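#!/usr/bin/env python
"""CIEDE2000 triangle-inequality Monte Carlo.

Samples 100,000 colour triples uniformly in the encoded RGB cube, maps them
to L*a*b* (sRGB primaries, D65 white, pure gamma-2.2 decode), and estimates
how often the direct CIEDE2000 route between two colours exceeds the detour
via the third — the same comparison as the green-cyan-magenta example.
Also reports the any-side count for contrast.
"""

import json
from pathlib import Path

import numpy as np

from pointillism.analysis import triangle_inequality_mc
from pointillism.colour import DisplayCalibration, ciede2000, rgb_to_lab

OUT = Path("results")
SEED = 20260901
N = 100_000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cal = DisplayCalibration()
    lg, lc, lm = (rgb_to_lab(c, cal) for c in ((0, 1, 0), (0, 1, 1), (1, 0, 1)))
    detour = ciede2000(lg, lc) + ciede2000(lc, lm)
    direct = ciede2000(lg, lm)
    print(f"green-cyan-magenta detour: {detour:.1f} < direct green-magenta: {direct:.1f}")

    results = {}
    for mode in ("path", "any"):
        res = triangle_inequality_mc(N, cal, np.random.default_rng(SEED), mode=mode)
        results[mode] = {"percent": res.percent, "se_percent": 100 * res.standard_error, "n": res.n}
        print(f"violations ({mode} count): {res.percent:.2f}% "
              f"+/- {100 * res.standard_error:.2f}% of {res.n} triangles")
    (OUT / "triangle_mc.json").write_text(json.dumps(results, indent=2) + "\n")
    print(f"wrote {OUT / 'triangle_mc.json'}")


if __name__ == "__main__":
    main()
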