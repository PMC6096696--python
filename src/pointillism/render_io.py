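"""Monochrome rendering operators and file plumbing.

Tone mappings turn an RGB raster into a single channel:

* ``luminance`` — the pixel's luminance as a fraction of display white;
* ``max_rule`` — the maximum encoded coordinate (all cardinals map to 1);
* ``hue_diameter`` — signed projection of the pixel's position in the
  chromatic hexagon onto the diameter through a chosen hue, rescaled to
  [0, 1]; the axis hue and its complement land on the two ends of the tone
  scale, and the ``accents`` choice decides which end is light;
* ``channel_mixer`` — a freestyle clipped weighted sum of the channels.

File formats: PNG and binary PPM at 8 bits/channel (round-half-to-even
quantisation), response tables as CSV with a fixed, checked schema, display
calibration from a small plain-text config.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .colour import DisplayCalibration, luminance_fraction
from .exceptions import DomainError, SchemaError

__all__ = [
    "ToneMapping",
    "to_grayscale",
    "read_image",
    "write_image",
    "RESPONSE_SCHEMA",
    "read_responses",
    "write_responses",
    "load_config",
    "seeded_rng",
    "log_run",
]

log = logging.getLogger("pointillism")

#: Required columns of a response CSV, in order.
RESPONSE_SCHEMA = ("observer_id", "condition", "pair", "contrast")


@dataclass(frozen=True)
class ToneMapping:
    kind: str  # luminance | max_rule | hue_diameter | channel_mixer
    axis_hue: float | None = None  # hue_diameter only
    weights: tuple[float, float, float] | None = None  # channel_mixer only
    accents: str = "light"  # hue_diameter: axis hue rendered light or dark

    def __post_init__(self) -> None:
        if self.kind not in ("luminance", "max_rule", "hue_diameter", "channel_mixer"):
            raise DomainError(f"unknown tone mapping {self.kind!r}")
        if self.kind == "hue_diameter" and self.axis_hue is None:
            raise DomainError("hue_diameter mapping needs an axis hue")
        if self.kind == "channel_mixer":
            if self.weights is None or not all(np.isfinite(self.weights)):
                raise DomainError("channel_mixer needs three finite weights")
        if self.accents not in ("light", "dark"):
            raise DomainError("accents must be 'light' or 'dark'")


def _hexagon_position(rgb: np.ndarray) -> np.ndarray:
    """Project encoded RGB onto the plane perpendicular to the grey axis.

    Cardinal colours land on the unit hexagon's vertices.
    """
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    u = r - 0.5 * g - 0.5 * b
    v = (np.sqrt(3.0) / 2.0) * (g - b)
    return np.stack([u, v], axis=-1)


def to_grayscale(
    image: np.ndarray, mapping: ToneMapping, cal: DisplayCalibration | None = None
) -> np.ndarray:
    """Map an RGB image (floats in [0,1], last axis 3) to one channel in [0,1]."""
    cal = cal or DisplayCalibration()
    image = np.asarray(image, dtype=float)
    if image.shape[-1] != 3:
        raise DomainError("expected an RGB image with last axis 3")
    if mapping.kind == "luminance":
        out = luminance_fraction(image, cal)
    elif mapping.kind == "max_rule":
        out = image.max(axis=-1)
    elif mapping.kind == "hue_diameter":
        from .colour import hue_to_rgb  # axis vertex from the hue circle

        axis = _hexagon_position(hue_to_rgb(mapping.axis_hue))
        axis = axis / np.linalg.norm(axis)
        proj = _hexagon_position(image) @ axis
        out = 0.5 + 0.5 * proj  # proj in [-1, 1] for cube colours
        if mapping.accents == "dark":
            out = 1.0 - out
    else:  # channel_mixer
        out = image @ np.asarray(mapping.weights, dtype=float)
    return np.clip(out, 0.0, 1.0)


def _quantize(image: np.ndarray) -> np.ndarray:
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0) * 255.0
    return np.rint(arr).astype(np.uint8)  # round-half-to-even


def write_image(path, image: np.ndarray) -> None:
    """Write a float image in [0,1] (grey or RGB) as 8-bit PNG or PPM."""
    path = Path(path)
    arr = _quantize(image)
    mode = "L" if arr.ndim == 2 else "RGB"
    img = Image.fromarray(arr, mode=mode)
    suffix = path.suffix.lower()
    if suffix == ".ppm":
        img.save(path, format="PPM")
    elif suffix == ".png":
        img.save(path, format="PNG")
    else:
        raise DomainError(f"unsupported image format {suffix!r} (use .png or .ppm)")


def read_image(path) -> np.ndarray:
    """Read an 8-bit PNG/PPM back to floats in [0,1]; round-trips bit-exactly."""
    with Image.open(path) as img:
        arr = np.asarray(img)
    return arr.astype(float) / 255.0


def write_responses(path, table: pd.DataFrame) -> None:
    for col in RESPONSE_SCHEMA:
        if col not in table.columns:
            raise SchemaError(f"response table is missing required column {col!r}")
    table.to_csv(path, index=False)


def read_responses(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    for col in RESPONSE_SCHEMA:
        if col not in table.columns:
            raise SchemaError(f"response file {path} is missing required column {col!r}")
    bad = ~table["contrast"].between(0, 1)
    if bad.any():
        raise SchemaError(f"{int(bad.sum())} contrast values outside [0, 1] in {path}")
    return table


def load_config(path) -> DisplayCalibration:
    """Display calibration from a plain-text config.

    Lines are ``key: values`` with whitespace-separated numbers; ``#`` starts
    a comment.  Keys: gamma, white_xy, primaries_xy (6 numbers, R G B order),
    primary_luminances_cdm2 (3 numbers), transfer (power|srgb).  Missing keys
    fall back to the defaults.
    """
    values: dict[str, list[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise SchemaError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
        key, _, rest = line.partition(":")
        values[key.strip()] = rest.split()
    kwargs = {}
    try:
        if "gamma" in values:
            kwargs["gamma"] = float(values["gamma"][0])
        if "transfer" in values:
            kwargs["transfer"] = values["transfer"][0]
        if "white_xy" in values:
            kwargs["white_point"] = tuple(float(v) for v in values["white_xy"][:2])
        if "primaries_xy" in values:
            nums = [float(v) for v in values["primaries_xy"]]
            if len(nums) != 6:
                raise SchemaError(f"{path}: primaries_xy needs 6 numbers, got {len(nums)}")
            kwargs["primary_chromaticities"] = tuple(
                (nums[2 * i], nums[2 * i + 1]) for i in range(3)
            )
        if "primary_luminances_cdm2" in values:
            kwargs["primary_luminances"] = tuple(
                float(v) for v in values["primary_luminances_cdm2"][:3]
            )
    except (ValueError, IndexError) as exc:
        raise SchemaError(f"{path}: malformed value: {exc}") from exc
    return DisplayCalibration(**kwargs)


def seeded_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def log_run(command: str, seed: int | None, config_path=None) -> None:
    """Log the seed and config hash of a CLI run, for reproducibility."""
    digest = "none"
    if config_path is not None:
        digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()[:12]
    log.info("command=%s seed=%s config_sha256=%s", command, seed, digest)
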