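"""Display-referred colour: calibration, photometry, and colour differences.

Colours are display-encoded (gamma-domain) RGB triples in [0, 1]^3, the "raw
coordinates" a graphics programmer types.  A :class:`DisplayCalibration`
grounds every photometric computation: it holds the measured luminances of
the three primaries at full drive, their CIE xy chromaticities, the white
point, and the transfer exponent.  The default calibration uses ITU-R BT.709
(sRGB) primaries with D65 white, a pure power-law gamma of 2.2, and primary
luminances in the measured ratio 69:197:53 cd/m^2.

Three measures of chromatic difference live here:

* CIE luminance Michelson contrast (:func:`luminance`, :func:`michelson_contrast`),
* the CIEDE2000 colour difference on L*a*b* (:func:`ciede2000`),
* plain Euclidean distance in the encoded RGB cube (:func:`rgb_cube_distance`).

The six cardinal colours are the full-intensity corners of the RGB cube's
chromatic hexagon, indexed cyclically Y=0, G=1, C=2, B=3, M=4, R=5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "CARDINAL_ORDER",
    "CARDINAL_RGB",
    "CARDINAL_INDEX",
    "DisplayCalibration",
    "decode_gamma",
    "encode_gamma",
    "luminance",
    "luminance_fraction",
    "michelson_contrast",
    "rgb_to_xyz",
    "rgb_to_lab",
    "ciede2000",
    "rgb_cube_distance",
    "colour_circle_distance",
    "max_rule",
    "hue_to_rgb",
]

#: Cardinal colours in cyclic hue order (index 0..5 along the colour circle).
CARDINAL_ORDER = "YGCBMR"

CARDINAL_RGB = {
    "Y": (1.0, 1.0, 0.0),
    "G": (0.0, 1.0, 0.0),
    "C": (0.0, 1.0, 1.0),
    "B": (0.0, 0.0, 1.0),
    "M": (1.0, 0.0, 1.0),
    "R": (1.0, 0.0, 0.0),
}

CARDINAL_INDEX = {letter: i for i, letter in enumerate(CARDINAL_ORDER)}

# BT.709 / sRGB chromaticities and the D65 white point.
_SRGB_PRIMARIES = ((0.640, 0.330), (0.300, 0.600), (0.150, 0.060))
_D65_WHITE = (0.3127, 0.3290)


def _as_rgb(c) -> np.ndarray:
    arr = np.asarray(c, dtype=float)
    if arr.shape[-1] != 3:
        raise DomainError(f"expected RGB triples with last axis 3, got shape {arr.shape}")
    return arr


def _check_unit_range(arr: np.ndarray, what: str = "RGB component") -> None:
    if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
        raise DomainError(f"{what} outside [0, 1]")


@dataclass(frozen=True)
class DisplayCalibration:
    """Photometric and colorimetric description of the display.

    Parameters
    ----------
    primary_luminances:
        Luminances in cd/m^2 of the R, G, B primaries at full drive.
    primary_chromaticities:
        CIE xy chromaticities of the three primaries.
    white_point:
        CIE xy chromaticity of the display white.
    gamma:
        Exponent of the power-law transfer function.
    transfer:
        ``"power"`` for a pure power law (default) or ``"srgb"`` for the
        piecewise sRGB curve.
    """

    primary_luminances: tuple[float, float, float] = (69.0, 197.0, 53.0)
    primary_chromaticities: tuple[tuple[float, float], ...] = _SRGB_PRIMARIES
    white_point: tuple[float, float] = _D65_WHITE
    gamma: float = 2.2
    transfer: str = "power"

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ConfigurationError("gamma must be strictly positive")
        if any(l <= 0 for l in self.primary_luminances):
            raise ConfigurationError("primary luminances must be strictly positive")
        for xy in (*self.primary_chromaticities, self.white_point):
            if not (0 <= xy[0] <= 1 and 0 <= xy[1] <= 1):
                raise ConfigurationError(f"chromaticity {xy} outside [0,1]^2")
        if self.transfer not in ("power", "srgb"):
            raise ConfigurationError(f"unknown transfer {self.transfer!r}")

    @property
    def white_luminance(self) -> float:
        return float(sum(self.primary_luminances))

    @property
    def rgb_to_xyz_matrix(self) -> np.ndarray:
        """3x3 matrix taking linear-light RGB to XYZ, scaled so that
        RGB (1,1,1) maps to the white point with Y = 1."""
        cols = []
        for x, y in self.primary_chromaticities:
            if y == 0:
                raise ConfigurationError("primary with y = 0 has undefined XYZ")
            cols.append([x / y, 1.0, (1.0 - x - y) / y])
        P = np.array(cols).T
        xw, yw = self.white_point
        if yw == 0:
            raise ConfigurationError("white point with y = 0 is invalid")
        white_xyz = np.array([xw / yw, 1.0, (1.0 - xw - yw) / yw])
        try:
            scale = np.linalg.solve(P, white_xyz)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError("primary matrix is singular") from exc
        if np.any(scale <= 0):
            raise ConfigurationError("white point outside the primary triangle")
        return P * scale

    @property
    def white_xyz(self) -> np.ndarray:
        return self.rgb_to_xyz_matrix @ np.ones(3)


def decode_gamma(c, cal: DisplayCalibration) -> np.ndarray:
    """Encoded [0,1] RGB -> linear-light RGB (electro-optical transfer)."""
    arr = _as_rgb(c)
    _check_unit_range(arr)
    arr = np.clip(arr, 0.0, 1.0)
    if cal.transfer == "srgb":
        return np.where(arr <= 0.04045, arr / 12.92, ((arr + 0.055) / 1.055) ** 2.4)
    return arr**cal.gamma


def encode_gamma(c, cal: DisplayCalibration) -> np.ndarray:
    """Linear-light RGB -> encoded RGB; inverse of :func:`decode_gamma`."""
    arr = _as_rgb(c)
    _check_unit_range(arr, "linear-light component")
    arr = np.clip(arr, 0.0, 1.0)
    if cal.transfer == "srgb":
        return np.where(arr <= 0.0031308, arr * 12.92, 1.055 * arr ** (1 / 2.4) - 0.055)
    return arr ** (1.0 / cal.gamma)


def luminance(c, cal: DisplayCalibration) -> np.ndarray | float:
    """Luminance in cd/m^2: linear-light components weighted by the primary
    luminances.  Additive over primaries."""
    lin = decode_gamma(c, cal)
    out = lin @ np.asarray(cal.primary_luminances, dtype=float)
    return float(out) if np.ndim(out) == 0 else out


def luminance_fraction(c, cal: DisplayCalibration) -> np.ndarray | float:
    """Luminance as a fraction of the display white's luminance, in [0, 1]."""
    out = luminance(c, cal) / cal.white_luminance
    return float(out) if np.ndim(out) == 0 else out


def michelson_contrast(i1, i2) -> np.ndarray | float:
    """Michelson contrast |I1 - I2| / (I1 + I2) of two mean intensities."""
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    if np.any(i1 < 0) or np.any(i2 < 0):
        raise DomainError("intensities must be nonnegative")
    total = i1 + i2
    if np.any(total == 0):
        raise DomainError("Michelson contrast undefined when both intensities are zero")
    out = np.abs(i1 - i2) / total
    return float(out) if np.ndim(out) == 0 else out


def rgb_to_xyz(c, cal: DisplayCalibration) -> np.ndarray:
    """Encoded RGB -> CIE XYZ (white maps to the white point, Y_white = 1)."""
    lin = decode_gamma(c, cal)
    return lin @ cal.rgb_to_xyz_matrix.T


def _lab_f(t: np.ndarray) -> np.ndarray:
    delta = 6.0 / 29.0
    return np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)


def rgb_to_lab(c, cal: DisplayCalibration) -> np.ndarray:
    """Encoded RGB -> CIE 1976 L*a*b* against the calibration's white."""
    xyz = rgb_to_xyz(c, cal)
    ratio = xyz / cal.white_xyz
    f = _lab_f(ratio)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def ciede2000(lab1, lab2, kL: float = 1.0, kC: float = 1.0, kH: float = 1.0):
    """CIEDE2000 colour difference between L*a*b* colours.

    Vectorised over leading axes.  Symmetric, nonnegative, zero exactly on
    identical inputs — but not a metric: it violates the triangle inequality
    on a few percent of random colour triples.
    """
    lab1 = np.asarray(lab1, dtype=float)
    lab2 = np.asarray(lab2, dtype=float)
    if not (np.all(np.isfinite(lab1)) and np.all(np.isfinite(lab2))):
        raise DomainError("Lab inputs must be finite")
    L1, a1, b1 = lab1[..., 0], lab1[..., 1], lab1[..., 2]
    L2, a2, b2 = lab2[..., 0], lab2[..., 1], lab2[..., 2]

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where(C1p == 0, 0.0, h1p)
    h2p = np.where(C2p == 0, 0.0, h2p)

    dLp = L2 - L1
    dCp = C2p - C1p

    hdiff = h2p - h1p
    dhp = np.where(hdiff > 180.0, hdiff - 360.0, np.where(hdiff < -180.0, hdiff + 360.0, hdiff))
    both_chromatic = (C1p * C2p) != 0
    dhp = np.where(both_chromatic, dhp, 0.0)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dhp) / 2.0)

    Lbar = 0.5 * (L1 + L2)
    Cbarp = 0.5 * (C1p + C2p)
    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbarp = np.where(
        both_chromatic,
        np.where(habs <= 180.0, 0.5 * hsum, np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0))),
        hsum,
    )

    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbarp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbarp))
        + 0.32 * np.cos(np.radians(3.0 * hbarp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbarp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbarp - 275.0) / 25.0) ** 2))
    RC = 2.0 * np.sqrt(Cbarp**7 / (Cbarp**7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbar - 50.0) ** 2 / np.sqrt(20.0 + (Lbar - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbarp
    SH = 1.0 + 0.015 * Cbarp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    tL = dLp / (kL * SL)
    tC = dCp / (kC * SC)
    tH = dHp / (kH * SH)
    out = np.sqrt(tL**2 + tC**2 + tH**2 + RT * tC * tH)
    return float(out) if np.ndim(out) == 0 else out


def rgb_cube_distance(a, b) -> np.ndarray | float:
    """Euclidean distance between encoded RGB triples; no gamma decoding.

    For cardinal colours the values are 1, sqrt(2) ~ 1.4, sqrt(3) ~ 1.7 for
    pairs one, two and three steps apart on the colour circle.
    """
    aa = _as_rgb(a)
    bb = _as_rgb(b)
    _check_unit_range(aa)
    _check_unit_range(bb)
    out = np.linalg.norm(aa - bb, axis=-1)
    return float(out) if np.ndim(out) == 0 else out


def colour_circle_distance(h1, h2) -> np.ndarray | float:
    """Cyclic step distance on the 6-point hue circle, in [0, 3]."""
    d = np.abs(np.asarray(h1, dtype=float) - np.asarray(h2, dtype=float)) % 6.0
    out = np.minimum(d, 6.0 - d)
    return float(out) if np.ndim(out) == 0 else out


def max_rule(c) -> np.ndarray | float:
    """Colour strength as the maximum encoded RGB coordinate.

    Equal to 1 for every cardinal colour: blue counts as strong as yellow
    even though yellow is five times as luminous.
    """
    arr = _as_rgb(c)
    _check_unit_range(arr)
    out = arr.max(axis=-1)
    return float(out) if np.ndim(out) == 0 else out


def hue_to_rgb(h) -> np.ndarray:
    """Full colour for a (possibly fractional) hue index on the YGCBMR circle.

    Integer indices give the cardinal colours; fractional indices ramp the
    single RGB channel that differs between the flanking cardinals, linearly
    in encoded coordinates.
    """
    h = np.asarray(h, dtype=float) % 6.0
    lo = np.floor(h).astype(int) % 6
    frac = h - np.floor(h)
    corners = np.array([CARDINAL_RGB[letter] for letter in CARDINAL_ORDER])
    left = corners[lo]
    right = corners[(lo + 1) % 6]
    out = left + frac[..., None] * (right - left)
    return out
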