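"""Bipartite pointillist stimulus synthesis.

A stimulus is two abutting squares filled with circular dots.  Dot centres
come from the barycentres of a Voronoi tessellation of uniformly random
points over the union of the squares; each dot's radius is the shortest
barycentre-to-vertex distance of its (clipped) cell times a common factor,
chosen by bisection so that a target fraction of the background stays
uncovered.  Dots are designated left or right either deterministically by
their centre (hard edge) or by a linear probability ramp across a boundary
strip (soft edge).

Three colour gamuts dress the dots:

* achromatic — greys with a normal tone dither of fixed standard deviation
  (20% of the black-white scale), clipped to range;
* monochromatic — tints and shades of one cardinal hue, mixed additively in
  linear light from colour/white/black (CWK) contents that sum to one,
  sampled with a skew factor of four favouring saturated colour;
* polychromatic — as monochromatic, but with the hue first dithered by a
  triangular density extending one step along the colour circle to each side.

Pixel coordinates are 0-based, top-left origin, half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import QhullError, Voronoi
from shapely.geometry import Polygon, box

from .colour import CARDINAL_INDEX, CARDINAL_RGB, DisplayCalibration, decode_gamma, encode_gamma, hue_to_rgb
from .exceptions import DomainError, FillCalibrationError, GeometryError

__all__ = [
    "GamutSpec",
    "StimulusSpec",
    "DotLayout",
    "sample_points",
    "voronoi_layout",
    "calibrate_fill",
    "assign_sides_hard",
    "assign_sides_soft",
    "sample_achromatic",
    "sample_cwk",
    "cwk_to_colour",
    "sample_hue_triangular",
    "achromatic_means",
    "render",
]

Region = tuple[float, float, float, float]  # (x0, y0, x1, y1)


@dataclass(frozen=True)
class GamutSpec:
    """Colour gamut of the dots."""

    kind: str = "achromatic"  # achromatic | monochromatic | polychromatic
    dither_sd: float = 0.20  # achromatic tone dither, fraction of full scale
    skew: float = 4.0  # CWK sampler skew factor
    hue_spread: float = 1.0  # polychromatic triangular half-width, in steps
    cwk_domain: str = "linear"  # additive mixing domain: linear | encoded

    def __post_init__(self) -> None:
        if self.kind not in ("achromatic", "monochromatic", "polychromatic"):
            raise DomainError(f"unknown gamut kind {self.kind!r}")
        if self.dither_sd < 0:
            raise DomainError("dither_sd must be nonnegative")
        if self.skew < 1:
            raise DomainError("skew must be >= 1")
        if self.kind == "polychromatic" and self.hue_spread <= 0:
            raise DomainError("hue_spread must be positive")


@dataclass(frozen=True)
class StimulusSpec:
    """Complete description of one bipartite pointillist stimulus.

    ``pair`` holds two cardinal letters for chromatic gamuts, or two mean
    grey intensities in [0, 1] for the achromatic gamut.  Defaults (dot
    count, fill, boundary width, background) are package reconstructions of
    plausible study values, all overridable.
    """

    pair: tuple = ("Y", "B")
    gamut: GamutSpec = field(default_factory=GamutSpec)
    edge_type: str = "hard"  # hard | soft
    square_size: int = 256  # pixels per square side
    n_dots: int = 1200  # over both squares
    uncovered_fraction: float = 0.25
    boundary_width: float = 0.2  # fraction of square side (soft edges)
    background: tuple[float, float, float] = (0.8, 0.8, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.uncovered_fraction < 1:
            raise DomainError("uncovered_fraction must lie in (0, 1)")
        if not 0 < self.boundary_width <= 1:
            raise DomainError("boundary_width must lie in (0, 1]")
        if self.n_dots < 10:
            raise DomainError("need at least 10 dots")
        if self.edge_type not in ("hard", "soft"):
            raise DomainError(f"unknown edge type {self.edge_type!r}")
        if self.gamut.kind in ("monochromatic", "polychromatic"):
            for c in self.pair:
                if c not in CARDINAL_RGB:
                    raise DomainError(f"{c!r} is not a cardinal colour")
        else:
            for v in self.pair:
                if not 0 <= float(v) <= 1:
                    raise DomainError("achromatic means must lie in [0, 1]")

    @property
    def region(self) -> Region:
        return (0.0, 0.0, 2.0 * self.square_size, float(self.square_size))

    @property
    def midline(self) -> float:
        return float(self.square_size)


@dataclass
class DotLayout:
    """Realised dots of one stimulus: geometry, sides, colours."""

    centres: np.ndarray  # (n, 2)
    radii: np.ndarray  # (n,)
    sides: np.ndarray | None = None  # (n,) of "left"/"right"
    colours: np.ndarray | None = None  # (n, 3) encoded RGB

    def __len__(self) -> int:
        return len(self.centres)

    def scaled(self, factor: float) -> "DotLayout":
        return DotLayout(self.centres, self.radii * factor, self.sides, self.colours)


def sample_points(n: int, region: Region, rng: np.random.Generator) -> np.ndarray:
    """``n`` independent uniform points in an axis-aligned rectangle."""
    x0, y0, x1, y1 = region
    if x1 <= x0 or y1 <= y0:
        raise DomainError("empty region")
    if n == 0:
        return np.empty((0, 2))
    pts = rng.random((n, 2))
    pts[:, 0] = x0 + pts[:, 0] * (x1 - x0)
    pts[:, 1] = y0 + pts[:, 1] * (y1 - y0)
    return pts


def _mirrored(points: np.ndarray, region: Region) -> np.ndarray:
    """Reflect the point set across all four region edges.

    Voronoi cells of the original points are then exactly their cells
    clipped to the region, and all of them are bounded.
    """
    x0, y0, x1, y1 = region
    left = points * [-1, 1] + [2 * x0, 0]
    right = points * [-1, 1] + [2 * x1, 0]
    down = points * [1, -1] + [0, 2 * y0]
    up = points * [1, -1] + [0, 2 * y1]
    return np.vstack([points, left, right, down, up])


def voronoi_layout(points: np.ndarray, region: Region, common_factor: float = 1.0) -> DotLayout:
    """One dot per Voronoi cell of ``points``, cells clipped to ``region``.

    Dot centre is the polygon barycentre of the clipped cell; the radius is
    the shortest barycentre-to-vertex distance times ``common_factor``.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise GeometryError("need at least 4 points for a useful tessellation")
    centred = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(points).max())) < 2:
        raise GeometryError("points are collinear; tessellation is degenerate")
    clip = box(*region)
    try:
        vor = Voronoi(_mirrored(points, region))
    except QhullError as exc:
        raise GeometryError(f"degenerate point configuration: {exc}") from exc
    centres = np.empty_like(points)
    radii = np.empty(len(points))
    for i in range(len(points)):
        region_idx = vor.point_region[i]
        vert_idx = vor.regions[region_idx]
        if -1 in vert_idx or len(vert_idx) < 3:
            raise GeometryError("unbounded or empty Voronoi cell despite mirroring")
        poly = Polygon(vor.vertices[vert_idx]).intersection(clip)
        if poly.is_empty or poly.area == 0:
            raise GeometryError("Voronoi cell clipped to nothing")
        c = poly.centroid
        verts = np.asarray(poly.exterior.coords[:-1])
        centres[i] = (c.x, c.y)
        radii[i] = np.min(np.hypot(verts[:, 0] - c.x, verts[:, 1] - c.y))
    return DotLayout(centres=centres, radii=radii * common_factor)


def coverage_mask(layout: DotLayout, region: Region) -> np.ndarray:
    """Boolean raster (rows x cols) of pixels covered by at least one dot.

    Pixel (row j, col i) is covered when its centre (i+0.5, j+0.5) lies
    within a dot; overlapping dots count once.
    """
    x0, y0, x1, y1 = region
    w, h = int(round(x1 - x0)), int(round(y1 - y0))
    mask = np.zeros((h, w), dtype=bool)
    for (cx, cy), r in zip(layout.centres, layout.radii):
        if r <= 0:
            continue
        i0 = max(int(np.floor(cx - x0 - r - 1)), 0)
        i1 = min(int(np.ceil(cx - x0 + r + 1)), w)
        j0 = max(int(np.floor(cy - y0 - r - 1)), 0)
        j1 = min(int(np.ceil(cy - y0 + r + 1)), h)
        if i0 >= i1 or j0 >= j1:
            continue
        xs = np.arange(i0, i1) + 0.5 + x0
        ys = np.arange(j0, j1) + 0.5 + y0
        dx = xs[None, :] - cx
        dy = ys[:, None] - cy
        mask[j0:j1, i0:i1] |= dx**2 + dy**2 <= r**2
    return mask


def uncovered_fraction(layout: DotLayout, region: Region) -> float:
    mask = coverage_mask(layout, region)
    return float(1.0 - mask.mean())


def calibrate_fill(
    layout: DotLayout,
    region: Region,
    target_uncovered: float,
    tol: float = 0.02,
    max_factor: float = 2.0,
    max_iter: int = 40,
) -> float:
    """Common radius factor achieving the target uncovered fraction.

    Bisection on the factor; the rasterised uncovered fraction is monotone
    decreasing in it (larger dots cover at least as much).
    """
    if not 0.01 < target_uncovered < 0.99:
        raise DomainError("target_uncovered must lie in (0.01, 0.99)")
    lo, hi = 0.0, max_factor
    if uncovered_fraction(layout.scaled(hi), region) > target_uncovered + tol:
        raise FillCalibrationError(
            f"cannot reach uncovered fraction {target_uncovered} with factor <= {max_factor}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        unc = uncovered_fraction(layout.scaled(mid), region)
        if abs(unc - target_uncovered) <= 0.5 * tol:
            return mid
        if unc > target_uncovered:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    if abs(uncovered_fraction(layout.scaled(mid), region) - target_uncovered) > tol:
        raise FillCalibrationError("fill bisection did not converge within tolerance")
    return mid


def assign_sides_hard(layout: DotLayout, midline: float) -> DotLayout:
    """Deterministic designation: left iff the centre's abscissa < midline."""
    sides = np.where(layout.centres[:, 0] < midline, "left", "right")
    return DotLayout(layout.centres, layout.radii, sides, layout.colours)


def assign_sides_soft(
    layout: DotLayout, midline: float, strip_width: float, rng: np.random.Generator
) -> DotLayout:
    """Probabilistic designation: P(right) ramps linearly 0 -> 1 across a
    strip of ``strip_width`` centred on the midline; independent per dot."""
    if strip_width <= 0:
        raise DomainError("strip width must be positive")
    x = layout.centres[:, 0]
    p_right = np.clip((x - (midline - strip_width / 2)) / strip_width, 0.0, 1.0)
    sides = np.where(rng.random(len(layout)) < p_right, "right", "left")
    return DotLayout(layout.centres, layout.radii, sides, layout.colours)


def sample_achromatic(mean: float, sd: float, rng: np.random.Generator, size=None):
    """Grey intensity: normal dither around the mean, clipped to [0, 1]."""
    if not 0 <= mean <= 1:
        raise DomainError("mean intensity must lie in [0, 1]")
    if sd == 0:
        return np.full(size, float(mean)) if size is not None else float(mean)
    out = np.clip(rng.normal(mean, sd, size), 0.0, 1.0)
    return float(out) if np.ndim(out) == 0 else out


def sample_cwk(skew: float, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Colour/white/black contents: three uniforms, the first multiplied by
    the skew factor, normalised to sum exactly to one."""
    if skew < 1:
        raise DomainError("skew must be >= 1")
    n = 1 if size is None else size
    u = rng.random((n, 3))
    u[:, 0] *= skew
    s = u.sum(axis=1)
    c = u[:, 0] / s
    w = u[:, 1] / s
    # closing the simplex as 1 - (c + w) keeps the row sum exactly 1.0
    cwk = np.column_stack([c, w, 1.0 - (c + w)])
    return cwk[0] if size is None else cwk


def cwk_to_colour(
    cwk: np.ndarray,
    full: np.ndarray,
    cal: DisplayCalibration | None = None,
    domain: str = "linear",
) -> np.ndarray:
    """Ostwald mixture c*full + w*white + k*black, additively.

    Default mixing is in linear light (the display adds light linearly); the
    encoded-domain option exists for ablation.
    """
    cal = cal or DisplayCalibration()
    single = np.asarray(cwk).ndim == 1
    cwk = np.atleast_2d(np.asarray(cwk, dtype=float))
    full = np.atleast_2d(np.asarray(full, dtype=float))
    c, w = cwk[:, :1], cwk[:, 1:2]
    if domain == "linear":
        full_lin = decode_gamma(full, cal)
        mix = c * full_lin + w * 1.0  # + k * 0
        out = encode_gamma(np.clip(mix, 0.0, 1.0), cal)
    elif domain == "encoded":
        out = np.clip(c * full + w * 1.0, 0.0, 1.0)
    else:
        raise DomainError(f"unknown mixing domain {domain!r}")
    return out[0] if single else out


def sample_hue_triangular(
    mean_h: float, spread: float, rng: np.random.Generator, size: int | None = None
):
    """Hue index from a symmetric triangular density centred at ``mean_h``
    extending ``spread`` steps to each side, wrapped mod 6."""
    if spread <= 0:
        raise DomainError("spread must be positive")
    out = rng.triangular(mean_h - spread, mean_h, mean_h + spread, size=size) % 6.0
    return float(out) if np.ndim(out) == 0 else out


def achromatic_means(contrast: float, mean_level: float = 0.5) -> tuple[float, float]:
    """Two grey means symmetric about ``mean_level`` with the given
    Michelson contrast: (m(1+c), m(1-c))."""
    if not 0 <= contrast <= 1:
        raise DomainError("contrast must lie in [0, 1]")
    return (mean_level * (1 + contrast), mean_level * (1 - contrast))


def _dot_colours(
    spec: StimulusSpec, sides: np.ndarray, cal: DisplayCalibration, rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    n = len(sides)
    is_left = sides == "left"
    extras = pd.DataFrame(index=np.arange(n))
    g = spec.gamut
    if g.kind == "achromatic":
        means = np.where(is_left, float(spec.pair[0]), float(spec.pair[1]))
        intensity = np.clip(rng.normal(means, g.dither_sd), 0.0, 1.0) if g.dither_sd > 0 else means
        colours = np.repeat(np.asarray(intensity, dtype=float)[:, None], 3, axis=1)
        extras["intensity"] = intensity
        return colours, extras
    if g.kind == "monochromatic":
        full = np.where(
            is_left[:, None], CARDINAL_RGB[spec.pair[0]], CARDINAL_RGB[spec.pair[1]]
        ).astype(float)
        hue = np.where(is_left, CARDINAL_INDEX[spec.pair[0]], CARDINAL_INDEX[spec.pair[1]]).astype(
            float
        )
    else:  # polychromatic: dither the hue first, then tint/shade
        mean_hue = np.where(is_left, CARDINAL_INDEX[spec.pair[0]], CARDINAL_INDEX[spec.pair[1]])
        hue = np.asarray(
            [sample_hue_triangular(float(m), g.hue_spread, rng) for m in mean_hue], dtype=float
        )
        full = hue_to_rgb(hue)
    cwk = sample_cwk(g.skew, rng, size=n)
    colours = cwk_to_colour(cwk, full, cal, domain=g.cwk_domain)
    extras["hue"] = hue
    extras[["c", "w", "k"]] = cwk
    return colours, extras


def render(
    spec: StimulusSpec, cal: DisplayCalibration | None = None
) -> tuple[np.ndarray, DotLayout, pd.DataFrame]:
    """Realise a stimulus: raster image, dot layout, per-dot metadata.

    Fully reproducible from ``spec.seed``.  Returns the image as a float
    array (height x width x 3) of encoded RGB in [0, 1]; dots are painted as
    hard disks in layout order over the background.
    """
    cal = cal or DisplayCalibration()
    rng = np.random.default_rng(spec.seed)
    region = spec.region
    pts = sample_points(spec.n_dots, region, rng)
    layout = voronoi_layout(pts, region)
    factor = calibrate_fill(layout, region, spec.uncovered_fraction)
    layout = layout.scaled(factor)
    if spec.edge_type == "hard":
        layout = assign_sides_hard(layout, spec.midline)
    else:
        layout = assign_sides_soft(
            layout, spec.midline, spec.boundary_width * spec.square_size, rng
        )
    colours, extras = _dot_colours(spec, layout.sides, cal, rng)
    layout.colours = colours

    x0, y0, x1, y1 = region
    w, h = int(round(x1 - x0)), int(round(y1 - y0))
    image = np.empty((h, w, 3), dtype=float)
    image[:] = spec.background
    for (cx, cy), r, col in zip(layout.centres, layout.radii, colours):
        if r <= 0:
            continue
        i0 = max(int(np.floor(cx - r - 1)), 0)
        i1 = min(int(np.ceil(cx + r + 1)), w)
        j0 = max(int(np.floor(cy - r - 1)), 0)
        j1 = min(int(np.ceil(cy + r + 1)), h)
        if i0 >= i1 or j0 >= j1:
            continue
        xs = np.arange(i0, i1) + 0.5
        ys = np.arange(j0, j1) + 0.5
        inside = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2 <= r**2
        image[j0:j1, i0:i1][inside] = col

    meta = pd.DataFrame(
        {
            "dot": np.arange(len(layout)),
            "x": layout.centres[:, 0],
            "y": layout.centres[:, 1],
            "radius": layout.radii,
            "side": layout.sides,
            "r": colours[:, 0],
            "g": colours[:, 1],
            "b": colours[:, 2],
        }
    )
    meta = pd.concat([meta, extras], axis=1)
    return image, layout, meta
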