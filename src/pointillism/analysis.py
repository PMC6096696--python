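"""The analysis chain for distinctiveness-matching data.

Order of operations mirrors the study: (1) normalise away each observer's
idiosyncratic offset and slope against the cross-observer median, (2) check
inter-observer concordance with Kendall's tau-b, (3) summarise settings per
cardinal pair and per pair class, (4) confront the data with the three
candidate models — CIE luminance Michelson contrast, CIEDE2000, and raw RGB
cube distance (plus the colour-circle step distance as a poor man's variant)
— via rank (tau) and linear (Pearson r) correlations, and (5) probe the
CIEDE2000 triangle inequality by Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .colour import (
    CARDINAL_INDEX,
    CARDINAL_ORDER,
    CARDINAL_RGB,
    DisplayCalibration,
    ciede2000,
    colour_circle_distance,
    luminance,
    michelson_contrast,
    rgb_cube_distance,
    rgb_to_lab,
)
from .exceptions import DomainError, InsufficientDataError
from .observer import _raw_model_value
from .transitions import DEFAULT_FIT, decompose, enumerate_cardinal_pairs

__all__ = [
    "MODEL_NAMES",
    "NormalizedTable",
    "PairMatrix",
    "TriangleMCResult",
    "normalize_observers",
    "concordance",
    "summarize_pairs",
    "pair_matrix",
    "model_predictions",
    "compare_models",
    "triangle_inequality_mc",
    "hexagon_summary",
]

MODEL_NAMES = ("luminance_contrast", "ciede2000", "rgb_cube", "colour_circle")

_CELL = ["condition", "pair"]


@dataclass
class NormalizedTable:
    """Response rows with a ``normalized_contrast`` column, plus the fitted
    per-observer slopes and intercepts that were divided out."""

    table: pd.DataFrame
    observer_fits: pd.DataFrame  # index observer_id, columns slope/intercept


def normalize_observers(table: pd.DataFrame, response_col: str = "contrast") -> NormalizedTable:
    """Remove idiosyncratic offset and slope per observer.

    For each observer, ordinary least squares of their own responses against
    the cross-observer median of the matching (condition, pair) cell; the
    normalised response is (response - intercept) / slope.  A single pass:
    medians are computed once from the raw table and not updated.
    """
    if table["observer_id"].nunique() < 2:
        raise InsufficientDataError("normalisation needs >= 2 observers")
    medians = table.groupby(_CELL)[response_col].median()
    x_all = table.set_index(_CELL).index.map(medians).to_numpy(dtype=float)
    out = table.copy()
    fits = {}
    normalized = np.empty(len(table))
    for obs, idx in table.groupby("observer_id").indices.items():
        x = x_all[idx]
        y = table[response_col].to_numpy(dtype=float)[idx]
        if np.ptp(y) == 0:
            raise InsufficientDataError(f"observer {obs} gave constant responses; slope undefined")
        slope, intercept = np.polyfit(x, y, 1)
        if slope == 0:
            raise InsufficientDataError(f"observer {obs} has zero fitted slope")
        fits[obs] = {"slope": float(slope), "intercept": float(intercept)}
        normalized[idx] = (y - intercept) / slope
    out["normalized_contrast"] = normalized
    return NormalizedTable(table=out, observer_fits=pd.DataFrame(fits).T)


def _per_observer_cell_medians(table: pd.DataFrame, response_col: str) -> pd.DataFrame:
    """Wide frame: rows are (condition, pair) cells, columns observers."""
    return (
        table.groupby(["observer_id", *_CELL])[response_col]
        .median()
        .unstack("observer_id")
    )


def concordance(
    table: pd.DataFrame,
    response_col: str = "contrast",
    by_condition: bool = False,
    alpha: float = 0.05,
) -> dict:
    """Pairwise Kendall tau-b between observers over matched cells.

    Returns a dict with the tau matrix, the two-sided p values (normal
    approximation, as implemented in scipy), a masked matrix where entries
    not significant at ``alpha`` are NaN, and the median off-diagonal tau.
    With ``by_condition`` the same is computed per stimulus condition.
    """
    wide = _per_observer_cell_medians(table, response_col).dropna()
    observers = list(wide.columns)
    if len(observers) < 2:
        raise InsufficientDataError("concordance needs >= 2 observers")
    if len(wide) < 3:
        raise InsufficientDataError("concordance needs >= 3 matched cells")
    k = len(observers)
    tau = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            t, p = stats.kendalltau(wide.iloc[:, i], wide.iloc[:, j])
            tau[i, j] = tau[j, i] = t
            pval[i, j] = pval[j, i] = p
    masked = np.where((pval <= alpha) | np.eye(k, dtype=bool), tau, np.nan)
    off = tau[~np.eye(k, dtype=bool)]
    result = {
        "observers": observers,
        "tau": pd.DataFrame(tau, index=observers, columns=observers),
        "p": pd.DataFrame(pval, index=observers, columns=observers),
        "masked": pd.DataFrame(masked, index=observers, columns=observers),
        "median_tau": float(np.median(off)),
    }
    if by_condition:
        result["by_condition"] = {
            cond: concordance(sub, response_col, by_condition=False, alpha=alpha)
            for cond, sub in table.groupby("condition")
        }
    return result


def summarize_pairs(table: pd.DataFrame, response_col: str = "normalized_contrast") -> pd.DataFrame:
    """Quartiles (Q1, median, Q3) per (condition, pair) cell, with the pair
    class attached, plus per-(condition, class) aggregate rows."""
    if table.empty:
        raise InsufficientDataError("empty response table")

    def quartiles(s: pd.Series) -> pd.Series:
        q1, q2, q3 = np.percentile(s, [25, 50, 75])
        return pd.Series({"q1": q1, "median": q2, "q3": q3, "n": len(s)})

    per_pair = table.groupby(_CELL)[response_col].apply(quartiles).unstack().reset_index()
    per_pair["pair_class"] = [decompose(p[0], p[1]).pair_class for p in per_pair["pair"]]

    tbl = table.copy()
    tbl["pair_class"] = [decompose(p[0], p[1]).pair_class for p in tbl["pair"]]
    per_class = (
        tbl.groupby(["condition", "pair_class"])[response_col]
        .apply(quartiles)
        .unstack()
        .reset_index()
    )
    per_class["pair"] = "(all)"
    return pd.concat([per_pair, per_class], ignore_index=True)


@dataclass
class PairMatrix:
    """6x6 symmetric matrix over cardinal hues with zero diagonal, plus its
    affine grey mapping (off-diagonal min -> 0 = black, max -> 1 = white)."""

    values: np.ndarray  # raw values, diagonal zero
    grey: np.ndarray  # mapped to [0, 1]
    vmin: float
    vmax: float
    labels: str = CARDINAL_ORDER

    def band(self, offset: int) -> np.ndarray:
        """All entries at cyclic hue offset ``offset`` (doubly periodic)."""
        idx = np.arange(6)
        return self.values[idx, (idx + offset) % 6]


def pair_matrix(values_by_pair: dict[str, float]) -> PairMatrix:
    """Build the array-plot matrix from one value per unordered pair."""
    mat = np.zeros((6, 6))
    for a, b in enumerate_cardinal_pairs():
        key = a + b if a + b in values_by_pair else b + a
        if key not in values_by_pair:
            raise DomainError(f"missing value for pair {a + b}")
        i, j = CARDINAL_INDEX[a], CARDINAL_INDEX[b]
        mat[i, j] = mat[j, i] = float(values_by_pair[key])
    off = mat[~np.eye(6, dtype=bool)]
    vmin, vmax = float(off.min()), float(off.max())
    if vmax > vmin:
        grey = np.clip((mat - vmin) / (vmax - vmin), 0.0, 1.0)
    else:
        grey = np.ones((6, 6))
    np.fill_diagonal(grey, 0.0)  # self-self comparisons are trivially zero/black
    return PairMatrix(values=mat, grey=grey, vmin=vmin, vmax=vmax)


def model_predictions(
    model_name: str, cal: DisplayCalibration | None = None
) -> dict[str, float]:
    """One predicted value per cardinal pair for a candidate model.

    ``luminance_contrast``: Michelson contrast of the two cardinals'
    luminances; ``ciede2000``: Delta E00 between the cardinals' L*a*b*
    coordinates; ``rgb_cube``: Euclidean distance between encoded RGB;
    ``colour_circle``: cyclic step distance.
    """
    if model_name not in MODEL_NAMES:
        raise DomainError(f"unknown model {model_name!r}; choose from {MODEL_NAMES}")
    cal = cal or DisplayCalibration()
    return {
        a + b: _raw_model_value(a + b, model_name, cal, DEFAULT_FIT)
        for a, b in enumerate_cardinal_pairs()
    }


def compare_models(
    table: pd.DataFrame,
    cal: DisplayCalibration | None = None,
    models: tuple[str, ...] = MODEL_NAMES,
    response_col: str = "normalized_contrast",
) -> pd.DataFrame:
    """Kendall tau-b and Pearson r of each model's predictions against the
    observed per-pair medians, per condition and pooled.

    Zero-variance predictions leave Pearson r as NaN (flagged); tau-b is
    still computed.
    """
    cal = cal or DisplayCalibration()
    preds = {m: model_predictions(m, cal) for m in models}
    blocks = [("pooled", table)] + [(c, sub) for c, sub in table.groupby("condition")]
    rows = []
    for cond, sub in blocks:
        observed = sub.groupby("pair")[response_col].median()
        for m in models:
            p = np.array([preds[m][pair] for pair in observed.index])
            o = observed.to_numpy(dtype=float)
            tau, _ = stats.kendalltau(o, p)
            if np.ptp(p) == 0 or np.ptp(o) == 0:
                r = np.nan
            else:
                r, _ = stats.pearsonr(o, p)
            rows.append(
                {
                    "condition": cond,
                    "model": m,
                    "kendall_tau": float(tau),
                    "pearson_r": float(r) if np.isfinite(r) else np.nan,
                    "n_pairs": len(observed),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class TriangleMCResult:
    """Monte-Carlo estimate of the CIEDE2000 triangle-inequality violation
    fraction, with its binomial standard error."""

    fraction: float
    standard_error: float
    n: int
    mode: str

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def triangle_inequality_mc(
    n_triangles: int,
    cal: DisplayCalibration | None = None,
    rng: np.random.Generator | None = None,
    mode: str = "path",
    batch: int = 200_000,
) -> TriangleMCResult:
    """Fraction of random RGB colour triangles violating the CIEDE2000
    triangle inequality.

    Triples (A, B, C) are sampled uniformly in the encoded RGB cube and
    converted to L*a*b* through the calibration.  ``mode="path"`` (default)
    tests the inequality as stated for an ordered triple — is the direct
    route A-C longer than the detour through B, dE(A,C) > dE(A,B) + dE(B,C)?
    — the same comparison as the green-cyan-magenta detour example.
    ``mode="any"`` counts a triangle as violating when any one of its three
    sides exceeds the sum of the other two (roughly three times as many,
    since at most one side can violate).
    """
    if n_triangles < 1:
        raise DomainError("need at least one triangle")
    if mode not in ("path", "any"):
        raise DomainError(f"unknown mode {mode!r}")
    cal = cal or DisplayCalibration()
    rng = rng if rng is not None else np.random.default_rng()
    violations = 0
    done = 0
    while done < n_triangles:
        m = min(batch, n_triangles - done)
        tri = rng.random((m, 3, 3))
        lab = rgb_to_lab(tri, cal)
        d_ab = ciede2000(lab[:, 0], lab[:, 1])
        d_bc = ciede2000(lab[:, 1], lab[:, 2])
        d_ac = ciede2000(lab[:, 0], lab[:, 2])
        if mode == "path":
            viol = d_ac > d_ab + d_bc
        else:
            viol = (d_ac > d_ab + d_bc) | (d_ab > d_bc + d_ac) | (d_bc > d_ab + d_ac)
        violations += int(viol.sum())
        done += m
    frac = violations / n_triangles
    se = float(np.sqrt(frac * (1.0 - frac) / n_triangles))
    return TriangleMCResult(fraction=frac, standard_error=se, n=n_triangles, mode=mode)


def hexagon_summary(fiducial: str, values_by_pair: dict[str, float]) -> dict[str, float]:
    """Connection weights from a fiducial cardinal to the five others,
    normalised to unit mean (so panels are comparable by line thickness)."""
    if fiducial not in CARDINAL_RGB:
        raise DomainError(f"{fiducial!r} is not a cardinal colour")
    weights = {}
    for other in CARDINAL_ORDER:
        if other == fiducial:
            continue
        key = fiducial + other if fiducial + other in values_by_pair else other + fiducial
        if key not in values_by_pair:
            raise DomainError(f"missing value for pair {fiducial}{other}")
        weights[other] = float(values_by_pair[key])
    mean = np.mean(list(weights.values()))
    if mean == 0:
        raise DomainError("cannot normalise all-zero values")
    return {k: v / mean for k, v in weights.items()}
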