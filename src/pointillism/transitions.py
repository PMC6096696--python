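"""Chromatic transition structure of cardinal colour pairs.

A bipartite transition between two cardinal colours decomposes channel by
channel: each RGB channel either switches between ON and OFF (a *transition*
with a polarity), stays fully ON on both sides (a *veil*), or stays OFF
(*absent*).  Pairs with one, two or three channel transitions are called
analogous, incongruent and complementary respectively; for cardinal pairs
the transition count equals the cyclic step distance on the colour circle.

Distinctiveness — the achromatic Michelson contrast observers judge to match
a chromatic transition — is summarised by the linear model

    D = a0 + a_t * N_t + a_v * N_v

with N_t the number of channel transitions and N_v the number of veils.
The default coefficients (0.406, 0.025, -0.083) are the reference fit to
pooled normalised settings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colour import CARDINAL_INDEX, CARDINAL_ORDER, CARDINAL_RGB
from .exceptions import DegeneratePairError, FittingError

__all__ = [
    "ChannelTransition",
    "TransitionStructure",
    "DistinctivenessFit",
    "DEFAULT_FIT",
    "decompose",
    "polarity_profile",
    "enumerate_cardinal_pairs",
    "predict_distinctiveness",
    "fit_distinctiveness",
    "structure_table",
]

_CHANNELS = "RGB"


@dataclass(frozen=True)
class ChannelTransition:
    """One RGB channel's behaviour across a bipartite transition."""

    channel: str  # "R", "G" or "B"
    left_value: int
    right_value: int

    @property
    def kind(self) -> str:
        if self.left_value != self.right_value:
            return "transition"
        return "veil" if self.left_value == 1 else "absent"

    @property
    def polarity(self) -> int:
        return int(np.sign(self.right_value - self.left_value))


@dataclass(frozen=True)
class TransitionStructure:
    """Per-channel decomposition of a cardinal colour pair."""

    pair: tuple[str, str]
    channels: tuple[ChannelTransition, ChannelTransition, ChannelTransition]

    @property
    def n_transitions(self) -> int:
        return sum(1 for ch in self.channels if ch.kind == "transition")

    @property
    def n_veils(self) -> int:
        return sum(1 for ch in self.channels if ch.kind == "veil")

    @property
    def veil_channels(self) -> tuple[str, ...]:
        return tuple(ch.channel for ch in self.channels if ch.kind == "veil")

    @property
    def transition_channels(self) -> tuple[str, ...]:
        return tuple(ch.channel for ch in self.channels if ch.kind == "transition")

    @property
    def pair_class(self) -> str:
        return {1: "analogous", 2: "incongruent", 3: "complementary"}[self.n_transitions]


def decompose(c1: str, c2: str) -> TransitionStructure:
    """Channel-by-channel decomposition of an (ordered) cardinal pair.

    Swapping the arguments keeps counts and class and negates every polarity.
    """
    for c in (c1, c2):
        if c not in CARDINAL_RGB:
            raise DegeneratePairError(f"{c!r} is not a cardinal colour (one of {CARDINAL_ORDER})")
    if c1 == c2:
        raise DegeneratePairError(f"pair ({c1}, {c2}) has no transition")
    left = CARDINAL_RGB[c1]
    right = CARDINAL_RGB[c2]
    channels = tuple(
        ChannelTransition(_CHANNELS[i], int(left[i]), int(right[i])) for i in range(3)
    )
    return TransitionStructure(pair=(c1, c2), channels=channels)


def polarity_profile(t: TransitionStructure) -> tuple[int, int, int]:
    """Signs of (right - left) per RGB channel; 0 for veils and absences."""
    return tuple(ch.polarity for ch in t.channels)


def enumerate_cardinal_pairs() -> list[tuple[str, str]]:
    """The 15 unordered cardinal pairs, in stable YGCBMR order:
    YG, YC, YB, YM, YR, GC, GB, GM, GR, CB, CM, CR, BM, BR, MR."""
    letters = CARDINAL_ORDER
    return [(letters[i], letters[j]) for i in range(6) for j in range(i + 1, 6)]


@dataclass(frozen=True)
class DistinctivenessFit:
    """Coefficients of the linear N_t/N_v distinctiveness model."""

    a0: float
    a_t: float
    a_v: float
    median_abs_error: float = float("nan")
    max_abs_error: float = float("nan")

    def predict(self, n_transitions, n_veils):
        out = self.a0 + self.a_t * np.asarray(n_transitions, dtype=float) + self.a_v * np.asarray(
            n_veils, dtype=float
        )
        return float(out) if np.ndim(out) == 0 else out


#: Reference coefficients from the pooled fit to normalised settings.
DEFAULT_FIT = DistinctivenessFit(a0=0.406, a_t=0.025, a_v=-0.083)


def predict_distinctiveness(fit: DistinctivenessFit, t: TransitionStructure) -> float:
    """Evaluate D = a0 + a_t N_t + a_v N_v for one transition structure."""
    return float(fit.predict(t.n_transitions, t.n_veils))


def _pair_structures(pairs: pd.Series) -> list[TransitionStructure]:
    cache: dict[str, TransitionStructure] = {}
    out = []
    for p in pairs:
        key = str(p)
        if key not in cache:
            cache[key] = decompose(key[0], key[1])
        out.append(cache[key])
    return out


def fit_distinctiveness(
    records: pd.DataFrame,
    response_col: str = "contrast",
    pair_col: str = "pair",
    extended: bool = False,
) -> DistinctivenessFit:
    """Ordinary least squares of observed distinctiveness on (1, N_t, N_v).

    Each row of ``records`` is one response; ``pair_col`` holds two-letter
    cardinal pairs like ``"YB"``.  With ``extended=True`` the design gains
    per-channel transition indicators and per-veil-colour indicators (the
    "dozen free parameters" refinement); the returned coefficients are still
    the shared (a0, a_t, a_v) — the refinement only absorbs residual
    structure and is off by default.
    """
    if records.empty:
        raise FittingError("empty response table")
    structures = _pair_structures(records[pair_col])
    nt = np.array([s.n_transitions for s in structures], dtype=float)
    nv = np.array([s.n_veils for s in structures], dtype=float)
    y = records[response_col].to_numpy(dtype=float)

    cols = [np.ones_like(nt), nt, nv]
    if extended:
        for ch in _CHANNELS:
            cols.append(np.array([1.0 if ch in s.transition_channels else 0.0 for s in structures]))
        for ch in _CHANNELS:
            cols.append(np.array([1.0 if ch in s.veil_channels else 0.0 for s in structures]))
    X = np.stack(cols, axis=1)
    if np.linalg.matrix_rank(X) < 3:
        raise FittingError("design matrix is rank deficient: need >= 3 distinct (N_t, N_v) combinations")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return DistinctivenessFit(
        a0=float(coef[0]),
        a_t=float(coef[1]),
        a_v=float(coef[2]),
        median_abs_error=float(np.median(np.abs(resid))),
        max_abs_error=float(np.max(np.abs(resid))),
    )


def structure_table() -> pd.DataFrame:
    """Tabular decomposition of all 15 cardinal pairs (CSV-ready)."""
    rows = []
    for a, b in enumerate_cardinal_pairs():
        s = decompose(a, b)
        rows.append(
            {
                "pair": a + b,
                "n_transitions": s.n_transitions,
                "n_veils": s.n_veils,
                "pair_class": s.pair_class,
                "polarity_profile": "".join(f"{p:+d}"[0] if p else "0" for p in polarity_profile(s)),
                "veil_channels": "".join(s.veil_channels),
                "transition_channels": "".join(s.transition_channels),
            }
        )
    return pd.DataFrame(rows)
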