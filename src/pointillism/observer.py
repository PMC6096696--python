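"""Synthetic observers for the distinctiveness-matching task.

The response datum in the matching task is the Michelson contrast of an achromatic
bipartition an observer sets to look "mutually equally distinct" as a
chromatic one.  This module generates response tables with the statistical
structure the analysis assumes: a latent distinctiveness per cardinal pair
(from one of the candidate models), per-observer idiosyncratic offset and
gain, Gaussian response noise, and optional quantisation to the coarse
contrast steps of the adjustment procedure.

Because matching data only identify idiosyncrasies *relative to the panel*,
the generated offsets are centred to zero mean and the gains to unit
geometric mean across the panel; an individual observer is still biased and
mis-scaled relative to consensus.

A default session uses the canonical bookkeeping: 5 observers, 4
conditions (hard/soft edge x monochromatic/polychromatic gamut), 15
cardinal pairs and 4 replicates per cell — 240 responses per observer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colour import (
    CARDINAL_RGB,
    DisplayCalibration,
    ciede2000,
    colour_circle_distance,
    CARDINAL_INDEX,
    luminance,
    michelson_contrast,
    rgb_cube_distance,
    rgb_to_lab,
)
from .exceptions import DomainError, InsufficientDataError
from .transitions import DEFAULT_FIT, DistinctivenessFit, decompose, enumerate_cardinal_pairs

__all__ = [
    "CONDITIONS",
    "ObserverModel",
    "GroundTruth",
    "make_observers",
    "latent_distinctiveness",
    "simulate_session",
]

#: The four stimulus conditions: edge type x gamut kind.
CONDITIONS = ("hard-mono", "hard-poly", "soft-mono", "soft-poly")

_MODELS = ("rgb_cube", "luminance_contrast", "ciede2000", "linear_Nt_Nv", "colour_circle")


@dataclass(frozen=True)
class ObserverModel:
    """One synthetic observer's idiosyncrasies.

    ``offset`` and ``gain`` map the latent distinctiveness to the observer's
    raw setting; ``noise_sd`` is per-response Gaussian noise; ``step`` > 0
    quantises responses to that grid (0 disables quantisation).
    """

    observer_id: str
    offset: float = 0.0
    gain: float = 1.0
    noise_sd: float = 0.05
    step: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise DomainError("gain must be strictly positive")
        if self.noise_sd < 0 or self.step < 0:
            raise DomainError("noise_sd and step must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    """Latent distinctiveness model and its affine map to contrast units.

    ``model`` picks the quantity evaluated on the nominal cardinal colours
    of a pair; ``scale`` and ``shift`` map it to Michelson contrast, clipped
    to [0, 1].
    """

    model: str = "linear_Nt_Nv"
    scale: float = 1.0
    shift: float = 0.0
    fit: DistinctivenessFit = field(default_factory=lambda: DEFAULT_FIT)

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise DomainError(f"unknown latent model {self.model!r}; choose from {_MODELS}")

    @classmethod
    def calibrated(
        cls,
        model: str,
        cal: DisplayCalibration | None = None,
        low: float = 0.32,
        high: float = 0.52,
    ) -> "GroundTruth":
        """Affine map placing the model's 15 pair values onto [low, high].

        The band defaults to the contrast range typical of pooled settings
        (medians of analogous through complementary pairs).
        """
        cal = cal or DisplayCalibration()
        raw = [_raw_model_value(a + b, model, cal, DEFAULT_FIT) for a, b in enumerate_cardinal_pairs()]
        lo, hi = min(raw), max(raw)
        if hi == lo:
            return cls(model=model, scale=0.0, shift=0.5 * (low + high))
        scale = (high - low) / (hi - lo)
        return cls(model=model, scale=scale, shift=low - scale * lo)


def _raw_model_value(
    pair: str, model: str, cal: DisplayCalibration, fit: DistinctivenessFit
) -> float:
    a, b = pair[0], pair[1]
    ca, cb = CARDINAL_RGB[a], CARDINAL_RGB[b]
    if model == "rgb_cube":
        return float(rgb_cube_distance(ca, cb))
    if model == "luminance_contrast":
        return float(michelson_contrast(luminance(ca, cal), luminance(cb, cal)))
    if model == "ciede2000":
        return float(ciede2000(rgb_to_lab(ca, cal), rgb_to_lab(cb, cal)))
    if model == "colour_circle":
        return float(colour_circle_distance(CARDINAL_INDEX[a], CARDINAL_INDEX[b]))
    if model == "linear_Nt_Nv":
        s = decompose(a, b)
        return float(fit.predict(s.n_transitions, s.n_veils))
    raise DomainError(f"unknown latent model {model!r}")


def latent_distinctiveness(
    pair: str, truth: GroundTruth, cal: DisplayCalibration | None = None
) -> float:
    """The noise-free contrast a pair evokes under the chosen ground truth."""
    cal = cal or DisplayCalibration()
    raw = _raw_model_value(pair, truth.model, cal, truth.fit)
    return float(np.clip(truth.shift + truth.scale * raw, 0.0, 1.0))


def make_observers(
    n: int,
    rng: np.random.Generator,
    offset_sd: float = 0.02,
    gain_log_sd: float = 0.05,
    noise_sd: float = 0.05,
    step: float = 0.0,
) -> list[ObserverModel]:
    """Draw a panel of observers with panel-centred idiosyncrasies.

    Offsets are Gaussian with ``offset_sd`` re-centred to zero mean; log
    gains are Gaussian with ``gain_log_sd`` re-centred to zero mean (unit
    geometric-mean gain).
    """
    if n < 1:
        raise DomainError("need at least one observer")
    offsets = rng.normal(0.0, offset_sd, n)
    offsets -= offsets.mean()
    log_gains = rng.normal(0.0, gain_log_sd, n)
    log_gains -= log_gains.mean()
    return [
        ObserverModel(
            observer_id=f"obs{i + 1}",
            offset=float(offsets[i]),
            gain=float(np.exp(log_gains[i])),
            noise_sd=noise_sd,
            step=step,
        )
        for i in range(n)
    ]


def simulate_session(
    observers: list[ObserverModel],
    truth: GroundTruth,
    rng: np.random.Generator,
    conditions: tuple[str, ...] = CONDITIONS,
    pairs: list[tuple[str, str]] | None = None,
    replicates: int = 4,
    cal: DisplayCalibration | None = None,
    response_times: bool = False,
) -> pd.DataFrame:
    """Simulate one session: every observer visits every condition x pair
    ``replicates`` times.

    Each response is clip(offset + gain * latent + N(0, noise_sd^2), 0, 1),
    optionally quantised to the observer's step.  With the defaults (4
    conditions, 15 pairs, 4 replicates) each observer contributes 240 rows.
    Response times, if requested, are log-normal with a median in the 7-12 s
    band; they are never analysed.
    """
    if len(observers) < 2:
        raise InsufficientDataError("need >= 2 observers for concordance analyses")
    cal = cal or DisplayCalibration()
    pairs = pairs if pairs is not None else enumerate_cardinal_pairs()
    latents = {a + b: latent_distinctiveness(a + b, truth, cal) for a, b in pairs}

    rows = []
    for obs in observers:
        median_rt = rng.uniform(7.0, 12.0)
        for cond in conditions:
            for a, b in pairs:
                lat = latents[a + b]
                for _ in range(replicates):
                    resp = obs.offset + obs.gain * lat + rng.normal(0.0, obs.noise_sd)
                    if obs.step > 0:
                        resp = np.round(resp / obs.step) * obs.step
                    resp = float(np.clip(resp, 0.0, 1.0))
                    row = {
                        "observer_id": obs.observer_id,
                        "condition": cond,
                        "pair": a + b,
                        "contrast": resp,
                    }
                    if response_times:
                        row["rt_s"] = float(median_rt * np.exp(rng.normal(0.0, 0.4)))
                    rows.append(row)
    return pd.DataFrame(rows)
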