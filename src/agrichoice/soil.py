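"""Five-degree soil limitation grading of chemical parameters.

Each parameter is graded I (no limitation) .. V (very severe) against
fixed breakpoints.  Quality-increasing parameters use a descending
breakpoint ladder with boundary values resolving to the better degree;
pH is graded on an acid and an alkaline ladder and the worse side wins.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEGREES",
    "LimitationThresholds",
    "SoilProfile",
    "LimitationProfile",
    "default_thresholds",
    "classify_parameter",
    "classify_plot",
    "aggregate_by_hub",
    "fertility_level",
]

DEGREES = ("I", "II", "III", "IV", "V")

SOIL_PARAMETERS = (
    "organic_matter",
    "total_nitrogen",
    "phosphorus",
    "potassium",
    "exchangeable_bases",
    "base_saturation",
    "cec",
    "ph",
)


@dataclass(frozen=True)
class LimitationThresholds:
    """Per-parameter degree breakpoints.

    ``breaks[param]`` is the 4-tuple (b1 > b2 > b3 > b4): value >= b1 is
    degree I, >= b2 degree II, and so on; below b4 is degree V.  pH uses
    ``ph_acid`` the same way and ``ph_alkaline`` as an ascending ladder
    (<= a1 -> I, <= a2 -> III, <= a3 -> IV, else V; the alkaline degree
    II cell overlaps degree I and is resolved in favour of I).
    """

    breaks: dict = field(
        default_factory=lambda: {
            "organic_matter": (2.0, 1.5, 1.0, 0.5),
            "total_nitrogen": (0.08, 0.06, 0.045, 0.03),
            "phosphorus": (20.0, 15.0, 10.0, 5.0),
            "potassium": (0.4, 0.3, 0.2, 0.1),
            "exchangeable_bases": (10.0, 7.5, 5.0, 2.0),
            "base_saturation": (60.0, 50.0, 30.0, 15.0),
            "cec": (25.0, 15.0, 10.0, 5.0),
        }
    )
    ph_acid: tuple = (6.0, 5.5, 5.3, 5.2)
    ph_alkaline: tuple = (7.8, 8.3, 8.5)

    def __post_init__(self):
        for name, bks in self.breaks.items():
            if len(bks) != 4 or any(a <= b for a, b in zip(bks, bks[1:])):
                raise ValueError(
                    f"{name}: breakpoints must be 4 strictly decreasing values"
                )
        if any(a <= b for a, b in zip(self.ph_acid, self.ph_acid[1:])):
            raise ValueError("ph_acid breakpoints must be strictly decreasing")
        if any(a >= b for a, b in zip(self.ph_alkaline, self.ph_alkaline[1:])):
            raise ValueError("ph_alkaline breakpoints must be strictly increasing")

    @property
    def parameters(self) -> tuple:
        return tuple(self.breaks) + ("ph",)


def default_thresholds() -> LimitationThresholds:
    return LimitationThresholds()


@dataclass(frozen=True)
class SoilProfile:
    """Measured soil chemistry for one plot."""

    organic_matter: float  # %
    total_nitrogen: float  # %
    phosphorus: float  # ppm Bray-1
    potassium: float  # meq/100 g
    exchangeable_bases: float  # meq/100 g
    base_saturation: float  # %
    cec: float  # meq/100 g
    ph: float

    def __post_init__(self):
        for name in SOIL_PARAMETERS:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if name != "ph" and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v!r}")

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in SOIL_PARAMETERS}


@dataclass(frozen=True)
class LimitationProfile:
    degrees: dict  # parameter -> "I".."V"
    worst_degree: str
    plot_id: object = None
    hub_id: object = None


def _ladder_degree(value: float, breaks) -> int:
    """0-based degree index on a descending-quality ladder."""
    for i, b in enumerate(breaks):
        if value >= b:
            return i
    return len(breaks)


def classify_parameter(
    value: float, parameter: str, thr: LimitationThresholds | None = None
) -> str:
    """Grade one measurement; boundary values take the better degree."""
    thr = thr or default_thresholds()
    if not np.isfinite(value):
        raise ValueError(f"{parameter}: value must be finite, got {value!r}")
    if parameter == "ph":
        acid = _ladder_degree(value, thr.ph_acid)
        a1, a2, a3 = thr.ph_alkaline
        if value <= a1:
            alk = 0  # overlap cell resolved to degree I
        elif value <= a2:
            alk = 2  # degree II cell is the overlap; next step is III
        elif value <= a3:
            alk = 3
        else:
            alk = 4
        return DEGREES[max(acid, alk)]
    if parameter not in thr.breaks:
        raise LookupError(f"unknown soil parameter {parameter!r}")
    return DEGREES[_ladder_degree(value, thr.breaks[parameter])]


def classify_plot(
    sp: SoilProfile,
    thr: LimitationThresholds | None = None,
    plot_id=None,
    hub_id=None,
) -> LimitationProfile:
    """Grade every parameter of a plot; worst degree is the maximum."""
    thr = thr or default_thresholds()
    degrees = {
        name: classify_parameter(value, name, thr)
        for name, value in sp.as_dict().items()
    }
    worst = DEGREES[max(DEGREES.index(d) for d in degrees.values())]
    return LimitationProfile(
        degrees=degrees, worst_degree=worst, plot_id=plot_id, hub_id=hub_id
    )


def fertility_level(worst_degree: str) -> int:
    """Map worst limitation degree to the 0/1/2 fertility covariate."""
    idx = DEGREES.index(worst_degree)
    if idx <= 1:  # I, II
        return 2
    if idx == 2:  # III
        return 1
    return 0  # IV, V


def _modal_degree(counter: Counter) -> str:
    """Most frequent degree; ties broken toward the worse degree."""
    top = max(counter.values())
    modes = [d for d, c in counter.items() if c == top]
    return DEGREES[max(DEGREES.index(d) for d in modes)]


def aggregate_by_hub(profiles) -> dict:
    """Per-hub degree tallies and severe-limitation flags.

    Returns ``{hub: {"tally": DataFrame(param x degree counts),
    "severe": [params with modal degree >= IV]}}``.
    """
    hubs: dict = {}
    for lp in profiles:
        hubs.setdefault(lp.hub_id, []).append(lp)
    out = {}
    for hub, lps in hubs.items():
        params = list(lps[0].degrees)
        tally = pd.DataFrame(0, index=params, columns=list(DEGREES))
        for lp in lps:
            for param, d in lp.degrees.items():
                tally.loc[param, d] += 1
        severe = []
        for param in params:
            counts = Counter(lp.degrees[param] for lp in lps)
            if DEGREES.index(_modal_degree(counts)) >= 3:
                severe.append(param)
        out[hub] = {"tally": tally, "severe": severe}
    return out
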