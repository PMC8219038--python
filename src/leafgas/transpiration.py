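"""Whole-plant cumulative transpiration from gravimetric pot records.

Pots are sealed with a membrane so soil evaporation is negligible, and
every water input/output is weighed.  Over the experiment the water
transpired per unit cumulative leaf area is

    E = (ΣV + Wi − Wf − FW) / At

where ΣV is the total volume of water added (1 ml ≡ 1 g), Wi and Wf the
initial and final pot-plus-plant weights (g), FW the plant's final fresh
weight (g) and At the cumulative leaf area.  Because weekly area
measurements sample a growing plant, At is computed by default as the
trapezoidal time-integral of the area series normalised by the
measurement interval pattern ("integral" mode, m²·d); a plain sum of the
weekly areas ("sum" mode, m²) is also available, and an explicit
``at_total`` overrides both.  The generator and estimator share the same
rule, so round trips are exact under either convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TranspirationSeries", "whole_plant_E", "cumulative_leaf_area"]


@dataclass
class TranspirationSeries:
    """Gravimetric record of one pot over the experiment.

    ``waterings`` is a list of (day, volume_ml) events; ``leaf_areas`` a
    list of (day, area_cm2) measurements.  ``at_total`` optionally gives
    the cumulative leaf area directly (m² or m²·d depending on the
    convention used downstream).
    """

    Wi: float  # g, initial pot + plant weight
    Wf: float  # g, final pot + plant weight
    FW: float  # g, final plant fresh weight
    waterings: list[tuple[float, float]] = field(default_factory=list)
    leaf_areas: list[tuple[float, float]] = field(default_factory=list)
    duration: float = 30.0  # d
    at_total: float | None = None

    def __post_init__(self) -> None:
        if min(self.Wi, self.Wf, self.FW) < 0:
            raise ValueError("weights must be >= 0")
        if any(v < 0 for _, v in self.waterings):
            raise ValueError("watering volumes must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    @property
    def total_water_added(self) -> float:
        """ΣV in g (1 ml water ≡ 1 g)."""
        return float(sum(v for _, v in self.waterings))


def cumulative_leaf_area(series: TranspirationSeries, mode: str = "integral") -> float:
    """Cumulative leaf area At from the weekly area record.

    ``mode="integral"`` returns the trapezoidal time-integral of area
    over the measurement days (m²·d); ``mode="sum"`` returns the plain
    sum of the measured areas (m²).  An explicit ``series.at_total``
    short-circuits both.
    """
    if series.at_total is not None:
        return series.at_total
    if not series.leaf_areas:
        raise ValueError("no leaf-area measurements and no at_total given")
    days = np.array([d for d, _ in series.leaf_areas], dtype=float)
    areas_m2 = np.array([a for _, a in series.leaf_areas], dtype=float) * 1e-4
    if mode == "sum":
        at = float(areas_m2.sum())
    elif mode == "integral":
        if days.size < 2:
            raise ValueError("integral mode needs >= 2 area measurements")
        at = float(np.trapezoid(areas_m2, days))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if at <= 0:
        raise ValueError("cumulative leaf area must be > 0")
    return at


def whole_plant_E(series: TranspirationSeries, mode: str = "integral") -> float:
    """Whole-plant transpiration per cumulative leaf area.

    E = (ΣV + Wi − Wf − FW)/At, in g per unit At (g m⁻² for the "sum"
    convention, g m⁻² d⁻¹-integrated for "integral").  A negative
    numerator (more mass at the end than accounted water) is reported
    as-is with a warning, since it flags condensation or bookkeeping
    errors rather than physics.
    """
    at = cumulative_leaf_area(series, mode=mode)
    if at <= 0:
        raise ValueError("cumulative leaf area must be > 0")
    numerator = series.total_water_added + series.Wi - series.Wf - series.FW
    if numerator < 0:
        warnings.warn(
            f"negative transpired mass {numerator:.3f} g: condensation or "
            "accounting anomaly", stacklevel=2,
        )
    return numerator / at
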