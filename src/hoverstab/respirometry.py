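"""Closed-chamber respirometry: oxygen-decline slopes and metabolic rates.

A fish sits in a sealed chamber of known volume while dissolved oxygen is
logged (typically once per minute for an hour).  The mass-specific oxygen
consumption rate is obtained from the slope of the O2 decline:

    MO2 = slope [mg L^-1 min^-1] * 60 * (V_chamber - V_fish) [L] * M^-0.9

where M is body mass in kg and 0.9 is the allometric exponent correcting
for the scaling of metabolic rate with mass.  The factor 60 converts the
per-minute slope to the hourly units in which MO2 is conventionally
reported (mg O2 kg^-1 h^-1).

Net hovering cost is MO2hover - MO2rest; the hover/rest ratio gives a
size-, temperature- and salinity-robust relative cost.  Energy is obtained
through the oxy-calorific equivalent of 3.25 cal per mg O2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .reference import (
    JOULES_PER_CAL,
    MASS_SCALING_EXPONENT,
    OXYCALORIFIC_CAL_PER_MG_O2,
)

__all__ = [
    "OxygenTrace",
    "RespirometryResult",
    "o2_slope",
    "mo2_from_trace",
    "net_and_ratio",
    "energy_kj",
    "summarize",
    "read_trace_csv",
]


@dataclass
class OxygenTrace:
    """Timestamped dissolved-oxygen series with chamber metadata.

    Parameters
    ----------
    time : array-like
        Sample times in minutes, strictly increasing.
    o2 : array-like
        Dissolved oxygen concentration, mg O2 L^-1, non-negative.
    chamber_vol : float
        Chamber water volume in litres.
    fish_vol : float, optional
        Fish volume in litres.  If omitted, the fish is assumed near
        neutrally buoyant (density ~1 kg/L) and ``mass / 1000 * 1000`` i.e.
        ``mass`` kg -> ``mass`` L is used.
    mass : float
        Fish mass in kg.
    """

    time: np.ndarray
    o2: np.ndarray
    chamber_vol: float
    mass: float
    fish_vol: float | None = None
    temperature: float | None = None
    salinity: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.o2.shape:
            raise ValueError("time and o2 must be 1-D arrays of equal length")
        if self.time.size < 3:
            raise ValueError("an oxygen trace needs at least 3 samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.o2 < 0):
            raise ValueError("negative oxygen concentration")
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.fish_vol is None:
            # near-neutral buoyancy: 1 kg of fish displaces ~1 L of water
            self.fish_vol = self.mass
        if not self.chamber_vol > self.fish_vol >= 0:
            raise ValueError("require chamber_vol > fish_vol >= 0")

    @property
    def net_volume(self) -> float:
        """Respirometer water volume minus the fish volume (L)."""
        return self.chamber_vol - float(self.fish_vol)


@dataclass
class RespirometryResult:
    """Per-individual metabolic summary (all MO2 in mg O2 kg^-1 h^-1)."""

    mo2_hover: float
    mo2_rest: float
    mo2_net: float
    ratio: float
    energy_10min_kj: float
    slope_hover: float
    slope_rest: float
    r2_hover: float
    r2_rest: float


def _window_mask(time: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.ones_like(time, dtype=bool)
    lo, hi = window
    return (time >= lo) & (time <= hi)


def o2_slope(
    trace: OxygenTrace, window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """OLS slope of the oxygen decline.

    Returns
    -------
    (slope, r2)
        ``slope`` is the magnitude of the decline in mg L^-1 min^-1
        (positive for falling O2); ``r2`` the coefficient of determination
        of the linear fit.
    """
    mask = _window_mask(trace.time, window)
    t, y = trace.time[mask], trace.o2[mask]
    if t.size < 3:
        raise ValueError("fewer than 3 samples in the requested window")
    if np.ptp(t) == 0:
        raise ValueError("constant time in window")
    fit = sps.linregress(t, y)
    if fit.slope > 0 and not np.isclose(fit.slope, 0.0):
        warnings.warn(
            "oxygen increases over the window; check for aeration or a leak",
            stacklevel=2,
        )
    r2 = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue) ** 2
    return -float(fit.slope), r2


def mo2_from_trace(
    trace: OxygenTrace, window: tuple[float, float] | None = None
) -> float:
    """Mass-specific oxygen consumption rate, mg O2 kg^-1 h^-1.

    MO2 = slope * 60 * (chamber_vol - fish_vol) * mass**-0.9.
    """
    slope, _ = o2_slope(trace, window)
    return mo2_from_slope(slope, trace.net_volume, trace.mass)


def mo2_from_slope(slope: float, net_volume: float, mass: float) -> float:
    """MO2 from a per-minute decline slope, net chamber volume and mass."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if net_volume <= 0:
        raise ValueError("net chamber volume must be positive")
    return slope * 60.0 * net_volume * mass ** (-MASS_SCALING_EXPONENT)


def net_and_ratio(hover: float, rest: float) -> tuple[float, float]:
    """Net hovering cost (hover - rest) and the hover/rest ratio."""
    if rest <= 0:
        raise ValueError("resting MO2 must be positive")
    return hover - rest, hover / rest


def energy_kj(mo2_net: float, minutes: float = 10.0) -> float:
    """Energy of net hovering cost over ``minutes``, kJ kg^-1.

    Uses the oxy-calorific equivalent of 3.25 cal per mg O2 and the
    thermodynamic calorie (4.184 J).
    """
    if minutes <= 0:
        raise ValueError("minutes must be positive")
    mg_per_kg = mo2_net * minutes / 60.0
    return mg_per_kg * OXYCALORIFIC_CAL_PER_MG_O2 * JOULES_PER_CAL / 1000.0


def summarize(
    hover: OxygenTrace,
    rest: OxygenTrace,
    window: tuple[float, float] | None = None,
    minutes: float = 10.0,
) -> RespirometryResult:
    """Full per-individual summary from a hovering and a resting trace."""
    slope_h, r2_h = o2_slope(hover, window)
    slope_r, r2_r = o2_slope(rest, window)
    mo2_h = mo2_from_slope(slope_h, hover.net_volume, hover.mass)
    mo2_r = mo2_from_slope(slope_r, rest.net_volume, rest.mass)
    net, ratio = net_and_ratio(mo2_h, mo2_r)
    return RespirometryResult(
        mo2_hover=mo2_h,
        mo2_rest=mo2_r,
        mo2_net=net,
        ratio=ratio,
        energy_10min_kj=energy_kj(net, minutes),
        slope_hover=slope_h,
        slope_rest=slope_r,
        r2_hover=r2_h,
        r2_rest=r2_r,
    )


def read_trace_csv(path, chamber_vol: float, mass: float, **kwargs) -> OxygenTrace:
    """Read a trace from CSV with columns ``time_min`` and ``o2_mg_per_l``."""
    import pandas as pd

    df = pd.read_csv(path)
    return OxygenTrace(
        time=df["time_min"].to_numpy(),
        o2=df["o2_mg_per_l"].to_numpy(),
        chamber_vol=chamber_vol,
        mass=mass,
        **kwargs,
    )
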