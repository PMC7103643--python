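"""DSC melting-peak integration and degree of crystallinity.

The heat of melting ``delta_Hm`` (J/g) is the baseline-corrected
integral of the endothermic melting peak of a thermogram recorded at a
known heating rate, and the degree of crystallinity is

    Xc (%) = 100 * delta_Hm / delta_Hm0

with the theoretical heat of melting of the 100%-crystalline polymer
``delta_Hm0`` = 293 J/g for polyethylene and 207 J/g for polypropylene.
Polystyrene (atactic) is treated as completely amorphous, Xc ~ 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "Thermogram",
    "CrystallinityResult",
    "ENTHALPY_FUSION_100",
    "integrate_melting_peak",
    "crystallinity",
]

# Theoretical heats of melting of 100% crystalline polymer (J/g).
ENTHALPY_FUSION_100 = {"PE": 293.0, "PP": 207.0}

AMORPHOUS_POLYMERS = frozenset({"PS"})


@dataclass(frozen=True)
class Thermogram:
    """One dynamic DSC segment.

    ``heat_flow`` is specific heat flow (W/g); ``endotherm_up`` records
    the instrument sign convention (True if endothermic events point
    up).  ``heating_rate`` is in degC/min and must be nonzero.
    """

    temperature: np.ndarray
    heat_flow: np.ndarray
    heating_rate: float = 10.0
    segment: str = "second heating"
    endotherm_up: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        hf = np.asarray(self.heat_flow, dtype=float)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "heat_flow", hf)
        if t.ndim != 1 or hf.ndim != 1 or t.size != hf.size:
            raise ValueError("temperature and heat_flow must be 1-D, equal length")
        if t.size < 10:
            raise ValueError("thermogram needs at least 10 samples")
        d = np.diff(t)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("temperature must be strictly monotone within a segment")
        if self.heating_rate == 0:
            raise ValueError("heating_rate must be nonzero")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(hf))):
            raise ValueError("thermogram values must be finite")


@dataclass(frozen=True)
class CrystallinityResult:
    delta_Hm: float          # J/g
    delta_Hm0: Optional[float]  # J/g; None for amorphous polymers
    Xc: float                # percent
    polymer: str
    amorphous: bool = False


def integrate_melting_peak(
    thermogram: Thermogram, window: Tuple[float, float]
) -> float:
    """Heat of melting (J/g) from the peak inside ``window`` (degC).

    A straight baseline joining the signal at the window endpoints is
    subtracted, the residual integrated over temperature by the
    trapezoid rule (W*degC/g), and the result divided by the heating
    rate expressed in degC/s.  A negative net area (no genuine
    endotherm in the window) is returned as-is with a warning.
    """
    lo, hi = min(window), max(window)
    t = thermogram.temperature
    hf = thermogram.heat_flow if thermogram.endotherm_up else -thermogram.heat_flow
    if t[0] > t[-1]:  # cooling segment stored high->low
        t, hf = t[::-1], hf[::-1]
    if lo < t[0] or hi > t[-1]:
        raise ValueError(
            f"window [{lo}, {hi}] outside thermogram range [{t[0]}, {t[-1]}]"
        )
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 2:
        raise ValueError("integration window contains fewer than 2 samples")
    tw, hw = t[mask], hf[mask]
    baseline = hw[0] + (hw[-1] - hw[0]) * (tw - tw[0]) / (tw[-1] - tw[0])
    area = float(np.trapezoid(hw - baseline, tw))  # W*degC/g
    beta_per_s = abs(thermogram.heating_rate) / 60.0
    delta_hm = area / beta_per_s
    if delta_hm < 0:
        warnings.warn(
            "negative net peak area: window likely contains no endotherm",
            stacklevel=2,
        )
    return delta_hm


def crystallinity(
    delta_Hm: float, polymer: str, delta_Hm0: Optional[float] = None
) -> CrystallinityResult:
    """Degree of crystallinity Xc (%) from the heat of melting.

    ``polymer`` must be PE or PP (reference enthalpies built in), PS
    (defined amorphous, Xc = 0), or any label if ``delta_Hm0`` is
    supplied explicitly.
    """
    polymer = polymer.upper()
    if polymer in AMORPHOUS_POLYMERS:
        return CrystallinityResult(
            delta_Hm=0.0, delta_Hm0=None, Xc=0.0, polymer=polymer, amorphous=True
        )
    if delta_Hm < 0:
        raise ValueError("delta_Hm must be non-negative")
    if delta_Hm0 is None:
        try:
            delta_Hm0 = ENTHALPY_FUSION_100[polymer]
        except KeyError:
            raise ValueError(
                f"no reference enthalpy for polymer {polymer!r}; pass delta_Hm0"
            ) from None
    xc = 100.0 * delta_Hm / delta_Hm0
    return CrystallinityResult(
        delta_Hm=delta_Hm, delta_Hm0=delta_Hm0, Xc=xc, polymer=polymer
    )
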