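"""Compression-test reduction for microplastic beads.

A bead squeezed between platens yields a load-strain curve: an initial
linear (elastic) region whose slope is the stiffness ``k``, possibly a
plastic plateau, densification at high strain, and -- for brittle
polymers such as PS and PE -- a sharp load drop where the bead
fractures.  This module reduces such curves to

* the linear elastic region and its slope ``k`` (stiffness),
* the fracture strain, if the bead broke, and
* the maximum compression ``epsilon_max = D / d_bar``, the ratio of the
  deformation diameter ``D`` (platen displacement at fracture, or at
  test termination for ductile beads, flagged as censored) to the
  initial bead diameter ``d_bar``.

Stiffness is reported under the conventional instrument label N/mm even
though the denominator is dimensionless strain (mm/mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "LoadStrainCurve",
    "CompressionSummary",
    "NoLinearRegionError",
    "detect_linear_region",
    "stiffness",
    "max_compression",
    "detect_fracture",
    "summarize_curve",
]


class NoLinearRegionError(ValueError):
    """No contiguous window of the curve met the linearity criterion."""


@dataclass(frozen=True)
class LoadStrainCurve:
    """A single bead's compression trace.

    Parameters
    ----------
    strain : array-like
        Compression per unit initial diameter (mm/mm), non-negative and
        strictly increasing.
    load : array-like
        Applied force (N).
    bead_id : str
        Label for the bead.
    initial_diameter : float
        Initial bead diameter ``d_bar`` (mm), > 0.
    """

    strain: np.ndarray
    load: np.ndarray
    bead_id: str = ""
    initial_diameter: float = 1.0

    def __post_init__(self) -> None:
        strain = np.asarray(self.strain, dtype=float)
        load = np.asarray(self.load, dtype=float)
        object.__setattr__(self, "strain", strain)
        object.__setattr__(self, "load", load)
        if strain.ndim != 1 or load.ndim != 1 or strain.size != load.size:
            raise ValueError("strain and load must be 1-D arrays of equal length")
        if strain.size < 4:
            raise ValueError("curve needs at least 4 points")
        if not np.all(np.isfinite(strain)) or not np.all(np.isfinite(load)):
            raise ValueError("strain and load must be finite")
        if np.any(strain < 0):
            raise ValueError("strain must be non-negative")
        if np.any(np.diff(strain) <= 0):
            raise ValueError("strain must be strictly increasing")
        if not self.initial_diameter > 0:
            raise ValueError("initial_diameter must be positive")

    def __len__(self) -> int:
        return int(self.strain.size)


@dataclass(frozen=True)
class CompressionSummary:
    """Reduced descriptors of one compression test."""

    bead_id: str
    stiffness: float                      # N per unit strain ("N/mm")
    epsilon_max: float                    # dimensionless, in [0, 1]
    fractured: bool
    fracture_strain: Optional[float]      # mm/mm, None if unfractured
    linear_region: Tuple[float, float]    # strain interval of the elastic fit
    censored: bool = field(default=False)  # epsilon_max taken at test end


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """Coefficient of determination of the least-squares line y ~ x.

    A zero-variance response is a perfect constant fit: R^2 = 1.
    """
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0.0:
        return 1.0
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return 1.0 - float(np.sum(resid**2) / sst)


def detect_linear_region(
    curve: LoadStrainCurve, min_points: int = 5, r2_min: float = 0.999
) -> Tuple[float, float]:
    """Locate the elastic (linear) region of a load-strain curve.

    Candidate windows are anchored at each start index at or after the
    first positive-load sample, in order, and expanded greedily while
    the least-squares linear fit keeps R^2 >= ``r2_min``.  The window at
    the *earliest* qualifying start wins: the elastic region precedes
    yield, so a longer linear stretch later in the curve (the plastic
    plateau, which fits a constant perfectly) must not displace it.
    Deterministic for fixed input.

    Returns the strain interval ``(lo, hi)`` of the chosen window.

    Raises
    ------
    NoLinearRegionError
        If no window of at least ``min_points`` samples satisfies the
        R^2 threshold.
    """
    if min_points < 3:
        raise ValueError("min_points must be >= 3")
    if not 0.0 < r2_min < 1.0:
        raise ValueError("r2_min must be in (0, 1)")
    x, y = curve.strain, curve.load
    n = x.size
    positive = np.nonzero(y > 0)[0]
    # anchor at the first positive-load sample, keeping the contact
    # point immediately before it (a curve through the origin starts at 0)
    first = max(int(positive[0]) - 1, 0) if positive.size else 0

    for start in range(first, n - min_points + 1):
        end = start + min_points  # exclusive
        if _r_squared(x[start:end], y[start:end]) < r2_min:
            continue
        while end < n and _r_squared(x[start : end + 1], y[start : end + 1]) >= r2_min:
            end += 1
        # backtrack: points past the yield kink pass the aggregate R^2
        # threshold while degrading the fit; trim while removal strictly
        # improves R^2 (keeps at least min_points)
        while end - start > min_points and (
            _r_squared(x[start : end - 1], y[start : end - 1])
            > _r_squared(x[start:end], y[start:end])
        ):
            end -= 1
        return float(x[start]), float(x[end - 1])
    raise NoLinearRegionError(
        f"no window of {min_points} points reaches R^2 >= {r2_min}"
    )


def stiffness(curve: LoadStrainCurve, region: Tuple[float, float]) -> float:
    """Stiffness k: least-squares slope of load vs. strain on ``region``.

    ``region`` is an inclusive strain interval inside the curve domain
    containing at least two samples.
    """
    lo, hi = region
    mask = (curve.strain >= lo) & (curve.strain <= hi)
    if mask.sum() < 2:
        raise ValueError("linear region must contain at least 2 samples")
    slope = np.polyfit(curve.strain[mask], curve.load[mask], 1)[0]
    return float(slope)


def max_compression(initial_diameter: float, deformation_diameter: float) -> float:
    """Maximum compression epsilon_max = D / d_bar (dimensionless)."""
    if initial_diameter <= 0:
        raise ValueError("initial_diameter must be positive")
    if deformation_diameter < 0:
        raise ValueError("deformation_diameter must be non-negative")
    return deformation_diameter / initial_diameter


def detect_fracture(
    curve: LoadStrainCurve, drop_fraction: float = 0.3
) -> Optional[float]:
    """Strain at which the bead fractured, or ``None`` if it never did.

    Fracture is flagged at the first sample whose load falls below
    ``(1 - drop_fraction)`` times the running maximum; the reported
    fracture strain is that of the sample immediately preceding the
    confirmed drop -- the last strain at which the bead still carried
    its load.  (Robust to sensor noise on a plastic plateau, where the
    literal load maximum can fall anywhere along the plateau.)
    Ductile beads (PP-like plateau + densification) return ``None``.
    """
    if not 0.0 < drop_fraction < 1.0:
        raise ValueError("drop_fraction must be in (0, 1)")
    load = curve.load
    running_max = np.maximum.accumulate(load)
    with np.errstate(invalid="ignore"):
        dropped = (load < (1.0 - drop_fraction) * running_max) & (running_max > 0)
    idx = np.nonzero(dropped)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    return float(curve.strain[max(i - 1, 0)])


def summarize_curve(
    curve: LoadStrainCurve,
    min_points: int = 5,
    r2_min: float = 0.999,
    drop_fraction: float = 0.3,
) -> CompressionSummary:
    """Full reduction of one curve to a :class:`CompressionSummary`.

    The deformation diameter D is the platen displacement at the
    fracture point, i.e. ``fracture_strain * d_bar``; for an unfractured
    bead it is the displacement at maximum applied strain, and the
    summary is flagged censored.
    """
    region = detect_linear_region(curve, min_points=min_points, r2_min=r2_min)
    k = stiffness(curve, region)
    frac = detect_fracture(curve, drop_fraction=drop_fraction)
    censored = frac is None
    strain_at_d = float(curve.strain[-1]) if censored else frac
    deformation_diameter = strain_at_d * curve.initial_diameter
    eps_max = max_compression(curve.initial_diameter, deformation_diameter)
    return CompressionSummary(
        bead_id=curve.bead_id,
        stiffness=k,
        epsilon_max=eps_max,
        fractured=not censored,
        fracture_strain=frac,
        linear_region=region,
        censored=censored,
    )
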