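"""AFM height-map flattening and surface roughness (Ra, Rq).

Raw AFM scan lines carry a slow bow from piezo nonlinearity and sample
tilt.  Following instrument-software convention, each scan line is
flattened independently by subtracting its least-squares second-order
polynomial in the column index; roughness is then computed on the
residual heights:

    Ra = (1/n) sum |y_i|          (arithmetic roughness, nm)
    Rq = sqrt((1/n) sum y_i^2)    (root-mean-square roughness, nm)

``n`` is the number of sampled points.  ``rq_sqrt=False`` reproduces
the literal no-square-root variant of the RMS formula sometimes seen in
print; the default takes the root so that Rq is in nm and Rq >= Ra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HeightMap", "RoughnessResult", "flatten_second_order", "roughness"]


@dataclass(frozen=True)
class HeightMap:
    """Rectangular grid of heights (nm); rows are scan lines."""

    heights: np.ndarray
    pixel_size: float = 1.0  # nm / pixel
    flattened: bool = False

    def __post_init__(self) -> None:
        h = np.atleast_2d(np.asarray(self.heights, dtype=float))
        object.__setattr__(self, "heights", h)
        if h.ndim != 2:
            raise ValueError("heights must be a 2-D grid")
        if h.shape[1] < 3:
            raise ValueError("each scan line needs >= 3 points for a quadratic fit")
        if not np.all(np.isfinite(h)):
            raise ValueError("heights must be finite")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")


@dataclass(frozen=True)
class RoughnessResult:
    Ra: float  # nm
    Rq: float  # nm


def flatten_second_order(height_map: HeightMap) -> HeightMap:
    """Subtract each scan line's least-squares quadratic in column index.

    Every output line has zero projection onto {1, x, x^2}, so the
    result is invariant to adding any per-line quadratic to the input.
    """
    h = height_map.heights
    ncol = h.shape[1]
    x = np.arange(ncol, dtype=float)
    # Shared Vandermonde basis; one lstsq solves all lines at once.
    basis = np.vander(x, 3, increasing=True)  # columns 1, x, x^2
    coef, *_ = np.linalg.lstsq(basis, h.T, rcond=None)
    residual = h - (basis @ coef).T
    return HeightMap(
        heights=residual, pixel_size=height_map.pixel_size, flattened=True
    )


def roughness(height_map: HeightMap, rq_sqrt: bool = True) -> RoughnessResult:
    """Arithmetic (Ra) and root-mean-square (Rq) roughness in nm.

    The map must be flattened first (``flattened`` flag enforced so that
    tilt and bow never masquerade as roughness).
    """
    if not height_map.flattened:
        raise ValueError("roughness requires a flattened map; run flatten_second_order")
    y = height_map.heights.ravel()
    if y.size == 0:
        raise ValueError("empty height map")
    ra = float(np.mean(np.abs(y)))
    msq = float(np.mean(y**2))
    rq = float(np.sqrt(msq)) if rq_sqrt else msq
    return RoughnessResult(Ra=ra, Rq=rq)
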