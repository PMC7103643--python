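"""ATR-FTIR preprocessing and difference spectroscopy.

Treatment-induced surface chemistry is exposed by subtracting a scaled
control spectrum from the treated spectrum.  The scale factor is chosen
so that the polymer's own bands in the 1500-1350 cm-1 region cancel:
the ordinary least-squares factor

    c = <treated, control> / <control, control>   (on the window)

minimises the window residual, and the difference spectrum
``treated - c * control`` is reported on the full grid.  Residual CO2
signal (2390-2280 and 702-623 cm-1) is removed beforehand with a
least-squares-scaled reference spectrum.  Band positions in difference
spectra are localised as minima of the Savitzky-Golay second
derivative; no baseline correction is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "Spectrum",
    "DifferenceSpectrum",
    "CO2_FIT_WINDOW",
    "CANCELLATION_WINDOW",
    "resample_to_common_grid",
    "subtract_co2",
    "scaled_difference",
    "second_derivative",
    "find_band_positions",
    "average_spectra",
]

# CO2 asymmetric-stretch region used to fit the reference scale factor.
CO2_FIT_WINDOW = (2280.0, 2390.0)
# Polymer-band region over which the control is scaled to cancel.
CANCELLATION_WINDOW = (1350.0, 1500.0)


@dataclass(frozen=True)
class Spectrum:
    """An absorbance spectrum on a strictly monotone wavenumber grid."""

    wavenumber: np.ndarray  # cm-1
    absorbance: np.ndarray  # a.u.
    label: str = ""

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumber, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.size and wn[0] > wn[-1]:  # store ascending
            wn, ab = wn[::-1].copy(), ab[::-1].copy()
        object.__setattr__(self, "wavenumber", wn)
        object.__setattr__(self, "absorbance", ab)
        if wn.ndim != 1 or ab.ndim != 1 or wn.size != ab.size:
            raise ValueError("wavenumber and absorbance must be 1-D, equal length")
        if wn.size < 50:
            raise ValueError("spectrum needs at least 50 points")
        if np.any(np.diff(wn) <= 0):
            raise ValueError("wavenumber grid must be strictly monotone")
        if wn[0] < 400.0 - 1e-9 or wn[-1] > 4000.0 + 1e-9:
            raise ValueError("wavenumber must lie within [400, 4000] cm-1")
        if not np.all(np.isfinite(ab)):
            raise ValueError("absorbance must be finite")

    def slice_window(self, window: Tuple[float, float]) -> np.ndarray:
        lo, hi = min(window), max(window)
        return (self.wavenumber >= lo) & (self.wavenumber <= hi)


@dataclass(frozen=True)
class DifferenceSpectrum:
    difference: Spectrum
    scale_factor: float  # multiplier applied to the control


def _same_grid(a: Spectrum, b: Spectrum) -> bool:
    return a.wavenumber.size == b.wavenumber.size and np.allclose(
        a.wavenumber, b.wavenumber
    )


def resample_to_common_grid(spectra: Sequence[Spectrum]) -> List[Spectrum]:
    """Linear interpolation of all spectra onto their intersection grid.

    The common grid spans the overlap of all wavenumber ranges at the
    coarsest spacing present, preserving input order.
    """
    if not spectra:
        return []
    lo = max(s.wavenumber[0] for s in spectra)
    hi = min(s.wavenumber[-1] for s in spectra)
    if lo >= hi:
        raise ValueError("spectra have disjoint wavenumber ranges")
    step = max(float(np.median(np.diff(s.wavenumber))) for s in spectra)
    grid = np.arange(lo, hi + step / 2, step)
    grid = grid[grid <= hi + 1e-9]
    out = []
    for s in spectra:
        ab = np.interp(grid, s.wavenumber, s.absorbance)
        out.append(Spectrum(wavenumber=grid.copy(), absorbance=ab, label=s.label))
    return out


def subtract_co2(
    spectrum: Spectrum,
    co2_reference: Spectrum,
    fit_window: Tuple[float, float] = CO2_FIT_WINDOW,
) -> Spectrum:
    """Remove residual CO2 bands using a scaled reference spectrum.

    The scale ``c`` is the least-squares factor fitted on the
    2390-2280 cm-1 CO2 window; ``c * reference`` is subtracted over the
    full grid.  Outside the reference's support the spectrum is
    unchanged (up to the reference's straight-line segments).
    """
    if not _same_grid(spectrum, co2_reference):
        spectrum, co2_reference = resample_to_common_grid([spectrum, co2_reference])
    mask = spectrum.slice_window(fit_window)
    ref_w = co2_reference.absorbance[mask]
    denom = float(ref_w @ ref_w)
    if denom == 0.0:
        raise ValueError("CO2 reference is zero on the fit window")
    c = float(spectrum.absorbance[mask] @ ref_w) / denom
    return replace(
        spectrum, absorbance=spectrum.absorbance - c * co2_reference.absorbance
    )


def scaled_difference(
    treated: Spectrum,
    control: Spectrum,
    window: Tuple[float, float] = CANCELLATION_WINDOW,
) -> DifferenceSpectrum:
    """Difference spectrum with the control scaled to cancel polymer bands.

    ``scale_factor = <treated, control> / <control, control>`` on the
    cancellation window; the difference ``treated - c * control`` is
    returned on the full common grid.
    """
    if not _same_grid(treated, control):
        treated, control = resample_to_common_grid([treated, control])
    mask = treated.slice_window(window)
    ctrl_w = control.absorbance[mask]
    denom = float(ctrl_w @ ctrl_w)
    if denom == 0.0:
        raise ValueError("control spectrum is zero on the cancellation window")
    c = float(treated.absorbance[mask] @ ctrl_w) / denom
    diff = Spectrum(
        wavenumber=treated.wavenumber.copy(),
        absorbance=treated.absorbance - c * control.absorbance,
        label=f"{treated.label} - {c:.4g}*{control.label}".strip(),
    )
    return DifferenceSpectrum(difference=diff, scale_factor=c)


def second_derivative(
    spectrum: Spectrum, window_points: int = 9, poly_order: int = 3
) -> Spectrum:
    """Savitzky-Golay second derivative with respect to wavenumber.

    Requires an (approximately) uniform grid; the operator is linear in
    the absorbance.
    """
    if window_points % 2 == 0:
        raise ValueError("window_points must be odd")
    if not window_points > poly_order >= 2:
        raise ValueError("need window_points > poly_order >= 2")
    if spectrum.wavenumber.size < window_points:
        raise ValueError("spectrum shorter than the filter window")
    steps = np.diff(spectrum.wavenumber)
    if np.ptp(steps) > 1e-6 * steps.mean():
        raise ValueError("second derivative requires a uniform wavenumber grid")
    d2 = savgol_filter(
        spectrum.absorbance,
        window_length=window_points,
        polyorder=poly_order,
        deriv=2,
        delta=float(steps.mean()),
    )
    return Spectrum(
        wavenumber=spectrum.wavenumber.copy(), absorbance=d2,
        label=f"d2 {spectrum.label}".strip(),
    )


def find_band_positions(
    d2: Spectrum,
    band_range: Tuple[float, float],
    prominence: float,
) -> List[float]:
    """Band centres: local minima of the second derivative in ``band_range``.

    Minima passing the prominence threshold are returned sorted by
    wavenumber; absorption bands (including shoulders next to a stronger
    band) appear as separate negative lobes of the second derivative.
    May return an empty list.
    """
    mask = d2.slice_window(band_range)
    if not mask.any():
        raise ValueError("band_range outside the spectrum grid")
    wn = d2.wavenumber[mask]
    y = d2.absorbance[mask]
    peaks, _ = find_peaks(-y, prominence=prominence)
    return sorted(float(wn[i]) for i in peaks)


def average_spectra(spectra: Sequence[Spectrum], label: str = "") -> Spectrum:
    """Mean of replicate spectra (resampled to the common grid first)."""
    if not spectra:
        raise ValueError("no spectra to average")
    common = resample_to_common_grid(spectra)
    ab = np.mean([s.absorbance for s in common], axis=0)
    return Spectrum(wavenumber=common[0].wavenumber.copy(), absorbance=ab, label=label)
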