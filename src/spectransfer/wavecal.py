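"""Pixel-to-wavelength calibration and spectral-resolution estimation.

A push-broom imager's spectral axis is calibrated by pointing it at a
monochromator stepped in 1 nm increments (or at a mercury-argon pen lamp)
and recording which detector pixel responds to each known wavelength.  The
pixel -> wavelength mapping is fitted piecewise as two quadratics

    lambda(i) = a * i**2 + b * i + c

joined at a fixed breakpoint pixel, each segment fitted by ordinary least
squares.  Spectral resolution is characterised by the full width at half
maximum (FWHM) of an isolated emission line, measured by linear
interpolation of the half-maximum crossings on each flank after baseline
(scan minimum) subtraction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthCalibration",
    "LineScan",
    "fit_wavelength_calibration",
    "wavelength_for_pixel",
    "estimate_fwhm",
    "reference_imager_calibration",
]


@dataclass
class WavelengthCalibration:
    """Two-segment quadratic pixel -> wavelength map.

    Segment 1 covers pixels ``(pixel_range[0], breakpoint_pixel]``, segment 2
    ``(breakpoint_pixel, pixel_range[1]]`` (half-open intervals).
    """

    breakpoint_pixel: int
    segment_coeffs: tuple[tuple[float, float, float], tuple[float, float, float]]
    pixel_range: tuple[int, int]
    residual_rms_nm: tuple[float, float] = (0.0, 0.0)
    monotone: bool = True

    def __call__(self, i):
        return wavelength_for_pixel(self, i)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "breakpoint_pixel": self.breakpoint_pixel,
                    "segment_coeffs": [list(c) for c in self.segment_coeffs],
                    "pixel_range": list(self.pixel_range),
                    "residual_rms_nm": list(self.residual_rms_nm),
                    "monotone": self.monotone,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "WavelengthCalibration":
        d = json.loads(Path(path).read_text())
        return cls(
            d["breakpoint_pixel"],
            tuple(tuple(c) for c in d["segment_coeffs"]),
            tuple(d["pixel_range"]),
            tuple(d["residual_rms_nm"]),
            d["monotone"],
        )


@dataclass
class LineScan:
    """An intensity scan along pixels or wavelengths (emission-line data)."""

    axis: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.shape != self.intensity.shape or self.axis.ndim != 1:
            raise ValueError("axis and intensity must be equal-length vectors")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")

    @classmethod
    def from_csv(cls, path) -> "LineScan":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def reference_imager_calibration() -> WavelengthCalibration:
    """Published calibration of the reference push-broom imager design.

    Two quadratic segments joined at pixel 944 over pixels (0, 1870]; the
    dispersion runs red-to-blue (wavelength decreases with pixel index).
    """
    return WavelengthCalibration(
        breakpoint_pixel=944,
        segment_coeffs=((-7.44e-6, -0.201, 796.19), (-3.39e-6, -0.208, 799.5)),
        pixel_range=(0, 1870),
    )


def fit_wavelength_calibration(
    pairs, breakpoint_pixel: int, pixel_range: tuple[int, int] | None = None
) -> WavelengthCalibration:
    """Least-squares quadratic fit of (pixel, wavelength) pairs per segment.

    Parameters
    ----------
    pairs : iterable of (pixel, wavelength_nm)
        Calibration observations; each segment needs at least 3.
    breakpoint_pixel : int
        Pixel separating the two segments (exclusive upper bound of seg. 1).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (pixel, wavelength) tuples")
    px, wl = arr[:, 0], arr[:, 1]
    if pixel_range is None:
        pixel_range = (int(np.floor(px.min())) - 1, int(np.ceil(px.max())))
    seg1 = px <= breakpoint_pixel
    coeffs, resid = [], []
    for mask, name in ((seg1, "first"), (~seg1, "second")):
        if mask.sum() < 3:
            raise ValueError(
                f"{name} segment has {int(mask.sum())} pairs; "
                "at least 3 are required for a quadratic fit"
            )
        c = np.polyfit(px[mask], wl[mask], 2)
        coeffs.append(tuple(c))
        resid.append(float(np.sqrt(np.mean((np.polyval(c, px[mask]) - wl[mask]) ** 2))))
    cal = WavelengthCalibration(
        int(breakpoint_pixel), (coeffs[0], coeffs[1]), pixel_range, tuple(resid)
    )
    # monotonicity audit over the integer pixel range
    grid = np.arange(pixel_range[0] + 1, pixel_range[1] + 1)
    lam = wavelength_for_pixel(cal, grid)
    diffs = np.diff(lam)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        cal.monotone = False
        warnings.warn("fitted pixel->wavelength mapping is not strictly monotone")
    join_gap = abs(
        np.polyval(coeffs[0], breakpoint_pixel) - np.polyval(coeffs[1], breakpoint_pixel)
    )
    if join_gap > 1.0:
        warnings.warn(
            f"segments disagree by {join_gap:.3f} nm at the breakpoint pixel"
        )
    return cal


def wavelength_for_pixel(cal: WavelengthCalibration, i):
    """Evaluate the calibration at pixel index/indices ``i`` (nm)."""
    i_arr = np.asarray(i, dtype=float)
    lo, hi = cal.pixel_range
    if np.any(i_arr <= lo) or np.any(i_arr > hi):
        raise ValueError(f"pixel index outside calibrated range ({lo}, {hi}]")
    a1, b1, c1 = cal.segment_coeffs[0]
    a2, b2, c2 = cal.segment_coeffs[1]
    first = i_arr <= cal.breakpoint_pixel
    lam = np.where(
        first,
        a1 * i_arr**2 + b1 * i_arr + c1,
        a2 * i_arr**2 + b2 * i_arr + c2,
    )
    return float(lam) if np.isscalar(i) or np.ndim(i) == 0 else lam


def estimate_fwhm(scan: LineScan, peak_location: float) -> float:
    """FWHM of the emission line nearest ``peak_location``.

    The scan minimum is subtracted as baseline; the half-maximum crossing on
    each flank is located by linear interpolation and the FWHM is their
    separation, in the units of ``scan.axis``.
    """
    y = scan.intensity - scan.intensity.min()
    x = scan.axis
    interior = np.arange(1, y.size - 1)
    is_max = (y[interior] >= y[interior - 1]) & (y[interior] >= y[interior + 1]) & (
        y[interior] > 0
    )
    peaks = interior[is_max]
    if peaks.size == 0:
        raise ValueError("no interior local maximum found in the scan")
    p = peaks[np.argmin(np.abs(x[peaks] - peak_location))]
    half = y[p] / 2.0

    def _crossing(direction: int) -> float:
        j = p
        while 0 <= j + direction < y.size and y[j + direction] >= half:
            j += direction
        k = j + direction
        if k < 0 or k >= y.size:
            raise ValueError("unresolved line: flank never falls below half maximum")
        # linear interpolation between samples j (>= half) and k (< half)
        frac = (y[j] - half) / (y[j] - y[k])
        return x[j] + frac * (x[k] - x[j])

    return float(abs(_crossing(+1) - _crossing(-1)))
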