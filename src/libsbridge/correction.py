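"""Standard-lamp spectral response estimation and cross-instrument correction.

A spectrometer measures ``I_meas(lam) = S(lam) * eta(lam)`` where ``S`` is the
source spectral flux and ``eta`` the instrument's wavelength-dependent
response. Measuring a radiometrically certified lamp with known irradiance
``E(lam)`` gives the response correction factor

    R(lam) = E(lam) / I_lamp(lam)  ∝  1 / eta(lam).

For two instruments L (low resolution) and H (high resolution), the transfer
function ``R_[L/H](lam) = R_H(lam) / R_L(lam) = eta_L / eta_H`` maps an
H-measured spectrum onto the L instrument's response scale:

    I_H(lam) * R_[L/H](lam) = S(lam) * eta_L(lam),

i.e. what L would have measured from the same source (up to resolution).
All grid alignment is piecewise-linear interpolation; the correction is
restricted to the overlap of both instruments with the lamp's certified
range (350-850 nm by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

from .spectra import Spectrum, _validate_grid

__all__ = [
    "ResponseFunction",
    "interp_align",
    "estimate_response",
    "build_transfer",
    "apply_correction",
]


class CorrectionError(ValueError):
    """Raised for invalid response/correction inputs."""


@dataclass
class ResponseFunction:
    """Wavelength-dependent correction factor on a stated valid range."""

    wavelengths: np.ndarray
    values: np.ndarray
    valid_range: tuple[float, float]

    def __post_init__(self) -> None:
        self.wavelengths = _validate_grid(self.wavelengths)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.wavelengths.shape:
            raise CorrectionError("values length must match wavelength grid")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise CorrectionError("response values must be finite and > 0")
        lo, hi = self.valid_range
        if not lo < hi:
            raise CorrectionError("valid_range must satisfy lo < hi")

    def __call__(self, wavelengths) -> np.ndarray:
        lam = np.asarray(wavelengths, dtype=float)
        lo, hi = self.valid_range
        if np.any(lam < lo - 1e-9) or np.any(lam > hi + 1e-9):
            raise CorrectionError(
                f"evaluation outside valid range [{lo}, {hi}] nm"
            )
        return np.interp(lam, self.wavelengths, self.values)

    def smoothed(self, window_nm: float = 1.0) -> "ResponseFunction":
        """Median-then-Savitzky-Golay denoising with a ~window_nm kernel.

        The window is deliberately narrow (about 1 nm): it suppresses
        shot-to-shot noise in the lamp ratio while leaving broadband structure
        — including the few-nm echelle ripple that the correction must cancel
        — essentially intact.
        """
        step = np.median(np.diff(self.wavelengths))
        n = max(int(round(window_nm / step)), 3)
        if n % 2 == 0:
            n += 1
        n = min(n, self.values.size if self.values.size % 2 else self.values.size - 1)
        vals = median_filter(self.values, size=n, mode="nearest")
        if n > 2:
            vals = savgol_filter(vals, n, min(2, n - 1), mode="interp")
        vals = np.clip(vals, np.finfo(float).tiny, None)
        return ResponseFunction(self.wavelengths.copy(), vals, self.valid_range)


def interp_align(s: Spectrum, new_grid) -> Spectrum:
    """Resample a spectrum onto ``new_grid`` by piecewise-linear interpolation.

    The continuous interpolant passes through every measured point exactly;
    extrapolation beyond the source support is refused.
    """
    new_grid = _validate_grid(np.asarray(new_grid, dtype=float))
    lo, hi = s.wavelengths[0], s.wavelengths[-1]
    if new_grid[0] < lo - 1e-12 or new_grid[-1] > hi + 1e-12:
        raise CorrectionError(
            f"target grid [{new_grid[0]:.3f}, {new_grid[-1]:.3f}] nm extends "
            f"outside source support [{lo:.3f}, {hi:.3f}] nm"
        )
    vals = np.interp(new_grid, s.wavelengths, s.intensities)
    return Spectrum(new_grid, vals, s.instrument_id, dict(s.meta))


def estimate_response(
    reference: Spectrum,
    measured: Spectrum,
    floor_frac: float = 1e-6,
    max_masked: float = 0.2,
    smooth: bool = False,
    smooth_window_nm: float = 1.0,
) -> ResponseFunction:
    """Estimate R(lam) = reference / measured on the overlapping support.

    The ratio lives on the measured instrument's grid (restricted to the
    lamp's certified range); the reference is linearly interpolated onto it.
    Points where the measured intensity falls at or below
    ``floor_frac * max(measured)`` are masked and filled by interpolating
    log R from their neighbors; more than ``max_masked`` masked points is an
    error. Optional denoising via :meth:`ResponseFunction.smoothed`.
    """
    lo = max(reference.wavelengths[0], measured.wavelengths[0])
    hi = min(reference.wavelengths[-1], measured.wavelengths[-1])
    if lo >= hi:
        raise CorrectionError("reference and measured lamp spectra do not overlap")
    mask = (measured.wavelengths >= lo) & (measured.wavelengths <= hi)
    lam = measured.wavelengths[mask]
    if lam.size < 2:
        raise CorrectionError("overlap contains fewer than 2 grid points")
    meas = measured.intensities[mask]
    ref = np.interp(lam, reference.wavelengths, reference.intensities)

    floor = floor_frac * np.max(meas)
    bad = meas <= floor
    if bad.mean() > max_masked:
        raise CorrectionError(
            f"{bad.mean():.0%} of measured lamp points at/below the division "
            f"floor (limit {max_masked:.0%})"
        )
    ratio = np.empty_like(meas)
    good = ~bad
    ratio[good] = ref[good] / meas[good]
    if bad.any():
        if ratio[good].min() <= 0:
            raise CorrectionError("non-positive ratio on unmasked points")
        ratio[bad] = np.exp(
            np.interp(lam[bad], lam[good], np.log(ratio[good]))
        )
    resp = ResponseFunction(lam, ratio, (float(lam[0]), float(lam[-1])))
    if smooth:
        resp = resp.smoothed(smooth_window_nm)
    return resp


def build_transfer(
    rl: ResponseFunction,
    rh: ResponseFunction,
    clip_range: tuple[float, float] = (350.0, 850.0),
    grid: np.ndarray | None = None,
) -> ResponseFunction:
    """Form the H-to-L transfer function R_[L/H] = R_H / R_L.

    Both responses are aligned onto a common grid over the intersection of
    their valid ranges, clipped to ``clip_range``. By default the common grid
    is R_H's own grid (the finer one keeps the ripple structure resolvable);
    pass ``grid`` to override.
    """
    lo = max(rl.valid_range[0], rh.valid_range[0], clip_range[0])
    hi = min(rl.valid_range[1], rh.valid_range[1], clip_range[1])
    if lo >= hi:
        raise CorrectionError("response valid ranges do not intersect")
    if grid is None:
        mask = (rh.wavelengths >= lo) & (rh.wavelengths <= hi)
        lam = rh.wavelengths[mask]
    else:
        lam = _validate_grid(np.asarray(grid, dtype=float))
        if lam[0] < lo - 1e-9 or lam[-1] > hi + 1e-9:
            raise CorrectionError("supplied grid extends outside the intersection")
    if lam.size < 2:
        raise CorrectionError("intersection contains fewer than 2 grid points")
    vals = rh(lam) / rl(lam)
    return ResponseFunction(lam, vals, (float(lam[0]), float(lam[-1])))


def apply_correction(s: Spectrum, r: ResponseFunction) -> Spectrum:
    """Multiply a spectrum by a response function on their overlap.

    The output is restricted to the overlap of the spectrum's support with
    the response's valid range; the response is linearly interpolated onto
    the spectrum's grid. Applied to raw (pre-normalization) intensities.
    """
    lo = max(s.wavelengths[0], r.valid_range[0])
    hi = min(s.wavelengths[-1], r.valid_range[1])
    if lo >= hi:
        raise CorrectionError("spectrum does not overlap the response valid range")
    mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    lam = s.wavelengths[mask]
    if lam.size < 2:
        raise CorrectionError("overlap contains fewer than 2 grid points")
    vals = s.intensities[mask] * r(lam)
    return Spectrum(lam, vals, s.instrument_id, dict(s.meta))


def correct_set(sset, r: ResponseFunction):
    """Apply a response correction to every spectrum of a set (shared grid)."""
    from .spectra import LabeledSpectrumSet

    lo = max(sset.wavelengths[0], r.valid_range[0])
    hi = min(sset.wavelengths[-1], r.valid_range[1])
    if lo >= hi:
        raise CorrectionError("set does not overlap the response valid range")
    mask = (sset.wavelengths >= lo) & (sset.wavelengths <= hi)
    lam = sset.wavelengths[mask]
    if lam.size < 2:
        raise CorrectionError("overlap contains fewer than 2 grid points")
    vals = sset.intensities[:, mask] * r(lam)[None, :]
    return LabeledSpectrumSet(lam, vals, sset.labels, sset.instrument_id, sset.meta)
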