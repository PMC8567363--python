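"""Lorentzian line-shape fitting for 1-D spectral traces.

Peaks are parameterized directly by their full width at half maximum (FWHM),
the quantity compared between the cis and trans proline resonances: a
Lorentzian with amplitude A, center x0 and FWHM w is

    L(x) = A (w/2)^2 / ((x - x0)^2 + (w/2)^2)

so L(x0) = A and L(x0 +/- w/2) = A/2.  Fits share one constant baseline per
trace; polynomial baseline correction is considered preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .exceptions import LineshapeFitError

__all__ = ["Spectrum1D", "LorentzianPeak", "lorentzian", "simulate_spectrum",
           "fit_lorentzians"]


@dataclass
class Spectrum1D:
    """A 1-D trace: strictly monotone axis (ppm or Hz) and intensities."""

    axis: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.axis) != len(self.intensities):
            raise ValueError("axis and intensities must have equal length")
        d = np.diff(self.axis)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("axis must be strictly monotone")


@dataclass
class LorentzianPeak:
    """One Lorentzian: center, FWHM (> 0), amplitude (> 0) and shared baseline."""

    center: float
    fwhm: float
    amplitude: float
    baseline: float = 0.0

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def hwhm(self) -> float:
        """Half width at half maximum, w/2."""
        return self.fwhm / 2.0


def lorentzian(x, center: float, fwhm: float, amplitude: float) -> np.ndarray:
    h = fwhm / 2.0
    return amplitude * h * h / ((np.asarray(x, float) - center) ** 2 + h * h)


def simulate_spectrum(peaks: list[LorentzianPeak], noise_sd: float, seed: int,
                      axis: np.ndarray) -> Spectrum1D:
    """Sum of Lorentzians plus baseline(s) plus seeded Gaussian noise."""
    axis = np.asarray(axis, dtype=float)
    lo, hi = min(axis[0], axis[-1]), max(axis[0], axis[-1])
    for p in peaks:
        if not lo <= p.center <= hi:
            raise ValueError(f"peak center {p.center} outside axis range [{lo}, {hi}]")
    y = np.zeros_like(axis)
    for p in peaks:
        y += lorentzian(axis, p.center, p.fwhm, p.amplitude) + p.baseline
    if noise_sd > 0:
        y += np.random.default_rng(seed).normal(0.0, noise_sd, len(axis))
    return Spectrum1D(axis, y)


def _model(params: np.ndarray, x: np.ndarray, n_peaks: int) -> np.ndarray:
    y = np.full_like(x, params[0])        # shared constant baseline
    for i in range(n_peaks):
        c, w, a = params[1 + 3 * i: 4 + 3 * i]
        y += lorentzian(x, c, w, a)
    return y


def _initial_guesses(spectrum: Spectrum1D, n_peaks: int) -> list[tuple[float, float, float]]:
    x, y = spectrum.axis, spectrum.intensities
    base = np.median(y)
    span = abs(x[-1] - x[0])
    spacing = max(2, len(x) // (8 * n_peaks))   # candidate maxima must be apart
    idx, props = find_peaks(y, height=base, distance=spacing)
    if len(idx) >= n_peaks:
        order = np.argsort(props["peak_heights"])[::-1][:n_peaks]
        idx = idx[order]
    else:
        # fall back to the n largest samples, subject to the same spacing
        order = np.argsort(y)[::-1]
        picked = []
        for i in order:
            if all(abs(i - j) >= spacing for j in picked):
                picked.append(i)
            if len(picked) == n_peaks:
                break
        idx = np.array(picked)
    heights = y[idx]
    guesses = []
    for i, h in zip(idx, heights):
        amp = max(h - base, 1e-12)
        guesses.append((float(x[i]), span / 20.0, float(amp)))
    return guesses


def fit_lorentzians(spectrum: Spectrum1D, n_peaks: int,
                    init: list[LorentzianPeak] | None = None,
                    max_nfev: int = 20_000) -> tuple[list[LorentzianPeak], float]:
    """Least-squares fit of an n-peak Lorentzian model with constant baseline.

    Without explicit initial guesses, the ``n_peaks`` tallest local maxima of
    the trace seed the optimizer.  Returns the fitted peaks sorted by center
    (each carrying the shared fitted baseline) and the residual 2-norm.

    Raises
    ------
    LineshapeFitError
        On non-convergence within ``max_nfev`` evaluations, carrying the last
        residual norm.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    x, y = spectrum.axis, spectrum.intensities
    if len(x) < 4 * n_peaks:
        raise ValueError(f"need >= {4 * n_peaks} points to fit {n_peaks} peaks")
    span = abs(x[-1] - x[0])
    lo, hi = min(x[0], x[-1]), max(x[0], x[-1])

    if init is not None:
        if len(init) != n_peaks:
            raise ValueError("init must provide one guess per peak")
        p0 = [init[0].baseline]
        for p in init:
            p0 += [p.center, p.fwhm, p.amplitude]
    else:
        p0 = [float(np.median(y))]
        for c, w, a in _initial_guesses(spectrum, n_peaks):
            p0 += [c, w, a]

    lower = [-np.inf] + [lo, 1e-12, 1e-12] * n_peaks
    upper = [np.inf] + [hi, 10 * span, np.inf] * n_peaks
    p0 = np.clip(p0, lower, upper)

    result = least_squares(lambda p: _model(p, x, n_peaks) - y, p0,
                           bounds=(lower, upper), max_nfev=max_nfev)
    residual_norm = float(np.linalg.norm(result.fun))
    if not result.success:
        raise LineshapeFitError(
            f"Lorentzian fit did not converge: {result.message}", residual_norm
        )
    baseline = float(result.x[0])
    peaks = [
        LorentzianPeak(center=float(result.x[1 + 3 * i]),
                       fwhm=float(result.x[2 + 3 * i]),
                       amplitude=float(result.x[3 + 3 * i]),
                       baseline=baseline)
        for i in range(n_peaks)
    ]
    peaks.sort(key=lambda p: p.center)
    return peaks, residual_norm
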