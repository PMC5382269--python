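"""Lamellar diffraction reduction: Bragg-peak fitting and the repeat period.

Each lamellar (h00) reflection is fitted with a Gaussian on a constant
background; the repeat distance D follows from a linear fit of peak
positions q_x versus order h (Bragg's law q = 2 pi h / D).  A free intercept
absorbs a constant instrumental q offset and is the default; a strict
through-origin fit is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class DiffPattern:
    """1D reduced diffraction curve: q (1/angstrom, increasing) vs counts."""

    q: np.ndarray
    intensity: np.ndarray
    intensity_err: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must have equal length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite intensities")


@dataclass
class PeakFit:
    """Gaussian fit of one Bragg reflection."""

    order: int
    center: float
    center_err: float
    sigma: float
    amplitude: float
    background: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("peak width must be positive")


def _gaussian_bg(q, amplitude, center, sigma, background):
    return amplitude * np.exp(-((q - center) ** 2) / (2.0 * sigma**2)) + background


def fit_bragg_peaks(pattern: DiffPattern, guesses) -> list:
    """Fit a Gaussian plus constant background in each peak window.

    ``guesses`` is a list of (order h, (q_lo, q_hi)) windows, each required
    to contain at least 7 points.  A window showing two comparable local
    maxima triggers a warning; non-convergence raises an error naming the
    window.
    """
    fits = []
    for h, (q_lo, q_hi) in guesses:
        sel = (pattern.q >= q_lo) & (pattern.q <= q_hi)
        q = pattern.q[sel]
        y = pattern.intensity[sel]
        if len(q) < 7:
            raise ValueError(
                f"window ({q_lo}, {q_hi}) for order {h} holds {len(q)} points; "
                "need at least 7"
            )
        background0 = float(np.min(y))
        amp0 = float(np.max(y) - background0)
        if amp0 <= 0:
            raise ValueError(f"window ({q_lo}, {q_hi}) has no intensity maximum")
        center0 = float(q[np.argmax(y)])
        sigma0 = max((q_hi - q_lo) / 8.0, 1e-6)
        _warn_if_double_peak(q, y, h)
        try:
            popt, pcov = curve_fit(
                _gaussian_bg,
                q,
                y,
                p0=[amp0, center0, sigma0, background0],
                maxfev=10000,
            )
        except RuntimeError as exc:
            raise RuntimeError(
                f"Gaussian fit did not converge in window ({q_lo}, {q_hi}) "
                f"for order {h}"
            ) from exc
        amp, center, sigma, background = popt
        center_err = float(np.sqrt(np.abs(pcov[1, 1])))
        if not q_lo <= center <= q_hi:
            raise RuntimeError(
                f"fitted center {center:.5f} left the window ({q_lo}, {q_hi}) "
                f"for order {h}"
            )
        fits.append(
            PeakFit(
                order=int(h),
                center=float(center),
                center_err=center_err,
                sigma=float(abs(sigma)),
                amplitude=float(amp),
                background=float(background),
            )
        )
    return fits


def _warn_if_double_peak(q, y, h) -> None:
    from scipy.signal import find_peaks

    prominence = 0.3 * (np.max(y) - np.min(y))
    idx, _ = find_peaks(y, prominence=prominence)
    if len(idx) > 1:
        warnings.warn(f"window for order {h} contains two intensity maxima")


def lamellar_period(peaks, intercept: str = "free"):
    """Lamellar repeat distance from peak positions vs diffraction order.

    Least squares of q_x versus h; D = 2 pi / slope, with dD propagated from
    the slope error.  ``intercept`` is "free" (default; absorbs an
    instrumental q offset) or "zero" (strict Bragg's law through the
    origin).  Returns (D, dD) in angstroms.
    """
    peaks = list(peaks)
    orders = np.asarray([p.order for p in peaks], dtype=float)
    q = np.asarray([p.center for p in peaks], dtype=float)
    if len(peaks) < 2 or len(np.unique(orders)) < 2:
        raise ValueError("need at least two peaks with distinct orders")
    n = len(q)
    if intercept == "free":
        h_mean = orders.mean()
        sxx = float(np.sum((orders - h_mean) ** 2))
        slope = float(np.sum((orders - h_mean) * (q - q.mean())) / sxx)
        resid = q - q.mean() - slope * (orders - h_mean)
        dof = n - 2
        slope_err = (
            float(np.sqrt(np.sum(resid**2) / dof / sxx)) if dof > 0 else np.nan
        )
    elif intercept == "zero":
        shh = float(np.sum(orders**2))
        slope = float(np.sum(orders * q) / shh)
        resid = q - slope * orders
        dof = n - 1
        slope_err = (
            float(np.sqrt(np.sum(resid**2) / dof / shh)) if dof > 0 else np.nan
        )
    else:
        raise ValueError("intercept must be 'free' or 'zero'")
    if slope <= 0:
        raise ValueError("non-positive slope: peak positions inconsistent")
    d_spacing = 2.0 * np.pi / slope
    d_err = 2.0 * np.pi * slope_err / slope**2 if np.isfinite(slope_err) else np.nan
    return float(d_spacing), float(d_err)


def bilayer_separation(d_spacing: float, d_bilayer: float) -> float:
    """Water-layer thickness D_w = D - d_bilayer (angstroms)."""
    if d_spacing <= d_bilayer:
        raise ValueError(
            f"lamellar period {d_spacing} must exceed bilayer thickness {d_bilayer}"
        )
    return d_spacing - d_bilayer


def auto_windows(d_guess: float, orders, half_width: float = None):
    """Peak windows centred on 2 pi h / d_guess for each order."""
    orders = list(orders)
    if half_width is None:
        half_width = 0.35 * 2.0 * np.pi / d_guess
    return [
        (h, (2.0 * np.pi * h / d_guess - half_width, 2.0 * np.pi * h / d_guess + half_width))
        for h in orders
    ]
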