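"""Scalar thermodynamic estimators.

Covers the water-layer thickness definition D_w = 2 n_w v_w0 / A_l, the
partial water volume dV/dN_w, the area compressibility modulus from area
fluctuations with block errors, the area thermal expansion coefficient, and
the conversion between relative humidity and equivalent osmotic pressure
including its error propagation.
"""

from __future__ import annotations

import numpy as np

from .constants import (
    BAR_PER_KJMOL_NM3,
    DEFAULT_CONSTANTS,
    Constants,
    K_B_SI,
)
from .frame import Curve


def dw_from_hydration(
    n_w: float, a_l: float, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Water-layer thickness D_w = 2 n_w v_w0 / A_l (nm)."""
    if a_l <= 0:
        raise ValueError("area per lipid must be positive")
    if n_w < 0:
        raise ValueError("n_w must be non-negative")
    return 2.0 * n_w * constants.v_w0 / a_l


def hydration_from_dw(
    d_w: float, a_l: float, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Inverse of :func:`dw_from_hydration`: waters per lipid from D_w."""
    if a_l <= 0:
        raise ValueError("area per lipid must be positive")
    return d_w * a_l / (2.0 * constants.v_w0)


def partial_water_volume(
    volume_series: Curve,
    window: int = 5,
    order: int = 2,
    a_l: float | None = None,
    n_lipids: int | None = None,
    constants: Constants = DEFAULT_CONSTANTS,
) -> Curve:
    """Partial water volume v_w = dV/dN_w from a local polynomial fit.

    ``volume_series`` holds system volume (nm^3) vs total water number N_w.
    A centered polynomial of the given order is fitted over a sliding
    ``window`` of points and differentiated at each grid point; windows are
    clamped at the edges.  When ``a_l`` and ``n_lipids`` are given, the
    output x axis is D_w (nm) via the hydration relation, else N_w.
    """
    n_w = np.asarray(volume_series.x, dtype=float)
    vol = np.asarray(volume_series.y, dtype=float)
    if len(n_w) < 3:
        raise ValueError("need at least three hydration levels")
    if np.any(np.diff(n_w) <= 0):
        raise ValueError("N_w values must be strictly increasing (no duplicates)")
    window = max(order + 1, min(window, len(n_w)))
    half = window // 2
    deriv = np.empty(len(n_w))
    err = np.zeros(len(n_w))
    for i in range(len(n_w)):
        lo = max(0, min(i - half, len(n_w) - window))
        sel = slice(lo, lo + window)
        x0 = n_w[i]
        xs = n_w[sel] - x0
        k = min(order, len(xs) - 1)
        coef, cov = _polyfit_cov(xs, vol[sel], k)
        deriv[i] = coef[-2] if k >= 1 else 0.0  # d/dx at x=0
        if cov is not None and k >= 1:
            err[i] = np.sqrt(max(cov[-2, -2], 0.0))
    if a_l is not None and n_lipids is not None:
        x_out = np.array(
            [dw_from_hydration(nw / n_lipids, a_l, constants) for nw in n_w]
        )
        x_unit = "nm"
    else:
        x_out = n_w
        x_unit = "waters"
    return Curve(x=x_out, y=deriv, y_err=err, x_unit=x_unit, y_unit="nm^3")


def _polyfit_cov(x, y, order):
    coef = np.polyfit(x, y, order)
    resid = y - np.polyval(coef, x)
    dof = len(x) - (order + 1)
    if dof <= 0:
        return coef, None
    s2 = float(resid @ resid) / dof
    v = np.vander(x, order + 1)
    try:
        cov = s2 * np.linalg.inv(v.T @ v)
    except np.linalg.LinAlgError:
        cov = None
    return coef, cov


def area_compressibility(
    area_series: Curve, temperature: float = 300.0, n_blocks: int = 8
):
    """Area compressibility modulus from equilibrium area fluctuations.

    K_A = k_B T <A> / (<A^2> - <A>^2) with areas in nm^2; returned in J/m^2.
    The error is the standard deviation of per-block estimates (the series
    is split into ``n_blocks`` contiguous blocks).
    """
    if not 2 <= n_blocks <= 50:
        raise ValueError("n_blocks out of range")
    areas = np.asarray(area_series.y, dtype=float)
    if len(areas) < 10 * n_blocks:
        raise ValueError(f"series too short: need >= {10 * n_blocks} samples")
    var = float(np.var(areas))
    if var == 0.0:
        raise ValueError("zero area variance: compressibility undefined")
    k_a = K_B_SI * temperature * float(np.mean(areas)) * 1e18 / var
    block_vals = []
    for block in np.array_split(areas, n_blocks):
        bv = float(np.var(block))
        if bv > 0:
            block_vals.append(K_B_SI * temperature * float(np.mean(block)) * 1e18 / bv)
    err = float(np.std(block_vals, ddof=1)) if len(block_vals) > 1 else np.nan
    return k_a, err


def area_expansion(a_vs_t: Curve):
    """Area thermal expansion coefficient alpha_A = (1/<A>) dA/dT (1/K).

    Returns (alpha_A, standard error) from a linear fit of A(T).
    """
    t = np.asarray(a_vs_t.x, dtype=float)
    a = np.asarray(a_vs_t.y, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("need at least two distinct temperatures")
    coef, cov = _polyfit_cov(t, a, 1)
    slope = coef[0]
    mean_a = float(np.mean(a))
    alpha = slope / mean_a
    err = np.sqrt(cov[0, 0]) / abs(mean_a) if cov is not None else 0.0
    return float(alpha), float(err)


def humidity_to_pressure(
    h_rel: float, temperature: float = 300.0, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Equivalent osmotic pressure of a vapour at relative humidity h_rel.

    Pi = -(k_B T / v_w0) ln(h_rel), in bar; h_rel in (0, 1].
    """
    if not 0.0 < h_rel <= 1.0:
        raise ValueError("relative humidity must lie in (0, 1]")
    from .constants import kt_kjmol

    kt = kt_kjmol(temperature)
    return -(kt / constants.v_w0) * np.log(h_rel) * BAR_PER_KJMOL_NM3


def pressure_error(
    pi_bar: float,
    delta_h: float = 0.02,
    temperature: float = 300.0,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """Osmotic-pressure uncertainty from the humidity-sensor accuracy.

    delta_Pi = (k_B T / v_w0) * delta_h * exp(Pi v_w0 / (k_B T)) — the
    humidity has been eliminated in favour of Pi, so the error grows
    exponentially towards strong dehydration.
    """
    if delta_h < 0:
        raise ValueError("delta_h must be non-negative")
    from .constants import kt_kjmol

    kt = kt_kjmol(temperature)
    scale = kt / constants.v_w0 * BAR_PER_KJMOL_NM3  # bar
    return scale * delta_h * np.exp(pi_bar / scale)
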