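"""Pressure-distance curve analysis.

Exponential fits of the hydration repulsion Pi(D_w) = Pi0 exp(-D_w/lambda),
integration to the interaction free energy per lipid, regression of free
energy against the hydrogen-bond balance, and the equilibrium separation
where the exponential repulsion balances van der Waals attraction between
membrane half-spaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import brentq

from .constants import KJMOL_PER_BAR_NM3
from .frame import Curve


@dataclass
class PDCurve:
    """Interaction pressure (bar) vs water-layer thickness (nm)."""

    d_w: np.ndarray
    pi: np.ndarray
    pi_err: np.ndarray | None = None
    source: str = "simulation"

    def __post_init__(self) -> None:
        self.d_w = np.asarray(self.d_w, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.d_w.shape != self.pi.shape:
            raise ValueError("d_w and pi must have equal length")
        if np.any(np.diff(self.d_w) <= 0):
            raise ValueError("d_w must be strictly increasing")
        if not (np.all(np.isfinite(self.d_w)) and np.all(np.isfinite(self.pi))):
            raise ValueError("non-finite values in pressure-distance curve")
        if self.pi_err is not None:
            self.pi_err = np.asarray(self.pi_err, dtype=float)
        if self.source not in ("simulation", "experiment", "synthetic"):
            raise ValueError(f"unknown source {self.source!r}")

    def __len__(self) -> int:
        return len(self.d_w)


@dataclass
class ExpFit:
    """Exponential decay fit Pi(D) = pi0 exp(-D/lam)."""

    pi0: float
    lam: float
    pi0_err: float
    lam_err: float
    covariance: np.ndarray
    fit_window: tuple

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("decay length must be positive")

    def __call__(self, d):
        return self.pi0 * np.exp(-np.asarray(d, dtype=float) / self.lam)


def fit_exponential_decay(curve: PDCurve, window=None) -> ExpFit:
    """Weighted least squares of ln(Pi) vs D_w (straight line in semi-log).

    Points with non-positive Pi are excluded with a warning; relative
    pressure errors weight the log-fit when available.
    """
    d = curve.d_w
    p = curve.pi
    err = curve.pi_err
    if window is not None:
        lo, hi = window
        sel = (d >= lo) & (d <= hi)
        d, p = d[sel], p[sel]
        err = err[sel] if err is not None else None
    pos = p > 0
    if not pos.all():
        warnings.warn(
            f"excluding {np.count_nonzero(~pos)} non-positive pressures from "
            "the exponential fit"
        )
        d, p = d[pos], p[pos]
        err = err[pos] if err is not None else None
    if len(d) < 3:
        raise ValueError("need at least three points with positive pressure")
    y = np.log(p)
    x = sm.add_constant(d)
    if err is not None and np.all(err > 0):
        w = (p / err) ** 2  # sigma_lnPi = pi_err / pi
        model = sm.WLS(y, x, weights=w)
    else:
        model = sm.OLS(y, x)
    res = model.fit()
    intercept, slope = res.params
    if slope >= 0:
        raise ValueError("pressure does not decay over the fit window")
    lam = -1.0 / slope
    pi0 = float(np.exp(intercept))
    cov = np.asarray(res.cov_params())
    lam_err = float(np.sqrt(cov[1, 1]) / slope**2)
    pi0_err = float(pi0 * np.sqrt(cov[0, 0]))
    return ExpFit(
        pi0=pi0,
        lam=float(lam),
        pi0_err=pi0_err,
        lam_err=lam_err,
        covariance=cov,
        fit_window=(float(d.min()), float(d.max())),
    )


def free_energy_curve(
    curve: PDCurve, a_l: float, tail: ExpFit, per_lipid_factor: float = 0.5
) -> Curve:
    """Interaction free energy per lipid by integrating Pi(D_w).

    G/N_l(D) = f A_l [ int_D^{Dmax} Pi dD' + Pi0 lam exp(-Dmax/lam) ]
    in kJ/mol, with the analytic exponential tail beyond the last point.
    The default prefactor f = 1/2 reflects that each water layer is shared
    by two leaflets; ``per_lipid_factor=1`` assigns it to one.
    """
    if a_l <= 0:
        raise ValueError("area per lipid must be positive")
    d = curve.d_w
    p = curve.pi
    # cumulative integral from each point to the last (trapezoid)
    seg = 0.5 * (p[1:] + p[:-1]) * np.diff(d)
    inner = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
    tail_int = tail.pi0 * tail.lam * np.exp(-d[-1] / tail.lam)
    g = per_lipid_factor * a_l * (inner + tail_int) * KJMOL_PER_BAR_NM3
    return Curve(x=d, y=g, x_unit="nm", y_unit="kJ/mol", meta={"a_l": a_l})


def hb_free_energy_regression(g_per_lipid, delta_nhb):
    """OLS of G/N_l against the hydrogen-bond balance change.

    Returns a dict with slope (kJ/mol per bond), intercept, their standard
    errors, R^2 and whether the intercept is statistically consistent with
    zero (|t| < 2).
    """
    g = np.asarray(g_per_lipid, dtype=float)
    dn = np.asarray(delta_nhb, dtype=float)
    if g.shape != dn.shape or len(g) < 3:
        raise ValueError("need equally long arrays with at least three points")
    if np.ptp(dn) == 0:
        raise ValueError("degenerate regression: constant Delta N_HB")
    res = sm.OLS(g, sm.add_constant(dn)).fit()
    intercept, slope = res.params
    int_err, slope_err = np.sqrt(np.diag(res.cov_params()))
    t_int = intercept / int_err if int_err > 0 else np.inf
    return {
        "slope": float(slope),
        "slope_err": float(slope_err),
        "intercept": float(intercept),
        "intercept_err": float(int_err),
        "r_squared": float(res.rsquared),
        "intercept_consistent_with_zero": bool(abs(t_int) < 2.0),
    }


# ---------------------------------------------------------------------------
# equilibrium separation and adhesion
# ---------------------------------------------------------------------------

def interaction_free_energy_per_area(d_nm, rep: ExpFit, hamaker: float):
    """g(D) = Pi0 lam exp(-D/lam) - H/(12 pi D^2), in J/m^2 (D in nm)."""
    d = np.asarray(d_nm, dtype=float) * 1e-9
    pi0 = rep.pi0 * 1e5  # Pa
    lam = rep.lam * 1e-9
    return pi0 * lam * np.exp(-d / lam) - hamaker / (12.0 * np.pi * d**2)


def _g_prime(d_m, pi0_pa, lam_m, hamaker):
    return -pi0_pa * np.exp(-d_m / lam_m) + hamaker / (6.0 * np.pi * d_m**3)


def equilibrium_and_adhesion(rep: ExpFit, hamaker: float):
    """Equilibrium separation and adhesion energy of the membrane stack.

    Balances the exponential hydration repulsion against the half-space
    van der Waals attraction -H/(12 pi D^2).  Returns (D_eq in nm, G_adh in
    mJ/m^2) where G_adh = -H/(12 pi D_eq^2) approximates the minimum depth
    by its van der Waals part (the exponential tail is neglected).
    """
    if hamaker <= 0:
        raise ValueError("Hamaker constant must be positive")
    pi0_pa = rep.pi0 * 1e5
    lam_m = rep.lam * 1e-9
    grid = np.geomspace(0.02e-9, 50e-9, 4000)
    gp = _g_prime(grid, pi0_pa, lam_m, hamaker)
    # a minimum of g has g' crossing from negative to positive
    rising = np.flatnonzero((gp[:-1] < 0) & (gp[1:] >= 0))
    if rising.size == 0:
        raise ValueError(
            "no interior free-energy minimum: repulsion/attraction never balance"
        )
    i = rising[0]
    d_eq_m = brentq(
        _g_prime,
        grid[i],
        grid[i + 1],
        args=(pi0_pa, lam_m, hamaker),
        xtol=1e-6 * 1e-9,
    )
    d_eq_nm = d_eq_m * 1e9
    g_adh = -hamaker / (12.0 * np.pi * d_eq_m**2) * 1e3  # mJ/m^2
    return float(d_eq_nm), float(g_adh)


def adhesion_ratio(d1_nm: float, d2_nm: float) -> float:
    """Adhesion-strength ratio (d1/d2)^-2 from the D^-2 scaling of the
    van der Waals minimum depth (equal Hamaker constants assumed)."""
    if d1_nm <= 0 or d2_nm <= 0:
        raise ValueError("separations must be positive")
    return (d1_nm / d2_nm) ** (-2)
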