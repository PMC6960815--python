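"""Low-force scaling analysis of force-extension curves.

Below about kBT/lp (~1 pN here) the chain behaves as a freely-jointed
sequence of Kuhn segments.  Two sub-regimes are fitted:

* linear response, F < 0.3 pN:  Lz/(M l0) = beta F lK / 3, giving the Kuhn
  length lK = 2 lp - l0 (fluctuation-dissipation);
* Pincus power law, 0.3 <= F <= 1 pN:  Lz ~ F^(1/nu - 1), where nu = 1/2
  recovers the phantom chain and nu = 3/5 the self-avoiding
  (electrostatically swollen) limit.

Across conditions the fitted exponent is summarized by the linear relation
nu = m theta + n against the zero-force degree of protonation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import units
from .chain import ChainTopology


class InsufficientDataError(ValueError):
    """Too few points inside the fit window."""


#: exponents outside this range are physically implausible here and flagged
NU_SANITY = (0.45, 0.8)


@dataclass
class ForceExtensionCurve:
    """Mean extension <r_z> (nm) versus applied force (pN), with errors."""

    forces: np.ndarray
    extensions: np.ndarray
    extension_se: np.ndarray | None = None
    condition: dict = field(default_factory=dict)

    def __post_init__(self):
        self.forces = np.asarray(self.forces, dtype=float)
        self.extensions = np.asarray(self.extensions, dtype=float)
        if self.extension_se is not None:
            self.extension_se = np.asarray(self.extension_se, dtype=float)
        if self.forces.size != self.extensions.size:
            raise ValueError("forces and extensions differ in length")
        if np.any(np.diff(self.forces) <= 0):
            raise ValueError("forces must be strictly increasing")

    def window(self, lo: float, hi: float):
        m = (self.forces >= lo) & (self.forces <= hi)
        se = None if self.extension_se is None else self.extension_se[m]
        return self.forces[m], self.extensions[m], se


@dataclass
class ScalingFit:
    """Fitted exponent/coefficients with window and residual diagnostics."""

    nu: float | None = None
    nu_se: float | None = None
    amplitude: float | None = None
    kuhn_length: float | None = None
    kuhn_length_se: float | None = None
    persistence_length: float | None = None
    fit_window: tuple[float, float] = (0.0, math.inf)
    residual_norm: float = 0.0
    n_points: int = 0
    flagged: bool = False


def pincus_window(persistence_length: float,
                  base: tuple[float, float] = (0.3, 1.0)
                  ) -> tuple[float, float]:
    """Fit window for the Pincus law, capped by the low-force criterion.

    The power-law regime lives inside the low-force region F < kBT/lp; for
    stiff (highly charged, weakly screened) chains kBT/lp drops below the
    nominal 1 pN upper bound, so the window is capped at kBT/lp computed
    from the zero-force persistence length of the same condition.
    """
    if persistence_length <= 0:
        raise ValueError("persistence length must be > 0")
    f_regime = units.KT_PN_NM / persistence_length
    return (base[0], min(base[1], max(f_regime, base[0] * 1.5)))


def _weights(se, n):
    if se is None or np.any(~np.isfinite(se)) or np.any(se <= 0):
        return np.ones(n)
    return 1.0 / se ** 2


def fit_linear_regime(curve: ForceExtensionCurve, topology: ChainTopology,
                      f_max: float = 0.3) -> ScalingFit:
    """Zero-intercept fit of the linear-response law; returns lK and lp.

    Points with F < ``f_max`` (pN) enter a weighted least-squares fit of
    Lz = (M l0 / 3) beta lK F; the implied persistence length is
    lp = (lK + l0) / 2.
    """
    f, lz, se = curve.window(0.0, f_max * (1.0 - 1e-12))
    if f.size < 2:
        raise InsufficientDataError(
            f"need >= 2 points below {f_max} pN, got {f.size}")
    w = _weights(se, f.size)
    slope = float((w * f * lz).sum() / (w * f * f).sum())
    var_slope = float(1.0 / (w * f * f).sum()) if se is not None else math.nan
    coef = topology.n_bonds * topology.l0 / (3.0 * units.KT_PN_NM)
    lk = slope / coef
    lk_se = math.sqrt(var_slope) / coef if np.isfinite(var_slope) else math.nan
    resid = lz - slope * f
    return ScalingFit(
        kuhn_length=lk, kuhn_length_se=lk_se,
        persistence_length=(lk + topology.l0) / 2.0,
        fit_window=(0.0, f_max),
        residual_norm=float(np.sqrt((w * resid ** 2).sum())),
        n_points=int(f.size))


def fit_pincus(curve: ForceExtensionCurve,
               window: tuple[float, float] = (0.3, 1.0)) -> ScalingFit:
    """Power-law fit Lz ~ F^(1/nu - 1) on the Pincus window.

    A weighted least-squares line in log-log coordinates gives the slope
    1/nu - 1; exponents outside the plausible range are flagged (reported,
    not silently discarded).
    """
    f, lz, se = curve.window(*window)
    if f.size < 3:
        raise InsufficientDataError(
            f"need >= 3 points in {window} pN, got {f.size}")
    if np.any(lz <= 0):
        raise ValueError("non-positive extensions in the Pincus window")
    x = np.log(f)
    y = np.log(lz)
    se_log = None if se is None else se / lz
    w = _weights(se_log, f.size)
    W = w.sum()
    xb = (w * x).sum() / W
    yb = (w * y).sum() / W
    sxx = (w * (x - xb) ** 2).sum()
    slope = float((w * (x - xb) * (y - yb)).sum() / sxx)
    intercept = float(yb - slope * xb)
    resid = y - slope * x - intercept
    if se_log is not None and np.all(np.isfinite(se_log)) \
            and np.all(se_log > 0):
        var_slope = 1.0 / sxx
    else:
        dof = max(f.size - 2, 1)
        var_slope = float((resid ** 2).sum() / dof / sxx)
    nu = 1.0 / (1.0 + slope)
    nu_se = math.sqrt(var_slope) * nu ** 2  # |d nu/d slope| = nu^2
    return ScalingFit(
        nu=nu, nu_se=nu_se, amplitude=math.exp(intercept),
        fit_window=window,
        residual_norm=float(np.sqrt((w * resid ** 2).sum())),
        n_points=int(f.size),
        flagged=not (NU_SANITY[0] <= nu <= NU_SANITY[1]))


def fit_nu_vs_theta(thetas, nus, nu_ses=None):
    """Least-squares line nu = m theta + n with coefficient errors.

    Returns ``(m, n, se_m, se_n)``.  When per-point errors are supplied the
    fit is weighted by 1/SE^2 and the coefficient errors come from the
    weighted normal equations; otherwise from the residual variance.
    """
    th = np.asarray(thetas, dtype=float)
    nu = np.asarray(nus, dtype=float)
    if th.size < 2:
        raise InsufficientDataError("need >= 2 (theta, nu) points")
    if np.ptp(th) < 1e-12:
        raise ValueError("degenerate theta values: slope is not identifiable")
    w = _weights(None if nu_ses is None else np.asarray(nu_ses, float),
                 th.size)
    X = np.column_stack([th, np.ones_like(th)])
    XtW = X.T * w
    A = XtW @ X
    beta = np.linalg.solve(A, XtW @ nu)
    resid = nu - X @ beta
    if nu_ses is not None:
        cov = np.linalg.inv(A)
    else:
        dof = max(th.size - 2, 1)
        cov = np.linalg.inv(A) * float((resid ** 2).sum() / dof)
    m, n = float(beta[0]), float(beta[1])
    return m, n, float(math.sqrt(cov[0, 0])), float(math.sqrt(cov[1, 1]))
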