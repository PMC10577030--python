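"""Allometric scaling fits and predicted force-mass relations.

Scaling relations are characterised by ordinary least squares on
log10-transformed data: the *elevation* (log10 intercept) and *slope*
(allometric exponent) with t-based 95 % confidence intervals.  A
semi-log variant covers quantities that can be negative (the wear
index).  The isometric edge-radius model R = a * m^(1/3), anchored at a
reference radius, feeds the fracture-force model to predict how cutting
force should scale with body mass; the prediction is itself summarised
by a log-log fit, in mN-mg units, so its elevation and slope compare
directly with measured scaling coefficients.

Also here: coefficient-of-variation comparison via the Feltz-Miller
asymptotic equality test, and the expected amplification of fracture
force with cutting speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .materials import MaterialSpec
from .sharpness import CuttingToolSpec, fracture_force

__all__ = [
    "ScalingFit",
    "loglog_fit",
    "semilog_fit",
    "IsometricRadiusModel",
    "isometric_model_from_reference",
    "PredictedScaling",
    "predict_scaling",
    "coefficient_of_variation",
    "cv_equality_test",
    "rate_amplification",
]


@dataclass(frozen=True)
class ScalingFit:
    """An OLS scaling relation: elevation, slope, R^2 and 95 % CIs."""

    elevation: float
    slope: float
    r_squared: float
    ci_elevation: tuple[float, float]
    ci_slope: tuple[float, float]
    n: int


def _ols_fit(x: np.ndarray, y: np.ndarray) -> ScalingFit:
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(0.05)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(res.rsquared)  # undefined (nan/inf) for a constant response
    return ScalingFit(
        elevation=float(res.params[0]),
        slope=float(res.params[1]),
        r_squared=r2,
        ci_elevation=(float(ci[0][0]), float(ci[0][1])),
        ci_slope=(float(ci[1][0]), float(ci[1][1])),
        n=int(res.nobs),
    )


def loglog_fit(x: np.ndarray, y: np.ndarray) -> ScalingFit:
    """OLS of log10(y) on log10(x); both variables must be positive."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-d arrays")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("log-log fit needs strictly positive data; "
                         "use semilog_fit for sign-indefinite responses")
    return _ols_fit(np.log10(x), np.log10(y))


def semilog_fit(x: np.ndarray, y: np.ndarray) -> ScalingFit:
    """OLS of untransformed y on log10(x), for responses that may be
    negative (e.g. the wear index)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-d arrays")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0):
        raise ValueError("x must be strictly positive")
    return _ols_fit(np.log10(x), y)


@dataclass(frozen=True)
class IsometricRadiusModel:
    """Isometric null model for the cutting-edge radius, R = a * m^(1/3).

    ``a`` is in m per mg^(1/3) so that ``radius`` takes mass in mg and
    returns metres.
    """

    a: float
    reference: tuple[float, float] | None = None  # (R_ref m, m_ref mg)

    def radius(self, body_mass_mg: np.ndarray | float) -> np.ndarray | float:
        return self.a * np.asarray(body_mass_mg, dtype=float) ** (1.0 / 3.0)


def isometric_model_from_reference(R_ref: float, m_ref: float) -> IsometricRadiusModel:
    """Anchor the isometric radius model at a known (R_ref, m_ref).

    ``a = R_ref / m_ref^(1/3)``; by construction ``radius(m_ref)``
    returns ``R_ref``.
    """
    if R_ref < 0 or m_ref <= 0:
        raise ValueError("need R_ref >= 0 and m_ref > 0")
    return IsometricRadiusModel(a=R_ref / m_ref ** (1.0 / 3.0),
                                reference=(R_ref, m_ref))


@dataclass(frozen=True)
class PredictedScaling:
    """Predicted force-mass curve and its log-log summary fit."""

    masses_mg: np.ndarray
    forces_N: np.ndarray
    fit: ScalingFit  # log10(F in mN) vs log10(m in mg)


def predict_scaling(
    model: IsometricRadiusModel,
    material: MaterialSpec,
    mu: float = 1.0,
    mass_range: tuple[float, float] = (2.1, 46.4),
    n_grid: int = 100,
    masses_mg: np.ndarray | None = None,
) -> PredictedScaling:
    """Predict cutting-force scaling under the isometric radius model.

    Evaluates F_f(m) = G_c t + C sigma_c R(m) t on a log10-uniform mass
    grid (default; or on supplied masses, e.g. the observed specimen
    masses) and fits log10 F (mN) against log10 m (mg).  The default
    range spans the callow size range 2.1-46.4 mg.
    """
    if masses_mg is None:
        lo, hi = mass_range
        if not 0 < lo < hi:
            raise ValueError("mass_range must be positive and increasing")
        if n_grid < 10:
            raise ValueError("n_grid must be at least 10")
        masses_mg = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    else:
        masses_mg = np.asarray(masses_mg, dtype=float)
        if np.any(masses_mg <= 0):
            raise ValueError("masses must be positive")
    radii = np.asarray(model.radius(masses_mg), dtype=float)
    forces = np.array([
        fracture_force(material, CuttingToolSpec(R=float(r), mu=mu)) for r in radii
    ])
    fit = loglog_fit(masses_mg, forces * 1e3)
    return PredictedScaling(masses_mg=masses_mg, forces_N=forces, fit=fit)


def coefficient_of_variation(values: np.ndarray) -> float:
    """Sample CV, sd/mean (sd with n-1 degrees of freedom)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(v.std(ddof=1) / mean)


def cv_equality_test(groups: list[np.ndarray]) -> tuple[float, float]:
    """Feltz-Miller asymptotic test for equality of CVs across groups.

    Returns (D_AD, p); the statistic is chi-square distributed with
    k - 1 degrees of freedom under the null of equal CVs.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    cvs = np.array([coefficient_of_variation(g) for g in groups])
    m = np.array([len(g) - 1 for g in groups], dtype=float)
    pooled = float((m * cvs).sum() / m.sum())
    if pooled == 0:
        return 0.0, 1.0
    stat = float((m * (cvs - pooled) ** 2).sum() / (pooled**2 * (0.5 + pooled**2)))
    p = float(stats.chi2.sf(stat, df=len(groups) - 1))
    return stat, p


def rate_amplification(
    v1: float,
    v2: float,
    mode: str = "tearing",
    exponent: float | None = None,
) -> float:
    """Expected force ratio when cutting speed changes from v1 to v2.

    In tearing, viscoelastic losses amplify the critical force with the
    square root of crack speed, so the ratio is sqrt(v2/v1) (a 3x speed
    increase gives ~1.73, i.e. roughly +75 %).  Cutting shows a much
    weaker dependence; ``mode='observed_exponent'`` evaluates
    ``(v2/v1)**exponent`` for an empirically determined exponent.
    """
    if v1 <= 0 or v2 <= 0:
        raise ValueError("speeds must be positive")
    if mode == "tearing":
        return math.sqrt(v2 / v1)
    if mode == "observed_exponent":
        if exponent is None:
            raise ValueError("observed_exponent mode requires an exponent")
        return (v2 / v1) ** exponent
    raise ValueError(f"unknown mode {mode!r}")
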