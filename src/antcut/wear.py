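"""Mandibular wear indices from tooth-length morphometry.

Freshly eclosed workers (callows) have never cut leaves, so their
mandibles define the pristine state.  Pristine tooth length for any
body mass is estimated from a log-log (allometric) regression fitted to
callows only.  For every specimen the losses of the two most distal
teeth are

    dT_i = predicted pristine length - observed length,

and the wear index is their weighted average

    W = (dT2 + alpha * dT1) / 2,

where ``alpha`` is the ratio between the average length losses,
``mean(dT2) / mean(dT1)``, computed over foragers (callows contribute
only measurement noise to both means).  W has dimension length; the
relative index ``W* = W / predicted pristine T2`` expresses the same
loss as a fraction of the pristine second tooth.

Tables are pandas DataFrames with columns ``specimen_id,
body_mass_mg, group, blade_um, T1_um, T2_um`` (lengths in um, mass in
mg, group in {"callow", "forager"}).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ToothBaselineFit",
    "PristineBaseline",
    "fit_pristine_baseline",
    "compute_wear",
    "WearForceFit",
    "wear_force_regression",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ToothBaselineFit:
    """Log10-log10 OLS of one tooth length against body mass."""

    intercept: float  # log10(um) at 1 mg
    slope: float      # allometric exponent
    resid_sd: float
    ci_slope: tuple[float, float]
    n: int

    def predict(self, body_mass_mg: np.ndarray | float) -> np.ndarray | float:
        return 10.0 ** (self.intercept + self.slope * np.log10(body_mass_mg))


@dataclass(frozen=True)
class PristineBaseline:
    """Per-tooth pristine-length baselines, fitted on callows only."""

    T1: ToothBaselineFit
    T2: ToothBaselineFit
    n_dropped: int = 0


def _fit_tooth(mass: np.ndarray, length: np.ndarray) -> ToothBaselineFit:
    X = sm.add_constant(np.log10(mass))
    res = sm.OLS(np.log10(length), X).fit()
    ci = res.conf_int(0.05)
    return ToothBaselineFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        resid_sd=float(np.sqrt(res.scale)),
        ci_slope=(float(ci[1][0]), float(ci[1][1])),
        n=int(res.nobs),
    )


def fit_pristine_baseline(callows: pd.DataFrame) -> PristineBaseline:
    """Fit the pristine tooth-length allometry on a callow table.

    Rows from any other group are rejected outright; specimens with an
    unmeasurable tooth (NaN) or non-positive length are dropped with a
    logged count, mirroring the practical loss of mandibles obstructed
    by the head capsule.
    """
    if (callows["group"] != "callow").any():
        raise ValueError("pristine baseline must be fitted on callows only")
    cols = ["body_mass_mg", "T1_um", "T2_um"]
    usable = callows.dropna(subset=cols)
    usable = usable[(usable[cols] > 0).all(axis=1)]
    n_dropped = len(callows) - len(usable)
    if n_dropped:
        logger.info("dropped %d callow(s) with unmeasurable teeth", n_dropped)
    if len(usable) < 3:
        raise ValueError(f"need at least 3 usable callows, got {len(usable)}")
    mass = usable["body_mass_mg"].to_numpy()
    return PristineBaseline(
        T1=_fit_tooth(mass, usable["T1_um"].to_numpy()),
        T2=_fit_tooth(mass, usable["T2_um"].to_numpy()),
        n_dropped=n_dropped,
    )


def compute_wear(
    specimens: pd.DataFrame,
    baseline: PristineBaseline,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Add dT1, dT2, W and W* columns to a specimen table.

    ``dT_i = pristine - observed`` so wear is positive.  If ``alpha``
    is not supplied it is estimated as ``mean(dT2)/mean(dT1)`` over the
    forager rows; with no foragers, or an average first-tooth loss of
    zero, the weighting is undefined and an explicit ``alpha`` is
    required.
    """
    out = specimens.copy()
    mass = out["body_mass_mg"].to_numpy()
    out["T1_pristine_um"] = baseline.T1.predict(mass)
    out["T2_pristine_um"] = baseline.T2.predict(mass)
    out["dT1_um"] = out["T1_pristine_um"] - out["T1_um"]
    out["dT2_um"] = out["T2_pristine_um"] - out["T2_um"]
    if alpha is None:
        foragers = out[out["group"] == "forager"]
        if foragers.empty:
            raise ValueError("no foragers to estimate alpha from; supply alpha")
        mean_dT1 = foragers["dT1_um"].mean()
        if not np.isfinite(mean_dT1) or abs(mean_dT1) < 1e-12:
            raise ValueError("average first-tooth loss is zero; alpha undefined")
        alpha = float(foragers["dT2_um"].mean() / mean_dT1)
    out["alpha"] = alpha
    out["W_um"] = (out["dT2_um"] + alpha * out["dT1_um"]) / 2.0
    out["W_star"] = out["W_um"] / out["T2_pristine_um"]
    return out


@dataclass(frozen=True)
class WearForceFit:
    """OLS of cutting force (mN) on absolute wear (um), untransformed."""

    slope: float  # mN per um
    intercept: float
    ci_slope: tuple[float, float]
    r_squared: float
    p_value: float
    n: int


def wear_force_regression(W_um: np.ndarray, F_c_mN: np.ndarray) -> WearForceFit:
    """Regress total cutting force on the absolute wear index.

    Performed on untransformed data (the wear index can be negative for
    noisy callow measurements, ruling out a log transform).
    """
    W = np.asarray(W_um, dtype=float)
    F = np.asarray(F_c_mN, dtype=float)
    if W.shape != F.shape or W.ndim != 1:
        raise ValueError("W and F must be matching 1-d arrays")
    if W.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(W) == 0:
        raise ValueError("wear index is constant; slope undefined")
    X = sm.add_constant(W)
    res = sm.OLS(F, X).fit()
    ci = res.conf_int(0.05)
    return WearForceFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        ci_slope=(float(ci[1][0]), float(ci[1][1])),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        n=int(res.nobs),
    )
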