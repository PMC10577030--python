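"""From raw sensor traces to calibrated cutting, spacing and fracture forces.

The measurement chain mirrors a bending-beam cutting-force rig read by
a displacement sensor:

1. *Calibration* — known weights are suspended from the beam and a
   polynomial force-to-reading model is fitted; the degree (1-3) is
   chosen by AIC.  Beam deflection is linear in force only for small
   loads, so a quadratic is typically selected.
2. *Drift correction* — the sensor output drifts slowly (~0.01 mN/s);
   a line through the unloaded baselines at the start and end of the
   recording is subtracted.
3. *Extraction* — the cut pass shows a loading ramp, a force peak at
   cut initiation, and an approximately constant steady-state phase.
   The total cutting force F_c is the calibrated force averaged over a
   fixed motor-travel window (default 2 mm) after the force settles;
   the spacing force F_s is the second pass averaged over the identical
   motor positions; the fracture force is F_f = F_c - F_s.

Forces are held in newtons internally; millinewtons appear only at I/O.
Motor positions are carried in mm, matching the trace files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ForceTrace",
    "CalibrationModel",
    "ValidityFlags",
    "CutMeasurement",
    "fit_calibration",
    "apply_calibration",
    "correct_drift",
    "extract_forces",
    "correct_lamina_thickness",
    "check_validity",
]

#: Upper end of the sensor calibration range (N); forces above it are
#: outside the fitted model and flagged invalid.
CALIBRATION_MAX_N = 0.245


@dataclass(frozen=True)
class ForceTrace:
    """One sensor recording of a cut or spacing pass.

    ``raw_reading`` is in sensor units; ``force`` (N) is filled in by
    :func:`apply_calibration` and corrected by :func:`correct_drift`.
    """

    time: np.ndarray
    raw_reading: np.ndarray
    motor_pos_mm: np.ndarray
    pass_label: str = "cut"
    force: np.ndarray | None = None
    drift_rate: float | None = None  # N/s, recorded by correct_drift

    def __post_init__(self) -> None:
        for name in ("time", "raw_reading", "motor_pos_mm"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.time.shape == self.raw_reading.shape == self.motor_pos_mm.shape):
            raise ValueError("time, raw_reading and motor_pos_mm must share a shape")
        if self.time.size < 2:
            raise ValueError("trace needs at least two samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.force is not None:
            object.__setattr__(self, "force", np.asarray(self.force, dtype=float))

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass(frozen=True)
class CalibrationModel:
    """Polynomial force -> reading calibration with AIC degree selection.

    ``coefficients`` are those of the selected polynomial in ascending
    order (numpy ``Polynomial`` convention).  The inverse map is
    evaluated on a dense monotone grid spanning slightly beyond the fit
    range so that retraction (small negative forces) stays invertible.
    """

    coefficients: np.ndarray
    degree: int
    fit_range: tuple[float, float]
    aic_by_degree: dict[int, float]
    coefficients_by_degree: dict[int, np.ndarray]
    monotone: bool = True
    _grid_force: np.ndarray = field(repr=False, default=None)
    _grid_reading: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        lo, hi = self.fit_range
        span = hi - lo
        grid_f = np.linspace(lo - 0.3 * span, hi + 0.1 * span, 8192)
        grid_r = np.polynomial.polynomial.polyval(grid_f, self.coefficients)
        if np.any(np.diff(grid_r) <= 0):
            # keep the monotone segment around the fit range
            warnings.warn("calibration polynomial is not monotone over the "
                          "extended inversion grid", stacklevel=2)
            d = np.diff(grid_r) > 0
            start = np.argmax(d)
            stop = start + np.argmin(d[start:]) if not d[start:].all() else grid_f.size - 1
            grid_f, grid_r = grid_f[start:stop + 1], grid_r[start:stop + 1]
        object.__setattr__(self, "_grid_force", grid_f)
        object.__setattr__(self, "_grid_reading", grid_r)

    def force_to_reading(self, force: np.ndarray | float) -> np.ndarray | float:
        return np.polynomial.polynomial.polyval(np.asarray(force, dtype=float),
                                                self.coefficients)

    def reading_to_force(self, reading: np.ndarray | float) -> np.ndarray:
        return np.interp(np.asarray(reading, dtype=float),
                         self._grid_reading, self._grid_force)

    def in_range(self, force: float) -> bool:
        lo, hi = self.fit_range
        return bool(lo <= force <= hi)


def _aic_gaussian(rss: float, n: int, k_params: int, floor: float) -> float:
    """AIC under a Gaussian likelihood with plugged-in variance.

    ``k_params`` counts the polynomial coefficients plus the variance.
    The residual sum of squares is floored at numerical precision so
    that exact fits of different degrees tie and are resolved by the
    lower-degree tie-break instead of by rounding noise.
    """
    rss = max(rss, floor)
    return n * np.log(rss / n) + 2 * k_params


def fit_calibration(
    forces: np.ndarray,
    readings: np.ndarray,
    degrees: tuple[int, ...] = (1, 2, 3),
) -> CalibrationModel:
    """Fit polynomial calibrations and select the degree by AIC.

    Requires at least ``degree + 2`` points for every requested degree
    (one more than the parameter count, so a residual variance exists).
    Ties in AIC are broken toward the lower degree.  A non-monotone
    reading-vs-force relation raises a warning and clears the
    ``monotone`` flag.
    """
    forces = np.asarray(forces, dtype=float)
    readings = np.asarray(readings, dtype=float)
    if forces.shape != readings.shape or forces.ndim != 1:
        raise ValueError("forces and readings must be matching 1-d arrays")
    if np.any(forces <= 0):
        raise ValueError("calibration forces must be positive")
    degrees = tuple(sorted(set(int(d) for d in degrees)))
    if not degrees:
        raise ValueError("no degrees requested")
    n = forces.size
    for d in degrees:
        if n < d + 2:
            raise ValueError(f"degree {d} needs at least {d + 2} calibration "
                             f"points, got {n}")
    order = np.argsort(forces)
    monotone = bool(np.all(np.diff(readings[order]) > 0))
    if not monotone:
        warnings.warn("sensor reading is not monotone in force", stacklevel=2)

    aic: dict[int, float] = {}
    coeffs: dict[int, np.ndarray] = {}
    rss_floor = n * (1e-10 * max(float(np.abs(readings).max()), 1e-30)) ** 2
    for d in degrees:
        c = np.polynomial.polynomial.polyfit(forces, readings, d)
        resid = readings - np.polynomial.polynomial.polyval(forces, c)
        aic[d] = _aic_gaussian(float(resid @ resid), n, d + 2, rss_floor)
        coeffs[d] = c
    best = degrees[0]
    for d in degrees[1:]:
        if aic[d] < aic[best]:
            best = d
    return CalibrationModel(
        coefficients=coeffs[best],
        degree=best,
        fit_range=(float(forces.min()), float(forces.max())),
        aic_by_degree=aic,
        coefficients_by_degree=coeffs,
        monotone=monotone,
    )


def apply_calibration(trace: ForceTrace, calib: CalibrationModel) -> ForceTrace:
    """Convert the raw reading channel to force (N)."""
    return replace(trace, force=calib.reading_to_force(trace.raw_reading))


def correct_drift(
    trace: ForceTrace,
    baseline_windows: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> ForceTrace:
    """Subtract the line through two unloaded baseline means.

    ``baseline_windows`` are (start, end) times in seconds of two
    unloaded phases, by default the first and last 1.5 s of the
    recording.  The recovered drift rate (N/s) is stored on the
    returned trace.
    """
    if trace.force is None:
        raise ValueError("trace must be calibrated before drift correction")
    t = trace.time
    if baseline_windows is None:
        baseline_windows = ((t[0], t[0] + 1.5), (t[-1] - 1.5, t[-1]))
    (a0, a1), (b0, b1) = baseline_windows
    if not (a0 < a1 and b0 < b1):
        raise ValueError("baseline windows must have positive length")
    if a1 > b0:
        raise ValueError("baseline windows must not overlap and must be ordered")
    m1 = (t >= a0) & (t <= a1)
    m2 = (t >= b0) & (t <= b1)
    if not (m1.any() and m2.any()):
        raise ValueError("baseline windows contain no samples")
    c1, c2 = t[m1].mean(), t[m2].mean()
    y1, y2 = trace.force[m1].mean(), trace.force[m2].mean()
    rate = (y2 - y1) / (c2 - c1)
    corrected = trace.force - (y1 + rate * (t - c1))
    return replace(trace, force=corrected, drift_rate=float(rate))


@dataclass(frozen=True)
class ValidityFlags:
    """Pass/fail flags mirroring the experimental validity criteria.

    The first, second, fourth and fifth criteria (head-capsule contact,
    mandible slipping out of the cut, epoxy-fixation failure, specimen
    slipping from the holder) are observational and supplied by the
    experimenter; the steady-state-length and calibration-range checks
    are computed from the trace.
    """

    no_head_contact: bool = True
    no_slip_out: bool = True
    steady_state_long_enough: bool = True
    no_fixation_failure: bool = True
    no_holder_slip: bool = True
    in_calibration_range: bool = True

    @property
    def all_pass(self) -> bool:
        return all((self.no_head_contact, self.no_slip_out,
                    self.steady_state_long_enough, self.no_fixation_failure,
                    self.no_holder_slip, self.in_calibration_range))


@dataclass(frozen=True)
class CutMeasurement:
    """Extracted forces for one cut/spacing trace pair (N, window in mm)."""

    F_c: float
    F_s: float
    F_f: float
    window: tuple[float, float]
    drift_rate: float | None
    flags: ValidityFlags
    specimen_id: str | None = None

    @property
    def valid(self) -> bool:
        return self.flags.all_pass


def check_validity(
    F_c: float,
    steady_len_mm: float,
    window_mm: float,
    calibration_max_N: float = CALIBRATION_MAX_N,
    *,
    no_head_contact: bool = True,
    no_slip_out: bool = True,
    no_fixation_failure: bool = True,
    no_holder_slip: bool = True,
) -> ValidityFlags:
    """Assemble validity flags for an extracted measurement."""
    return ValidityFlags(
        no_head_contact=no_head_contact,
        no_slip_out=no_slip_out,
        steady_state_long_enough=bool(steady_len_mm >= window_mm),
        no_fixation_failure=no_fixation_failure,
        no_holder_slip=no_holder_slip,
        in_calibration_range=bool(np.isfinite(F_c) and F_c <= calibration_max_N),
    )


def _advance_segment(trace: ForceTrace) -> np.ndarray:
    """Indices of the forward-moving (advance) phase of the motor."""
    pos = trace.motor_pos_mm
    stop = int(np.argmax(pos))
    moving = np.flatnonzero(np.diff(pos[: stop + 1]) > 0)
    if moving.size == 0:
        raise ValueError("trace has no advancing motor phase")
    return np.arange(moving[0] + 1, stop + 1)


def _plateau_start(pos: np.ndarray, force: np.ndarray, peak_idx: int,
                   band: float, band_mm: float) -> int | None:
    """First index after the peak where the force stays within ``band``
    of its forward running median over ``band_mm`` of travel."""
    if peak_idx >= pos.size - 2:
        return None
    dx = np.median(np.diff(pos))
    w = max(int(round(band_mm / dx)), 2)
    f = force[peak_idx:]
    if f.size < w:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(f, w)
    med = np.median(windows, axis=1)
    ok = np.all(np.abs(windows - med[:, None]) <= band * np.abs(med[:, None]), axis=1)
    hits = np.flatnonzero(ok)
    if hits.size == 0:
        return None
    return peak_idx + int(hits[0])


def extract_forces(
    cut: ForceTrace,
    spacing: ForceTrace,
    window_mm: float = 2.0,
    settle_mm: float = 0.1,
    band: float = 0.15,
    band_mm: float = 0.2,
    specimen_id: str | None = None,
    calibration_max_N: float = CALIBRATION_MAX_N,
    compliance_mm_per_N: float = 0.0,
    observational_flags: dict[str, bool] | None = None,
) -> CutMeasurement:
    """Extract F_c, F_s and F_f = F_c - F_s from a calibrated pair.

    The initiation peak is the global force maximum of the advance
    phase.  The steady state starts at the first position after the
    peak where the force stays within ``band`` (default +/-15 %) of its
    forward running median for ``band_mm`` of travel, plus a settling
    distance ``settle_mm``.  Both forces are averaged over the same
    ``window_mm`` of motor positions.  ``compliance_mm_per_N``
    optionally converts motor travel to sheet displacement by removing
    beam deflection (off by default; a ~2 % effect).

    A too-short steady state or an undetectable peak yields a
    measurement flagged invalid rather than an exception.
    """
    if cut.force is None or spacing.force is None:
        raise ValueError("both passes must be calibrated (and drift-corrected) first")
    obs = observational_flags or {}

    adv_c = _advance_segment(cut)
    adv_s = _advance_segment(spacing)
    pos_c = cut.motor_pos_mm[adv_c]
    f_c = cut.force[adv_c]
    pos_s = spacing.motor_pos_mm[adv_s]
    f_s = spacing.force[adv_s]
    if compliance_mm_per_N != 0.0:
        pos_c = pos_c - compliance_mm_per_N * f_c
        pos_s = pos_s - compliance_mm_per_N * f_s

    def invalid(window: tuple[float, float]) -> CutMeasurement:
        flags = check_validity(np.nan, 0.0, window_mm, calibration_max_N, **obs)
        return CutMeasurement(F_c=np.nan, F_s=np.nan, F_f=np.nan, window=window,
                              drift_rate=cut.drift_rate, flags=flags,
                              specimen_id=specimen_id)

    peak_idx = int(np.argmax(f_c))
    if f_c[peak_idx] <= 0:
        return invalid((np.nan, np.nan))
    start_idx = _plateau_start(pos_c, f_c, peak_idx, band, band_mm)
    if start_idx is None:
        return invalid((np.nan, np.nan))

    x0 = pos_c[start_idx] + settle_mm
    x1 = x0 + window_mm
    steady_len = pos_c[-1] - pos_c[start_idx]

    mask_c = (pos_c >= x0) & (pos_c <= x1)
    mask_s = (pos_s >= x0) & (pos_s <= x1)
    if not (mask_c.any() and mask_s.any()):
        return invalid((x0, x1))
    F_c = float(f_c[mask_c].mean())
    F_s = float(f_s[mask_s].mean())
    flags = check_validity(F_c, float(steady_len), window_mm, calibration_max_N, **obs)
    return CutMeasurement(F_c=F_c, F_s=F_s, F_f=F_c - F_s, window=(float(x0), float(x1)),
                          drift_rate=cut.drift_rate, flags=flags,
                          specimen_id=specimen_id)


def correct_lamina_thickness(F_measured: float, t_l: float, t_mean: float) -> float:
    """Rescale a force measured on lamina of thickness ``t_l`` to the
    mean thickness ``t_mean``: ``F * t_mean / t_l`` (units cancel)."""
    if t_l <= 0 or t_mean <= 0:
        raise ValueError("thicknesses must be positive")
    return F_measured * t_mean / t_l
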