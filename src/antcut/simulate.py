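"""Synthetic data generators for every input of the cutting pipeline.

The generators emulate, with known ground truth, the five kinds of raw
data the analysis consumes:

* two-pass cut/spacing force traces (loading ramp, initiation peak,
  steady-state plateau, retraction, sensor drift and noise) recorded by
  a displacement sensor with a quadratic force-to-reading response;
* sensor calibration tables (suspended weights vs sensor reading);
* worker populations (callows with pristine mandibles, foragers with
  additive tooth wear) whose tooth lengths follow a mass allometry;
* material-test curves (paired pure-shear tearing and uniaxial
  tension) constructed to return prescribed G_c and E;
* leaf-property tables with lognormal (G_c, t, sigma_c) marginals.

Every generator draws from one ``numpy.random.Generator`` seeded per
call; identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .materials import TearingPair
from .traces import ForceTrace

__all__ = [
    "QuadraticSensor",
    "DEFAULT_SENSOR",
    "TraceGenParams",
    "PopulationGenParams",
    "LeafGenParams",
    "gen_trace_pair",
    "gen_calibration_table",
    "gen_population",
    "gen_leaf_table",
    "gen_material_curves",
    "ground_truth",
]

#: Recording rate of the fibre-optic displacement sensor (Hz).
SENSOR_RATE_HZ = 81.4


@dataclass(frozen=True)
class QuadraticSensor:
    """Force (N) -> raw reading map used to synthesise sensor output.

    The bending-beam sensor reads a distance that is linear in force for
    small deflections and sub-linear at higher loads, hence a quadratic
    response ``reading = c0 + c1*F + c2*F**2`` with ``c2 < 0``.  The
    default is monotone well beyond the calibration range.
    """

    c0: float = 0.0
    c1: float = 1.5
    c2: float = -0.9

    def reading(self, force: np.ndarray | float) -> np.ndarray | float:
        return self.c0 + self.c1 * force + self.c2 * force**2


DEFAULT_SENSOR = QuadraticSensor()


@dataclass(frozen=True)
class TraceGenParams:
    """Ground truth for one cut/spacing trace pair.

    Forces in N, lengths in m, speeds in m/s.  Defaults emulate the
    study conditions: a medium 65 mN total cutting force with a 5 mN
    spacing force, 0.3 mm/s motor speed over 5 mm travel, ~0.01 mN/s
    sensor drift, recording at 81.4 Hz.  ``noise_sd`` is additive
    Gaussian sensor noise expressed in force units.
    """

    true_cut_force: float = 0.065
    true_spacing_force: float = 0.005
    peak_overshoot_factor: float = 1.5
    motor_speed: float = 0.3e-3
    total_travel: float = 5e-3
    drift_rate: float = 1e-5
    noise_sd: float = 0.5e-3
    sample_rate: float = SENSOR_RATE_HZ
    seed: int = 0
    # unloaded dwell before the motor engages / after it returns, used
    # for drift baselines
    lead_in_s: float = 2.0
    tail_s: float = 2.0
    # travel over which the force ramps to the initiation peak, and
    # width of the triangular overshoot back down to the plateau
    ramp_travel: float = 0.3e-3
    peak_width: float = 0.2e-3
    sensor: QuadraticSensor = DEFAULT_SENSOR

    def __post_init__(self) -> None:
        if not self.true_cut_force >= self.true_spacing_force >= 0:
            raise ValueError("need true_cut_force >= true_spacing_force >= 0")
        if not self.total_travel > 0:
            raise ValueError("total_travel must be positive")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if not self.motor_speed > 0:
            raise ValueError("motor_speed must be positive")
        if self.peak_overshoot_factor < 1:
            raise ValueError("peak_overshoot_factor must be >= 1")
        if self.ramp_travel + self.peak_width >= self.total_travel:
            raise ValueError("ramp and peak must fit within the total travel")


def _advance_force(x: np.ndarray, plateau: float, peak: float | None,
                   ramp: float, width: float) -> np.ndarray:
    """True force along the advance, as a function of motor position (m)."""
    f = np.full_like(x, plateau)
    if peak is None:  # spacing pass: ramp straight to the plateau
        m = x < ramp
        f[m] = plateau * x[m] / ramp
        return f
    m = x < ramp
    f[m] = peak * x[m] / ramp
    m = (x >= ramp) & (x < ramp + width)
    f[m] = peak + (plateau - peak) * (x[m] - ramp) / width
    return f


def _retract_force(s: np.ndarray, plateau: float, delta: float = 0.3e-3) -> np.ndarray:
    """Negative excursion while the tool is withdrawn through the cut."""
    return -0.15 * plateau * (s / delta) * np.exp(1.0 - s / delta)


def _make_pass(params: TraceGenParams, plateau: float, peak: float | None,
               rng: np.random.Generator, label: str) -> ForceTrace:
    dt = 1.0 / params.sample_rate
    advance_T = params.total_travel / params.motor_speed
    n_lead = int(round(params.lead_in_s / dt))
    n_adv = int(round(advance_T / dt))
    n_tail = int(round(params.tail_s / dt))
    n = n_lead + 2 * n_adv + n_tail
    t = np.arange(n) * dt

    pos = np.zeros(n)
    force = np.zeros(n)

    i0, i1 = n_lead, n_lead + n_adv
    x_adv = (t[i0:i1] - t[i0]) * params.motor_speed
    pos[i0:i1] = x_adv
    force[i0:i1] = _advance_force(x_adv, plateau, peak,
                                  params.ramp_travel, params.peak_width)

    i2 = i1 + n_adv
    dt_travel = dt * params.motor_speed
    s_back = (t[i1:i2] - t[i1]) * params.motor_speed + dt_travel
    pos[i1:i2] = np.maximum(x_adv[-1] - s_back, 0.0)
    force[i1:i2] = _retract_force(s_back, plateau)
    pos[i2:] = 0.0

    raw_force = force + params.drift_rate * t
    if params.noise_sd > 0:
        raw_force = raw_force + rng.normal(0.0, params.noise_sd, size=n)
    raw = params.sensor.reading(raw_force)
    return ForceTrace(time=t, raw_reading=np.asarray(raw),
                      motor_pos_mm=pos * 1e3, pass_label=label)


def gen_trace_pair(params: TraceGenParams) -> tuple[ForceTrace, ForceTrace]:
    """Generate a cut pass and its matching spacing pass.

    The cut pass ramps to an initiation peak
    (``true_cut_force * peak_overshoot_factor``), drops to a plateau at
    ``true_cut_force``, and goes negative on retraction; the spacing
    pass plateaus at ``true_spacing_force`` over the same motor
    positions.  Drift and noise are added in force units, then mapped
    through the sensor response to give the raw reading channel.
    """
    rng = np.random.default_rng(params.seed)
    cut = _make_pass(params, params.true_cut_force,
                     params.true_cut_force * params.peak_overshoot_factor,
                     rng, "cut")
    spacing = _make_pass(params, params.true_spacing_force, None, rng, "spacing")
    return cut, spacing


def gen_calibration_table(
    sensor: QuadraticSensor = DEFAULT_SENSOR,
    forces_N: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Calibration table: suspended-weight force vs averaged reading.

    Defaults to ten weights spanning 10-245 mN, the range used to
    calibrate the bending-beam sensor.
    """
    if forces_N is None:
        forces_N = np.linspace(0.010, 0.245, 10)
    forces_N = np.asarray(forces_N, dtype=float)
    readings = np.asarray(sensor.reading(forces_N), dtype=float)
    if noise_sd > 0:
        readings = readings + np.random.default_rng(seed).normal(0, noise_sd, forces_N.size)
    return pd.DataFrame({"force_N": forces_N, "reading": readings})


@dataclass(frozen=True)
class PopulationGenParams:
    """Ground truth for a synthetic worker population.

    Body masses are log-uniform over ``mass_range`` (mg, spanning the
    sampled worker size range 1.8-46.4 mg).  Pristine tooth and blade
    lengths follow ``L = A * m**b`` (um, mass in mg) with isometric
    exponents by default.  Foragers receive additive wear drawn from a
    normal distribution truncated at zero (mean 8 um, sd 10 um);
    callows get wear exactly zero.  Wear is split between the two
    distal teeth such that dT2/dT1 = ``wear_ratio`` (1 = equal loss).
    Measurement noise is added last to all observed lengths.
    """

    n_workers: int = 85
    mass_range: tuple[float, float] = (1.8, 46.4)
    group_mix: float = 0.46  # fraction of foragers
    wear_mean: float = 8.0
    wear_sd: float = 10.0
    tooth_allometry: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "T1": (40.0, 1.0 / 3.0),
            "T2": (30.0, 1.0 / 3.0),
            "blade": (250.0, 1.0 / 3.0),
        }
    )
    wear_ratio: float = 1.0
    morphometric_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_workers < 0:
            raise ValueError("n_workers must be non-negative")
        if not 0 <= self.group_mix <= 1:
            raise ValueError("group_mix must lie in [0, 1]")
        lo, hi = self.mass_range
        if not 0 < lo <= hi:
            raise ValueError("mass_range must be positive and ordered")
        if self.wear_ratio <= 0:
            raise ValueError("wear_ratio must be positive")


def _truncated_wear(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    if n == 0:
        return np.zeros(0)
    if sd == 0:
        return np.full(n, max(mean, 0.0))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def gen_population(params: PopulationGenParams) -> pd.DataFrame:
    """Generate a specimen table with known true wear.

    Columns: ``specimen_id, body_mass_mg, group, blade_um, T1_um,
    T2_um, true_wear_um`` (the last is the injected ground truth, not
    available to the analysis in real data).
    """
    n = params.n_workers
    cols = ["specimen_id", "body_mass_mg", "group", "blade_um", "T1_um", "T2_um",
            "true_wear_um"]
    if n == 0:
        return pd.DataFrame(columns=cols)
    rng = np.random.default_rng(params.seed)
    lo, hi = params.mass_range
    mass = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    is_forager = rng.random(n) < params.group_mix
    wear = np.zeros(n)
    wear[is_forager] = _truncated_wear(rng, params.wear_mean, params.wear_sd,
                                       int(is_forager.sum()))

    def pristine(key: str) -> np.ndarray:
        A, b = params.tooth_allometry[key]
        return A * mass**b

    r = params.wear_ratio
    dT2 = wear                   # weighted index recovers W = injected wear
    dT1 = wear / r
    T1 = pristine("T1") - dT1
    T2 = pristine("T2") - dT2
    blade = pristine("blade")
    if params.morphometric_noise_sd > 0:
        sd = params.morphometric_noise_sd
        T1 = T1 + rng.normal(0, sd, n)
        T2 = T2 + rng.normal(0, sd, n)
        blade = blade + rng.normal(0, sd, n)
    return pd.DataFrame({
        "specimen_id": [f"w{i:03d}" for i in range(n)],
        "body_mass_mg": mass,
        "group": np.where(is_forager, "forager", "callow"),
        "blade_um": blade,
        "T1_um": T1,
        "T2_um": T2,
        "true_wear_um": wear,
    })


@dataclass(frozen=True)
class LeafGenParams:
    """Lognormal leaf-trait marginals.

    ``*_log_params`` are (log-median, log-sd) of natural-log normal
    distributions, so the sample medians converge to
    ``exp(log-median)``.  Defaults target the median tropical leaf:
    G_c = 400 N/m, t = 200 um, sigma_c = 3 MPa, with spreads typical of
    broad leaf-trait surveys.
    """

    n_species: int = 1000
    gc_log_params: tuple[float, float] = (float(np.log(400.0)), 0.6)
    t_log_params: tuple[float, float] = (float(np.log(200e-6)), 0.3)
    sigma_log_params: tuple[float, float] = (float(np.log(3e6)), 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 0:
            raise ValueError("n_species must be non-negative")
        for name in ("gc_log_params", "t_log_params", "sigma_log_params"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} log-sd must be non-negative")


def gen_leaf_table(params: LeafGenParams) -> pd.DataFrame:
    """Table of per-species leaf properties (G_c in N/m, t in m, sigma_c in Pa)."""
    rng = np.random.default_rng(params.seed)

    def draw(log_params: tuple[float, float]) -> np.ndarray:
        mu, sd = log_params
        if sd == 0:
            return np.full(params.n_species, np.exp(mu))
        return rng.lognormal(mu, sd, params.n_species)

    return pd.DataFrame({
        "species_id": [f"sp{i:04d}" for i in range(params.n_species)],
        "G_c": draw(params.gc_log_params),
        "t": draw(params.t_log_params),
        "sigma_c": draw(params.sigma_log_params),
    })


def gen_material_curves(
    G_c: float = 98.0,
    E: float = 4.1e6,
    width: float = 20e-3,
    thickness: float = 200e-6,
    d_crit: float = 2e-3,
    n_points: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[TearingPair, pd.DataFrame]:
    """Construct test curves that return prescribed G_c and E.

    The unnotched tearing curve is linear, ``F = k x`` with
    ``k = 2 G_c w t / d_crit**2`` so that the work to the critical
    displacement equals ``G_c * w * t`` exactly.  The tension curve has
    slope E over 0-10 % strain.  ``noise_sd`` adds relative Gaussian
    noise to both force and stress channels.
    """
    if min(G_c, E, width, thickness, n_points) <= 0 or d_crit < 0:
        raise ValueError("material-curve parameters must be positive")
    rng = np.random.default_rng(seed)
    d_max = 1.5 * d_crit if d_crit > 0 else 3e-3
    x = np.linspace(0.0, d_max, n_points)
    if d_crit > 0:
        k = 2.0 * G_c * width * thickness / d_crit**2
    else:
        k = 1.0
    f = k * x
    if noise_sd > 0:
        f = f + rng.normal(0, noise_sd * max(f.max(), 1e-12), n_points)
        f[0] = 0.0
    pair = TearingPair(displacement=x, force=f,
                       notched_critical_displacement=d_crit,
                       width=width, thickness=thickness)
    strain = np.linspace(0.0, 0.2, n_points)
    stress = E * strain
    if noise_sd > 0:
        stress = stress + rng.normal(0, noise_sd * stress.max(), n_points)
    tension = pd.DataFrame({"strain": strain, "stress_Pa": stress})
    return pair, tension


def ground_truth(params: Any) -> dict:
    """JSON-serialisable sidecar of a generator's ground-truth parameters."""
    d = asdict(params)
    out = {}
    for k, v in d.items():
        if isinstance(v, dict) and k == "sensor":
            out[k] = v
        elif isinstance(v, tuple):
            out[k] = list(v)
        elif isinstance(v, dict):
            out[k] = {kk: list(vv) if isinstance(vv, tuple) else vv for kk, vv in v.items()}
        else:
            out[k] = v
    return out
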