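"""From forces to foraging capability.

Bite force in leaf-cutter ants rises with strong positive allometry,
F_b = F_ref * (m/m_ref)^0.90 (about 800 mN for a 40 mg forager).  The
force *required* to cut a leaf of toughness G_c and thickness t with a
pristine mandible is approximately G_c * t, and mandibular wear W
shifts it up linearly at the empirically determined rate of
~2.09 mN/um.  Comparing the two over a table of leaf species gives the
fraction of leaves a worker of a given size and wear state can cut,
and how that fraction collapses for small, worn workers.

Also here: the excess-force ratio F_b/F_c and its scaling across the
size range, and the back-of-envelope lifetime cutting length of a
forager.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sharpness import CuttingToolSpec

__all__ = [
    "BiteForceModel",
    "bite_force",
    "required_force",
    "CapacityResult",
    "cuttable_fraction",
    "excess_force_ratio",
    "excess_scaling_factor",
    "lifetime_cut_length",
]

#: Wear sensitivity of the total cutting force (mN per um of wear
#: index), the regression slope measured on PDMS.
DEFAULT_WEAR_SLOPE_MN_PER_UM = 2.09


@dataclass(frozen=True)
class BiteForceModel:
    """Peak bite force allometry F_b(m) = F_ref * (m/m_ref)^exponent.

    Defaults: 800 mN at 40 mg with exponent 0.90.
    """

    F_ref_mN: float = 800.0
    m_ref_mg: float = 40.0
    exponent: float = 0.90

    def __post_init__(self) -> None:
        if self.F_ref_mN <= 0 or self.m_ref_mg <= 0:
            raise ValueError("reference force and mass must be positive")


def bite_force(model: BiteForceModel, body_mass_mg: float) -> float:
    """Peak bite force (mN) of a worker of the given body mass (mg)."""
    if body_mass_mg <= 0:
        raise ValueError("body mass must be positive")
    return model.F_ref_mN * (body_mass_mg / model.m_ref_mg) ** model.exponent


def required_force(
    G_c: float,
    t: float,
    W_um: float = 0.0,
    wear_slope_mN_per_um: float = DEFAULT_WEAR_SLOPE_MN_PER_UM,
    tool: CuttingToolSpec | None = None,
    sigma_c: float | None = None,
) -> float:
    """Cutting force (mN) required for one leaf at a given wear state.

    The pristine requirement is the minimum-force bound ``G_c * t``
    (SI inputs, returned in mN); wear shifts it up by
    ``wear_slope * W``, assumed material-independent.  Supplying a
    ``tool`` and ``sigma_c`` adds the geometry term
    ``C sigma_c R t`` of the fracture-force model — a sensitivity
    refinement, off by default.
    """
    if G_c <= 0 or t <= 0:
        raise ValueError("G_c and t must be positive")
    if W_um < 0:
        raise ValueError("wear index must be non-negative here")
    F = G_c * t * 1e3
    if tool is not None:
        if sigma_c is None:
            raise ValueError("sigma_c is required when a tool is supplied")
        F += tool.C * sigma_c * tool.R * t * 1e3
    return F + wear_slope_mN_per_um * W_um


@dataclass(frozen=True)
class CapacityResult:
    """Cuttable-leaf fraction for one (mass, wear) state."""

    body_mass_mg: float
    W_um: float
    fraction_cuttable: float
    n_species: int
    bite_force_mN: float


def cuttable_fraction(
    leaves: pd.DataFrame,
    model: BiteForceModel,
    body_mass_mg: float,
    W_um: float = 0.0,
    wear_slope_mN_per_um: float = DEFAULT_WEAR_SLOPE_MN_PER_UM,
    tool: CuttingToolSpec | None = None,
) -> CapacityResult:
    """Fraction of leaf species a worker can cut.

    ``leaves`` must have columns ``G_c`` (N/m), ``t`` (m) and, if a
    tool is supplied, ``sigma_c`` (Pa).  A species is cuttable when its
    required force does not exceed the worker's peak bite force (ties
    count as cuttable).
    """
    if leaves.empty:
        raise ValueError("leaf table is empty")
    F_b = bite_force(model, body_mass_mg)
    G_c = leaves["G_c"].to_numpy(dtype=float)
    t = leaves["t"].to_numpy(dtype=float)
    F_req = G_c * t * 1e3 + wear_slope_mN_per_um * W_um
    if tool is not None:
        sigma_c = leaves["sigma_c"].to_numpy(dtype=float)
        F_req = F_req + tool.C * sigma_c * tool.R * t * 1e3
    frac = float(np.mean(F_req <= F_b))
    return CapacityResult(body_mass_mg=body_mass_mg, W_um=W_um,
                          fraction_cuttable=frac, n_species=len(leaves),
                          bite_force_mN=F_b)


def excess_force_ratio(model: BiteForceModel, body_mass_mg: float, F_c_mN: float) -> float:
    """Excess-force ratio F_b(m) / F_c: how many times over the
    required cutting force a worker can bite."""
    if F_c_mN <= 0:
        raise ValueError("cutting force must be positive")
    return bite_force(model, body_mass_mg) / F_c_mN


def excess_scaling_factor(m1_mg: float, m2_mg: float, exponent: float = 0.90) -> float:
    """Factor by which the excess-force ratio changes across a mass span.

    With size-invariant cutting forces, F_c/F_b scales as m^-exponent,
    so the ratio changes by (m2/m1)^exponent — about 30^0.9 ~ 21 across
    a 30-fold size range.
    """
    if m1_mg <= 0 or m2_mg <= 0:
        raise ValueError("masses must be positive")
    return (m2_mg / m1_mg) ** exponent


def lifetime_cut_length(
    colony_foragers: float = 1e6,
    annual_leaf_area_m2: float = 3000.0,
    cut_km_per_m2: float = 3.0,
    active_months: float = 4.0,
    months_per_year: float = 12.0,
) -> float:
    """Leaf tissue cut per forager over its active lifetime (m).

    A colony of ``colony_foragers`` workers cuts
    ``annual_leaf_area_m2`` of leaf area per year; each square metre
    takes ``cut_km_per_m2`` kilometres of cutting; an individual
    forages for ``active_months`` of the year.  The default colony
    (10^6 foragers, 3000 m^2/yr, 3 km/m^2, 4 months) gives 3 m per
    forager — about 500 body lengths.
    """
    if colony_foragers <= 0:
        raise ValueError("colony_foragers must be positive")
    if months_per_year <= 0 or active_months < 0:
        raise ValueError("months must be positive")
    if annual_leaf_area_m2 < 0 or cut_km_per_m2 < 0:
        raise ValueError("area and cut length must be non-negative")
    total_cut_m_per_year = annual_leaf_area_m2 * cut_km_per_m2 * 1e3
    return active_months / months_per_year * total_cut_m_per_year / colony_foragers
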