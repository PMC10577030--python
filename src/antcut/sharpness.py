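"""Minimum cutting force, the fracture-force model and the sharpness index.

Cutting a thin sheet creates new surface, so the cutting force is bound
from below by the energy cost of fracture alone::

    F_min = G_c * t

independent of the tool.  A real tool adds geometry-dependent losses at
the crack tip.  If the tool is characterised by a single length scale R
(typically the cutting-edge radius) and the material by the length
G_c / sigma_c, dimensional analysis gives the fracture force

    F_f = G_c * t + C * sigma_c * R * t,        C = 1 + mu,

where mu is the friction coefficient between tool and substrate (the
exact result C = 1 + mu holds for a cylindrical wire).  The sharpness
index

    S = G_c * t / F_f = 1 / (1 + C * sigma_c * R / G_c)

is dimensionless and lies in (0, 1]; S = 1 means the tool cuts at the
theoretical minimum force and is "ideally sharp".

All quantities are SI (N, m, Pa) internally; millinewtons and
micrometres appear only at the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass

from .materials import MaterialSpec

__all__ = [
    "CuttingToolSpec",
    "SharpnessResult",
    "min_cut_force",
    "fracture_force",
    "sharpness_index",
    "radius_for_sharpness",
    "invert_radius",
    "evaluate",
]


@dataclass(frozen=True)
class CuttingToolSpec:
    """An idealised cutting tool.

    ``R`` is the characteristic length of the cutting edge (m), usually
    the edge radius; ``mu`` the friction coefficient against the
    substrate.  ``C_override`` replaces the wire result ``C = 1 + mu``
    for other tool idealisations.
    """

    R: float
    mu: float = 1.0
    C_override: float | None = None

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ValueError(f"edge radius must be non-negative, got {self.R!r}")
        if self.mu < 0:
            raise ValueError(f"friction coefficient must be non-negative, got {self.mu!r}")
        if self.C_override is not None and self.C_override <= 0:
            raise ValueError("C_override must be positive")

    @property
    def C(self) -> float:
        return 1.0 + self.mu if self.C_override is None else self.C_override


@dataclass(frozen=True)
class SharpnessResult:
    """Forces and sharpness of one tool/material pairing (SI units)."""

    F_min: float
    F_f: float
    S: float
    geometry_term: float  # C * sigma_c * R / G_c, dimensionless


def _C(mu: float, C_override: float | None) -> float:
    return CuttingToolSpec(R=0.0, mu=mu, C_override=C_override).C


def min_cut_force(material: MaterialSpec) -> float:
    """Lower bound on the cutting force, ``G_c * t`` (N)."""
    return material.G_c * material.t


def fracture_force(material: MaterialSpec, tool: CuttingToolSpec) -> float:
    """Fracture force ``G_c t + C sigma_c R t`` (N)."""
    return material.G_c * material.t + tool.C * material.sigma_c * tool.R * material.t


def sharpness_index(material: MaterialSpec, tool: CuttingToolSpec) -> float:
    """Sharpness index ``S = 1 / (1 + C sigma_c R / G_c)`` in (0, 1]."""
    return 1.0 / (1.0 + tool.C * material.sigma_c * tool.R / material.G_c)


def evaluate(material: MaterialSpec, tool: CuttingToolSpec) -> SharpnessResult:
    """Evaluate minimum force, fracture force and sharpness together."""
    geometry = tool.C * material.sigma_c * tool.R / material.G_c
    return SharpnessResult(
        F_min=min_cut_force(material),
        F_f=fracture_force(material, tool),
        S=1.0 / (1.0 + geometry),
        geometry_term=geometry,
    )


def radius_for_sharpness(
    S_target: float,
    material: MaterialSpec,
    mu: float = 1.0,
    C_override: float | None = None,
) -> float:
    """Edge radius (m) at which the sharpness index equals ``S_target``.

    Inverts S = 1/(1 + C sigma_c R / G_c):
    ``R = (1/S - 1) * G_c / (C * sigma_c)``.  S = 0.5 gives the radius
    at which tool geometry accounts for half the cutting force.
    """
    if not 0 < S_target <= 1:
        raise ValueError(f"S_target must lie in (0, 1], got {S_target!r}")
    C = _C(mu, C_override)
    return (1.0 / S_target - 1.0) * material.G_c / (C * material.sigma_c)


def invert_radius(
    F_f: float,
    material: MaterialSpec,
    mu: float = 1.0,
    C_override: float | None = None,
) -> float:
    """Edge radius (m) implied by a measured fracture force.

    ``R = (F_f - G_c t) / (C sigma_c t)``.  Forces below the minimum
    ``G_c t`` are physically impossible under the model and raise.
    """
    F_min = min_cut_force(material)
    if F_f < F_min:
        raise ValueError(
            f"fracture force {F_f:g} N is below the theoretical minimum "
            f"G_c*t = {F_min:g} N; no edge radius can produce it"
        )
    C = _C(mu, C_override)
    return (F_f - F_min) / (C * material.sigma_c * material.t)
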