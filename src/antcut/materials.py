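"""Substrate mechanics from standard material tests.

Thin-sheet cutting substrates (elastomer sheets, leaf lamina) are
characterised by three quantities: the fracture toughness ``G_c``
(energy per unit area of new crack surface, J m^-2), a characteristic
strength ``sigma_c`` (taken as the ultimate tensile strength, Pa), and
the sheet thickness ``t`` (m).  Together these set the minimum cutting
force ``G_c * t`` and the material length scale ``G_c / sigma_c`` that
competes with the cutting-edge radius of the tool.

Toughness is measured with the paired pure-shear tearing protocol: an
unnotched and a notched rectangular sample are stretched identically;
the critical displacement at which the notched sample ruptures is read
off, the force-displacement curve of the unnotched sample is integrated
up to that displacement, and the work is divided by sample width and
thickness.  The Young's modulus comes from the initial linear region of
a uniaxial tension test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MaterialSpec:
    """Mechanical description of a thin cutting substrate.

    Parameters
    ----------
    G_c : float
        Fracture toughness in J m^-2 (equivalently N m^-1).
    sigma_c : float
        Characteristic strength in Pa (ultimate tensile strength).
    t : float
        Sheet thickness in m.
    E : float, optional
        Young's modulus in Pa.  Not needed by the force model; carried
        for completeness when known.
    """

    G_c: float
    sigma_c: float
    t: float
    E: float | None = None

    def __post_init__(self) -> None:
        for name in ("G_c", "sigma_c", "t"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.E is not None and not self.E > 0:
            raise ValueError(f"E must be positive, got {self.E!r}")


#: 4:1 Sylgard-184 PDMS sheet, 200 um target thickness.  sigma_c is the
#: published ultimate tensile strength of PDMS, not derived from the
#: tension fit.
PDMS = MaterialSpec(G_c=100.0, sigma_c=4e6, t=200e-6, E=4.1e6)

#: Median mechanical properties across a large survey of tropical leaf
#: lamina: G_c ~ 400 N/m, t = 200 um, sigma_c ~ 3 MPa.
MEDIAN_TROPICAL_LEAF = MaterialSpec(G_c=400.0, sigma_c=3e6, t=200e-6)

#: Japanese laurel (Aucuba japonica) lamina: median-leaf toughness and
#: strength with the measured laurel thickness of ~250 um.
LAUREL = MaterialSpec(G_c=400.0, sigma_c=3e6, t=250e-6)

MATERIAL_PRESETS: dict[str, MaterialSpec] = {
    "pdms": PDMS,
    "leaf": MEDIAN_TROPICAL_LEAF,
    "laurel": LAUREL,
}


@dataclass(frozen=True)
class TearingPair:
    """A paired pure-shear tearing test.

    ``displacement`` / ``force`` sample the loading curve of the
    unnotched sample (m, N), starting at zero displacement.
    ``notched_critical_displacement`` is the displacement (m) at which
    the notched partner sample ruptured, read from a synchronised
    recording.  ``width`` and ``thickness`` are the sample dimensions
    (m) used to normalise the work of fracture.
    """

    displacement: np.ndarray
    force: np.ndarray
    notched_critical_displacement: float
    width: float
    thickness: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "displacement", np.asarray(self.displacement, dtype=float))
        object.__setattr__(self, "force", np.asarray(self.force, dtype=float))
        if self.displacement.shape != self.force.shape:
            raise ValueError("displacement and force must have the same shape")
        if self.displacement.size < 2:
            raise ValueError("tearing curve needs at least two samples")
        if self.displacement[0] != 0:
            raise ValueError("tearing curve must start at zero displacement")
        if np.any(np.diff(self.displacement) <= 0):
            raise ValueError("displacement must be strictly increasing")
        if not (self.width > 0 and self.thickness > 0):
            raise ValueError("width and thickness must be positive")
        if self.notched_critical_displacement < 0:
            raise ValueError("critical displacement must be non-negative")


def toughness_pure_shear(pair: TearingPair) -> float:
    """Fracture toughness G_c (J m^-2) from a paired tearing test.

    Integrates the unnotched force-displacement curve from zero to the
    critical displacement of the notched sample (trapezoid rule, with
    linear interpolation at the endpoint) and divides the work by
    ``width * thickness``.
    """
    d_crit = pair.notched_critical_displacement
    if d_crit == 0:
        return 0.0
    if d_crit > pair.displacement[-1]:
        raise ValueError(
            "critical displacement lies beyond the sampled unnotched curve "
            f"({d_crit:g} > {pair.displacement[-1]:g} m)"
        )
    if np.any(pair.force < 0):
        warnings.warn("tearing curve contains negative forces", stacklevel=2)
    mask = pair.displacement < d_crit
    x = np.append(pair.displacement[mask], d_crit)
    f = np.append(pair.force[mask], np.interp(d_crit, pair.displacement, pair.force))
    work = np.trapezoid(f, x)
    return float(work / (pair.width * pair.thickness))


def youngs_modulus(
    strain: np.ndarray,
    stress: np.ndarray,
    strain_range: tuple[float, float] = (0.0, 0.10),
) -> float:
    """Young's modulus (Pa): OLS slope of stress on strain in a range.

    The default range, 0-10 % strain, is the initial linear loading
    region of an elastomer tension test.
    """
    strain = np.asarray(strain, dtype=float)
    stress = np.asarray(stress, dtype=float)
    lo, hi = strain_range
    if not hi > lo:
        raise ValueError("strain_range must be increasing")
    mask = (strain >= lo) & (strain <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"need at least 3 samples with strain in [{lo}, {hi}], got {int(mask.sum())}"
        )
    slope, _ = np.polyfit(strain[mask], stress[mask], 1)
    return float(slope)
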