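"""Origin and sign of the induced effective velocity.

A static file with spatially varying cell lengths or vacuole sizes
advects hormone even though nothing moves.  The diagnostic is the ratio
between the cytoplasmic concentration C and the area-weighted average
concentration of the whole cell unit: C/Cbar = Vcell/V, where
Vcell = (l+lam)(omega+lam) is the cell-unit area and V the storage
capacitance.  Where this ratio grows along the file the proportion of
hormone sitting in the (transporting) cytoplasm grows, and the effective
velocity

    U_eff(x) = (K (l+lam) + M)/(omega+lam) * d/dx (Vcell/V)

is positive; the sign of d/dx(C/Cbar) is exactly the sign of U_eff.
Closed-form gradients are provided for the mechanistic special cases
(vacuole only, apoplast only, transverse walls only, constant
cytoplasmic area), all of which are limits of the general expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .continuum import capacitance, transport_groupings
from .geometry import LengthProfile
from .membrane import DimensionlessParameters

__all__ = [
    "ConcentrationRatio",
    "RATIO_CASES",
    "concentration_ratio",
    "ratio_gradient",
    "induced_velocity",
    "positive_velocity_threshold",
]

RATIO_CASES = (
    "general",
    "vacuole_only",
    "apoplast_only",
    "transverse_only",
    "constant_cytoplasm",
)


@dataclass
class ConcentrationRatio:
    """C/Cbar diagnostic along a file."""

    V_cell: np.ndarray   # dimensionless cell-unit area (l+lam)(omega+lam)
    ratio: np.ndarray    # C/Cbar = V_cell/V
    gradient: Optional[np.ndarray] = None
    sigma: Optional[float] = None  # constant cytoplasmic area (1-phi)l, if applicable


def concentration_ratio(l, phi, params: DimensionlessParameters) -> ConcentrationRatio:
    """Cytoplasmic over area-weighted average concentration, C/Cbar = Vcell/V."""
    l = np.asarray(l, dtype=float)
    phi = np.asarray(phi, dtype=float)
    V_cell = (l + params.lam) * (params.omega + params.lam)
    V = capacitance(params, l, phi)
    return ConcentrationRatio(V_cell=V_cell, ratio=V_cell / V)


def ratio_gradient(
    profile: LengthProfile,
    params: DimensionlessParameters,
    x,
    case: str = "general",
    t: float = 0.0,
):
    """Closed-form d/dx (C/Cbar) along a static profile.

    ``general`` evaluates the full expression

        -omega (omega+lam)/V^2 * [(l^2 phi' + lam l phi' + lam phi l')(P_v - 1)
                                   + lam l' (1 - P_a)],

    whose special cases drop the apoplast (``vacuole_only``: lam = 0), the
    vacuole (``apoplast_only``: phi = 0), or keep only the transverse
    walls (``transverse_only``).  ``constant_cytoplasm`` enforces
    (1-phi) l constant, leaving the gradient proportional to l'.
    """
    if case not in RATIO_CASES:
        raise ValueError(f"unknown case {case!r}; expected one of {RATIO_CASES}")
    p = params
    lam, om = p.lam, p.omega
    Pa, Pv = p.ratio_a, p.ratio_v
    x = np.asarray(x, dtype=float)
    l = np.asarray(profile.l(x, t), dtype=float)
    phi = np.asarray(profile.phi(x, t), dtype=float)
    l_x = np.asarray(profile.dl_dx(x, t), dtype=float)
    phi_x = np.asarray(profile.dphi_dx(x, t), dtype=float)

    if case == "vacuole_only":
        # no apoplast: C/Cbar = 1/(1 + phi (P_v - 1))
        return -phi_x * (Pv - 1.0) / (1.0 + phi * (Pv - 1.0)) ** 2
    if case == "apoplast_only":
        den = om * l + lam * (om + lam + l) * Pa
        return -l_x * om * lam * (1.0 - Pa) * (om + lam) / den**2
    if case == "transverse_only":
        # only the walls between cytoplasms: C/Cbar = (l+lam)/(l+lam P_a)
        return -l_x * lam * (1.0 - Pa) / (l + lam * Pa) ** 2
    V = capacitance(p, l, phi)
    if case == "constant_cytoplasm":
        sigma = (1.0 - phi) * l
        residual = (1.0 - phi) * l_x - l * phi_x
        if np.max(np.abs(residual)) > 1e-8 * max(1.0, float(np.max(np.abs(l_x)))):
            raise ValueError(
                "constant_cytoplasm requires (1-phi) dl/dx = l dphi/dx along the profile"
            )
        return (
            om * (om + lam) * ((sigma + lam) * (Pv - 1.0) + lam * (1.0 - Pa))
            / V**2 * l_x
        )
    bracket = (l**2 * phi_x + lam * l * phi_x + lam * phi * l_x) * (Pv - 1.0) + lam * l_x * (
        1.0 - Pa
    )
    return -om * (om + lam) / V**2 * bracket


def induced_velocity(profile: LengthProfile, params: DimensionlessParameters, x, t: float = 0.0):
    """Induced effective velocity of a static spatial file via the ratio form.

    U_eff(x) = (K (l+lam) + M)/(omega+lam) * d/dx (Vcell/V); identical to
    the advective coefficient of the macroscale equation for u = 0.
    """
    p = params
    x = np.asarray(x, dtype=float)
    l = np.asarray(profile.l(x, t), dtype=float)
    K, M = transport_groupings(p)
    grad = ratio_gradient(profile, p, x, case="general", t=t)
    return (K * (l + p.lam) + M) / (p.omega + p.lam) * grad


def positive_velocity_threshold(sigma: float, lam: float, ratio_a: float) -> float:
    """Largest P_v for which an increasing-length file still advects forward.

    For constant cytoplasmic area sigma = (1-phi) l and dl/dx > 0 the
    induced velocity is positive iff P_v < (sigma + lam P_a)/(sigma + lam).
    The threshold is just below one for thin walls, so knocking out the
    tonoplast importer (P_v = B1/C1 << 1) flips the velocity positive.
    """
    return (sigma + lam * ratio_a) / (sigma + lam)
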