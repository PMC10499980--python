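"""Membrane chemistry of weak-acid hormone transport.

Weak-acid hormones such as gibberellin (GA), ABA and auxin exist in a
protonated (neutral) and an anionic form.  Only the protonated fraction —
set by the compartment pH and the dissociation constant pK — crosses lipid
membranes passively; the anion is carried by transporter proteins whose
flux follows Goldman–Hodgkin–Katz (GHK) electrodiffusion across the charged
membrane.  This module converts the raw physiology (pH values, membrane
potentials, transporter permeabilities) into the partition factors and the
four *effective* permeabilities

    P_ca = B1*P_pass + B2*P_imp      (cytoplasm -> apoplast)
    P_ac = A1*P_pass + A2*P_imp      (apoplast  -> cytoplasm)
    P_cv = B1*P_pass + B3*P_exp      (cytoplasm -> vacuole)
    P_vc = C1*P_pass + C3*P_exp      (vacuole   -> cytoplasm)

that drive every flux in the cell-file model, together with the
quasi-static concentration ratios  P_a = P_ca/P_ac  (apoplast/cytoplasm)
and  P_v = P_cv/P_vc  (vacuole/cytoplasm).

Loss-of-function transporter mutants are handled by zeroing the importer
(``P_imp``) and/or the tonoplast exporter (``P_exp``) permeability before
the effective permeabilities are combined, so every downstream mutant
formula emerges from the single wild-type expression.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .geometry import CellFileGeometry

__all__ = [
    "WILD_TYPE",
    "NO_CYT_IMPORTER",
    "NO_TON_IMPORTER",
    "DOUBLE_MUTANT",
    "MUTANTS",
    "HormonePhysiology",
    "PartitionFactors",
    "EffectivePermeabilities",
    "DimensionlessParameters",
    "protonated_fraction",
    "ghk_factor",
    "partition_factors",
    "effective_permeabilities",
    "nondimensionalize",
]

# mutant flags: which transporter genes are knocked out
WILD_TYPE = "wild_type"
NO_CYT_IMPORTER = "no_cyt_importer"   # npf2.12-like: P_imp = 0
NO_TON_IMPORTER = "no_ton_importer"   # npf2.14-like: P_exp = 0
DOUBLE_MUTANT = "double"              # both knocked out
MUTANTS = (WILD_TYPE, NO_CYT_IMPORTER, NO_TON_IMPORTER, DOUBLE_MUTANT)


@dataclass(frozen=True)
class HormonePhysiology:
    """Dimensional cell-scale chemistry and transport parameters.

    Permeabilities are in um/s, diffusivity in um^2/s, potentials in volts
    (signed, inside relative to outside), temperature in kelvin and the
    upstream concentration in uM.
    """

    pK: float
    pH_apo: float
    pH_cyt: float
    pH_vac: float
    V_mem: float
    V_ton: float
    T_abs: float = 300.0
    F_D: float = 96500.0
    R_gas: float = 8.31
    P_pass: float = 0.0
    P_imp: float = 0.0
    P_exp: float = 0.0
    P_plas: float = 0.0
    D_apo: float = 32.0
    C_up: float = 1.0

    def __post_init__(self) -> None:
        for name in ("P_pass", "P_imp", "P_exp", "P_plas"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.T_abs <= 0:
            raise ValueError("T_abs must be positive")
        if self.D_apo <= 0:
            raise ValueError("D_apo must be positive")

    def with_mutant(self, mutant: str) -> "HormonePhysiology":
        """Return a copy with the mutant's transporter permeabilities zeroed."""
        if mutant not in MUTANTS:
            raise ValueError(f"unknown mutant {mutant!r}; expected one of {MUTANTS}")
        changes = {}
        if mutant in (NO_CYT_IMPORTER, DOUBLE_MUTANT):
            changes["P_imp"] = 0.0
        if mutant in (NO_TON_IMPORTER, DOUBLE_MUTANT):
            changes["P_exp"] = 0.0
        return dataclasses.replace(self, **changes) if changes else self


@dataclass(frozen=True)
class PartitionFactors:
    """pH partition fractions and GHK anion-transport weights."""

    A1: float  # protonated fraction, apoplast
    B1: float  # protonated fraction, cytoplasm
    C1: float  # protonated fraction, vacuole
    A2: float  # GHK weight, apoplast side of plasma membrane
    B2: float  # GHK weight, cytoplasm side of plasma membrane
    B3: float  # GHK weight, cytoplasm side of tonoplast
    C3: float  # GHK weight, vacuole side of tonoplast
    phi_mem: float  # scaled plasma-membrane potential F*V/(R*T)
    phi_ton: float  # scaled tonoplast potential


@dataclass(frozen=True)
class EffectivePermeabilities:
    """Combined passive + facilitated permeabilities and their ratios."""

    P_ca: float
    P_ac: float
    P_cv: float
    P_vc: float
    ratio_a: float  # P_a = P_ca/P_ac, quasi-static apoplast/cytoplasm ratio
    ratio_v: float  # P_v = P_cv/P_vc, quasi-static vacuole/cytoplasm ratio


def protonated_fraction(pH: float, pK: float):
    """Fraction of hormone in the protonated (membrane-permeant) form.

    Henderson–Hasselbalch partitioning: 1/(1 + 10**(pH - pK)).
    """
    return 1.0 / (1.0 + 10.0 ** (np.asarray(pH) - pK))


def ghk_factor(phi):
    """GHK voltage weighting q(phi) = phi / (exp(phi) - 1).

    The singularity at phi = 0 is removable (q -> 1); a short series is
    used for |phi| < 1e-6.  Stable for |phi| up to several hundred.
    """
    phi = np.asarray(phi, dtype=float)
    small = np.abs(phi) < 1e-6
    # series: phi/(e^phi - 1) = 1 - phi/2 + phi^2/12 + O(phi^4)
    series = 1.0 - phi / 2.0 + phi * phi / 12.0
    with np.errstate(over="ignore", invalid="ignore"):
        exact = np.where(small, 1.0, phi / np.expm1(np.where(small, 1.0, phi)))
    out = np.where(small, series, exact)
    return out if out.ndim else float(out)


def partition_factors(phys: HormonePhysiology) -> PartitionFactors:
    """Partition fractions A1, B1, C1 and GHK weights A2, B2, B3, C3."""
    A1 = float(protonated_fraction(phys.pH_apo, phys.pK))
    B1 = float(protonated_fraction(phys.pH_cyt, phys.pK))
    C1 = float(protonated_fraction(phys.pH_vac, phys.pK))
    phi_mem = phys.F_D * phys.V_mem / (phys.R_gas * phys.T_abs)
    phi_ton = phys.F_D * phys.V_ton / (phys.R_gas * phys.T_abs)
    return PartitionFactors(
        A1=A1,
        B1=B1,
        C1=C1,
        A2=float(ghk_factor(phi_mem)) * (1.0 - A1),
        B2=float(ghk_factor(-phi_mem)) * (1.0 - B1),
        B3=float(ghk_factor(phi_ton)) * (1.0 - B1),
        C3=float(ghk_factor(-phi_ton)) * (1.0 - C1),
        phi_mem=phi_mem,
        phi_ton=phi_ton,
    )


def effective_permeabilities(
    phys: HormonePhysiology, mutant: str = WILD_TYPE
) -> EffectivePermeabilities:
    """Effective cytoplasm<->apoplast and cytoplasm<->vacuole permeabilities.

    The ``mutant`` flag zeroes the corresponding transporter permeability
    before combining, so mutant transport coefficients are obtained from
    the same formulas as the wild type.
    """
    phys = phys.with_mutant(mutant)
    k = partition_factors(phys)
    P_ca = k.B1 * phys.P_pass + k.B2 * phys.P_imp
    P_ac = k.A1 * phys.P_pass + k.A2 * phys.P_imp
    P_cv = k.B1 * phys.P_pass + k.B3 * phys.P_exp
    P_vc = k.C1 * phys.P_pass + k.C3 * phys.P_exp
    if P_ac == 0.0 or P_vc == 0.0:
        raise ValueError(
            "all permeabilities feeding P_ac or P_vc are zero; "
            "the quasi-static ratios P_a, P_v are undefined"
        )
    return EffectivePermeabilities(
        P_ca=P_ca, P_ac=P_ac, P_cv=P_cv, P_vc=P_vc,
        ratio_a=P_ca / P_ac, ratio_v=P_cv / P_vc,
    )


@dataclass(frozen=True)
class DimensionlessParameters:
    """Dimensionless parameter set of the cell-file transport model.

    Geometry ratios use the reference cell length ``l_ref`` (the common
    length of an identical file, or the average initial length of a
    spatially varying file); permeabilities are scaled with the apoplastic
    diffusive rate D_apo/(l_ref + a); time with L0**2/D_apo where L0 is the
    initial file length.
    """

    eps: float      # cell length / file length = 1/N
    lam: float      # apoplast thickness / cell length
    omega: float    # cell width / cell length
    phi: float      # vacuolar area fraction (reference value)
    P_pass: float
    P_imp: float
    P_exp: float
    P_plas: float
    P_ca: float
    P_ac: float
    P_cv: float
    P_vc: float
    ratio_a: float
    ratio_v: float
    time_scale: float   # seconds per dimensionless time unit, L0^2/D_apo
    l_ref: float        # reference cell length, um
    file_length: float  # initial file length L0, um
    d_apo: float        # apoplastic diffusivity, um^2/s

    # --- rescaled variables of the asymptotic limit regimes -------------
    @property
    def lam_tilde(self) -> float:
        """lam/eps — O(1) apoplast ratio of the short-cell limit."""
        return self.lam / self.eps

    @property
    def lam_bar(self) -> float:
        """lam/eps**2 — O(1) apoplast ratio of the long-cell limit."""
        return self.lam / self.eps**2

    @property
    def omega_tilde(self) -> float:
        """omega/eps — O(1) width ratio of the long-cell limit."""
        return self.omega / self.eps

    @property
    def ratio_a_tilde(self) -> float:
        """P_a/eps — O(1) apoplast/cytoplasm ratio of both limits."""
        return self.ratio_a / self.eps

    @property
    def P_ca_bar(self) -> float:
        """P_ca/eps**2 — O(1) membrane permeability of both limits."""
        return self.P_ca / self.eps**2

    def without_plasmodesmata(self) -> "DimensionlessParameters":
        return dataclasses.replace(self, P_plas=0.0)

    def with_phi(self, phi: float) -> "DimensionlessParameters":
        return dataclasses.replace(self, phi=phi)


def nondimensionalize(
    phys: HormonePhysiology,
    geom: "CellFileGeometry",
    mutant: str = WILD_TYPE,
) -> DimensionlessParameters:
    """Scale the dimensional parameter set into the model's dimensionless form.

    Lengths scale with the (average initial) cell length, permeabilities
    with D_apo/(l_ref + a), time with L0^2/D_apo.
    """
    l_ref = geom.l_av
    if l_ref <= 0 or geom.width_um <= 0 or geom.apoplast_um < 0:
        raise ValueError("geometry lengths must be positive")
    scale = (l_ref + geom.apoplast_um) / phys.D_apo
    perm = effective_permeabilities(phys, mutant)
    phys_m = phys.with_mutant(mutant)
    L0 = geom.file_length
    return DimensionlessParameters(
        eps=1.0 / geom.n_cells,
        lam=geom.apoplast_um / l_ref,
        omega=geom.width_um / l_ref,
        phi=float(np.mean(geom.fractions)) if geom.fractions is not None else geom.phi,
        P_pass=phys_m.P_pass * scale,
        P_imp=phys_m.P_imp * scale,
        P_exp=phys_m.P_exp * scale,
        P_plas=phys_m.P_plas * scale,
        P_ca=perm.P_ca * scale,
        P_ac=perm.P_ac * scale,
        P_cv=perm.P_cv * scale,
        P_vc=perm.P_vc * scale,
        ratio_a=perm.ratio_a,
        ratio_v=perm.ratio_v,
        time_scale=L0**2 / phys.D_apo,
        l_ref=l_ref,
        file_length=L0,
        d_apo=phys.D_apo,
    )
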