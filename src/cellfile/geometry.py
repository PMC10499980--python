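"""Cell-file geometry, prescribed length/vacuole fields and division schedules.

The file spans N cell units; the continuum coordinate x runs from the
centre of cell 1 (x = 0) to the centre of cell N+1 (x = 1), scaled with the
initial file length L0 = N*(l_av + a).  Cell lengths l and vacuolar
fractions phi are *prescribed* fields l(x, t), phi(x, t) — growth is
kinematic, not mechanical — and each profile kind carries its derivatives
analytically so the effective coefficients built from them are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CellFileGeometry",
    "LengthProfile",
    "StaticUniformProfile",
    "LinearGrowthProfile",
    "LinearSpatialProfile",
    "DivisionSchedule",
    "ExponentialDivisionProfile",
    "FittedLinearFile",
    "cell_centers",
    "fit_linear_file",
    "growth_velocity",
    "vacuolar_expansion_fraction",
    "average_vacuolar_fraction",
    "division_length",
]


@dataclass(frozen=True)
class CellFileGeometry:
    """Static description of a cell file.

    ``lengths_um``/``fractions`` hold per-cell values for cells 1..N+1
    (ends of the domain sit at the centres of cells 1 and N+1).  For an
    identical file pass scalars via :meth:`uniform`.
    """

    n_cells: int
    width_um: float
    apoplast_um: float
    lengths_um: np.ndarray          # shape (N+1,)
    fractions: np.ndarray           # shape (N+1,), each in (0, 1)

    def __post_init__(self) -> None:
        lengths = np.atleast_1d(np.asarray(self.lengths_um, dtype=float))
        fracs = np.atleast_1d(np.asarray(self.fractions, dtype=float))
        if lengths.size == 1:
            lengths = np.full(self.n_cells + 1, lengths[0])
        if fracs.size == 1:
            fracs = np.full(self.n_cells + 1, fracs[0])
        if lengths.size != self.n_cells + 1 or fracs.size != self.n_cells + 1:
            raise ValueError("need lengths/fractions for cells 1..N+1")
        if np.any(lengths <= 0):
            raise ValueError("cell lengths must be positive")
        if np.any((fracs <= 0) | (fracs >= 1)):
            raise ValueError("vacuolar fractions must lie in (0, 1)")
        object.__setattr__(self, "lengths_um", lengths)
        object.__setattr__(self, "fractions", fracs)

    @classmethod
    def uniform(
        cls,
        n_cells: int,
        length_um: float,
        width_um: float,
        apoplast_um: float,
        phi: float,
    ) -> "CellFileGeometry":
        return cls(
            n_cells=n_cells,
            width_um=width_um,
            apoplast_um=apoplast_um,
            lengths_um=np.full(n_cells + 1, float(length_um)),
            fractions=np.full(n_cells + 1, float(phi)),
        )

    @property
    def l_av(self) -> float:
        """Average initial cell length, um: L0/N - a.

        End cells carry half weight because the domain runs between their
        centres.
        """
        l = self.lengths_um
        return float((l[1:-1].sum() + 0.5 * (l[0] + l[-1])) / self.n_cells)

    @property
    def file_length(self) -> float:
        """Initial file length L0 = N*(l_av + a), um."""
        return self.n_cells * (self.l_av + self.apoplast_um)

    @property
    def phi(self) -> float:
        """Representative vacuolar fraction (length-weighted mean)."""
        l = self.lengths_um
        w = np.concatenate([[0.5 * l[0]], l[1:-1], [0.5 * l[-1]]])
        return float(np.sum(w * self.fractions) / np.sum(w))

    @property
    def lengths_dimless(self) -> np.ndarray:
        return self.lengths_um / self.l_av


def cell_centers(lengths: np.ndarray, lam: float, n_cells: Optional[int] = None) -> np.ndarray:
    """Cell-centre positions x_i in [0, 1] from per-cell dimensionless lengths.

    ``lengths`` holds l_1..l_{N+1} in units of the average cell length;
    ``lam`` is the dimensionless apoplast thickness.  The centre of cell i
    sits a distance l_1/2 + sum_{j=2}^{i-1} l_j + l_i/2 + (i-1)*lam along
    the file, scaled by the total N*(1 + lam).
    """
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("cell lengths must be positive")
    N = (lengths.size - 1) if n_cells is None else n_cells
    if lengths.size != N + 1:
        raise ValueError("expected N+1 cell lengths")
    # cumulative interior lengths: sum_{j=2}^{i-1} l_j
    interior = np.concatenate([[0.0, 0.0], np.cumsum(lengths[1:-1])])[: N + 1]
    i = np.arange(N + 1)
    x = lengths[0] / 2.0 + interior + lengths / 2.0 + i * lam
    x[0] = 0.0
    return x / (N * (1.0 + lam))


@dataclass(frozen=True)
class FittedLinearFile:
    """Self-consistent discretisation of a linearly varying cell file."""

    l_av_um: float
    file_length_um: float
    alpha: float                 # dimensionless length gradient
    nu: float                    # dimensionless first-cell length
    lengths_um: np.ndarray       # shape (N+1,)
    fractions: np.ndarray        # shape (N+1,)
    centers: np.ndarray          # dimensionless positions x_i in [0, 1]
    n_cells: int
    apoplast_um: float

    def geometry(self, width_um: float) -> CellFileGeometry:
        return CellFileGeometry(
            n_cells=self.n_cells,
            width_um=width_um,
            apoplast_um=self.apoplast_um,
            lengths_um=self.lengths_um,
            fractions=self.fractions,
        )


def fit_linear_file(
    l1_um: float,
    lN1_um: float,
    phi1: float,
    phiN1: float,
    n_cells: int,
    apoplast_um: float,
    rel_tol: float = 1e-12,
    max_iter: int = 1000,
) -> FittedLinearFile:
    """Fit per-cell lengths so each equals the linear profile at its own centre.

    The macroscale profile l(x) = alpha*x + nu is pinned by the first and
    last (N+1-st) cell lengths; a cell's centre position depends on all the
    lengths, so the discretisation is a fixed point: iterate centre
    positions and profile evaluation until the lengths are self-consistent,
    then read off l_av, L0, alpha and nu.
    """
    if l1_um <= 0 or lN1_um <= 0:
        raise ValueError("end-cell lengths must be positive")
    N = n_cells
    a = apoplast_um
    lengths = np.linspace(l1_um, lN1_um, N + 1)  # initial guess: linear in index
    for _ in range(max_iter):
        # dimensional centre positions measured from the centre of cell 1
        interior = np.concatenate([[0.0, 0.0], np.cumsum(lengths[1:-1])])[: N + 1]
        x = lengths[0] / 2.0 + interior + lengths / 2.0 + np.arange(N + 1) * a
        x[0] = 0.0
        alpha_hat = (lN1_um - l1_um) / x[-1]
        new = l1_um + alpha_hat * x
        if np.max(np.abs(new - lengths)) < rel_tol * max(l1_um, lN1_um):
            lengths = new
            break
        lengths = new
    else:
        raise RuntimeError("linear-file fit did not converge; inconsistent inputs")
    l_av = (lengths[1:-1].sum() + 0.5 * (lengths[0] + lengths[-1])) / N
    L0 = N * (l_av + a)
    fractions = phi1 + (phiN1 - phi1) * x / x[-1]
    return FittedLinearFile(
        l_av_um=float(l_av),
        file_length_um=float(L0),
        alpha=float((lN1_um - l1_um) / l_av),
        nu=float(l1_um / l_av),
        lengths_um=lengths,
        fractions=fractions,
        centers=x / x[-1],
        n_cells=N,
        apoplast_um=a,
    )


# ---------------------------------------------------------------------------
# prescribed length / vacuolar-fraction profiles
# ---------------------------------------------------------------------------

class LengthProfile:
    """Base class: dimensionless fields l(x, t), phi(x, t) with derivatives.

    Derivatives are analytic per profile kind — never finite differences —
    so the effective velocity and sink built from them are exact.
    """

    kind: str = "abstract"

    def l(self, x, t):  # noqa: E743 - field name follows the model
        raise NotImplementedError

    def phi(self, x, t):
        raise NotImplementedError

    def dl_dx(self, x, t):
        return np.zeros_like(np.asarray(x, dtype=float))

    def dl_dt(self, x, t):
        return np.zeros_like(np.asarray(x, dtype=float))

    def dphi_dx(self, x, t):
        return np.zeros_like(np.asarray(x, dtype=float))

    def dphi_dt(self, x, t):
        return np.zeros_like(np.asarray(x, dtype=float))

    @property
    def is_static(self) -> bool:
        return False

    @property
    def is_uniform(self) -> bool:
        """True when l and phi do not vary with x."""
        return False


@dataclass(frozen=True)
class StaticUniformProfile(LengthProfile):
    """Identical non-growing cells: l = 1, phi = phi0."""

    phi0: float = 0.1
    kind: str = field(default="static_uniform", init=False)

    def l(self, x, t):
        return np.ones_like(np.asarray(x, dtype=float))

    def phi(self, x, t):
        return np.full_like(np.asarray(x, dtype=float), self.phi0)

    @property
    def is_static(self) -> bool:
        return True

    @property
    def is_uniform(self) -> bool:
        return True


@dataclass(frozen=True)
class LinearGrowthProfile(LengthProfile):
    """Identical cells elongating linearly in time: l = kappa*t + 1.

    With ``vacuolar_expansion`` (the default, appropriate for the root
    elongation zone) the cytoplasmic area (1 - phi)*l stays fixed at its
    initial value, so phi = 1 - (1 - phi0)/l; otherwise phi is constant.
    """

    kappa: float
    phi0: float = 0.1
    vacuolar_expansion: bool = True
    kind: str = field(default="linear_time", init=False)

    def l(self, x, t):
        return np.asarray(x, dtype=float) * 0.0 + (self.kappa * np.asarray(t, dtype=float) + 1.0)

    def phi(self, x, t):
        l = self.l(x, t)
        if self.vacuolar_expansion:
            return vacuolar_expansion_fraction(l, 1.0, self.phi0)
        return np.full_like(np.asarray(l, dtype=float), self.phi0)

    def dl_dt(self, x, t):
        return np.full_like(np.asarray(x, dtype=float), self.kappa)

    def dphi_dt(self, x, t):
        if not self.vacuolar_expansion:
            return np.zeros_like(np.asarray(x, dtype=float))
        l = self.l(x, t)
        return (1.0 - self.phi0) / l**2 * self.kappa

    @property
    def is_uniform(self) -> bool:
        return True


@dataclass(frozen=True)
class LinearSpatialProfile(LengthProfile):
    """Static file with linearly varying lengths: l(x) = alpha*x + nu.

    The vacuolar fraction varies linearly between the end cells,
    phi(x) = phi1 + (phiN1 - phi1)*x.
    """

    alpha: float
    nu: float
    phi1: float = 0.1
    phiN1: float = 0.9
    kind: str = field(default="linear_space", init=False)

    def l(self, x, t=0.0):
        return self.alpha * np.asarray(x, dtype=float) + self.nu

    def phi(self, x, t=0.0):
        return self.phi1 + (self.phiN1 - self.phi1) * np.asarray(x, dtype=float)

    def dl_dx(self, x, t=0.0):
        return np.full_like(np.asarray(x, dtype=float), self.alpha)

    def dphi_dx(self, x, t=0.0):
        return np.full_like(np.asarray(x, dtype=float), self.phiN1 - self.phi1)

    @property
    def is_static(self) -> bool:
        return True


@dataclass(frozen=True)
class DivisionSchedule:
    """Synchronous growth-and-division timing.

    Cells elongate exponentially at relative rate mu and divide in two as
    soon as they double, which fixes mu = ln(2)/T_div.  ``lam`` is the
    dimensionless thickness of the apoplast wall inserted between the two
    daughters.
    """

    T_div: float
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.T_div <= 0:
            raise ValueError("T_div must be positive")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")

    @property
    def mu(self) -> float:
        return math.log(2.0) / self.T_div


def division_length(t, sched: DivisionSchedule):
    """Cell length l_d(t) under exponential growth with halving at t = nT.

    l_d = (1 - lam*(1 - 2**(-floor(t/T)))) * exp(mu*(t - T*floor(t/T))).
    At t = nT exactly the post-division (right-limit) value is returned:
    the state after an event carries the new cell count.
    """
    t = np.asarray(t, dtype=float)
    n = np.floor(t / sched.T_div)
    prefactor = 1.0 - sched.lam * (1.0 - 2.0 ** (-n))
    out = prefactor * np.exp(sched.mu * (t - sched.T_div * n))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ExponentialDivisionProfile(LengthProfile):
    """Identical exponentially growing cells dividing synchronously.

    l(t) follows :func:`division_length`; the vacuole stays at a fixed
    fraction ``phi0`` (meristem-like growth, cytoplasm and vacuole expand
    together).  ``l_undivided`` = exp(mu*t) tracks the overall file growth,
    which division does not alter.
    """

    sched: DivisionSchedule
    phi0: float = 0.1
    kind: str = field(default="exponential_division", init=False)

    def l(self, x, t):
        return np.asarray(x, dtype=float) * 0.0 + division_length(t, self.sched)

    def phi(self, x, t):
        return np.full_like(np.asarray(x, dtype=float), self.phi0)

    def dl_dt(self, x, t):
        # between events dl/dt = mu * l_d
        return self.sched.mu * self.l(x, t)

    def l_undivided(self, t):
        return np.exp(self.sched.mu * np.asarray(t, dtype=float))

    @property
    def is_uniform(self) -> bool:
        return True


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def growth_velocity(profile: LengthProfile, lam: float):
    """Velocity field u(x, t) of the growing file, anchored at u(0, t) = 0.

    Cell density is 1/(l + lam); mass conservation gives
    d/dx (u/(l + lam)) = (1/(l + lam)^2) * dl/dt.  For spatially uniform
    profiles this integrates exactly to u = x/(l + lam) * dl/dt; static
    profiles give u = 0.  General mixed profiles are integrated
    numerically with the trapezoidal rule on a refined grid.
    """
    if profile.is_static:
        def u(x, t=0.0):
            return np.zeros_like(np.asarray(x, dtype=float))
        return u
    if profile.is_uniform:
        def u(x, t):
            x = np.asarray(x, dtype=float)
            l = profile.l(0.0, t)
            return x / (l + lam) * profile.dl_dt(0.0, t)
        return u

    def u(x, t, _n=2001):
        x = np.asarray(x, dtype=float)
        hi = max(float(np.max(x)), 1.0)
        grid = np.linspace(0.0, hi, _n)
        integrand = profile.dl_dt(grid, t) / (profile.l(grid, t) + lam) ** 2
        cumulative = np.concatenate(
            [[0.0], np.cumsum((integrand[1:] + integrand[:-1]) / 2.0 * np.diff(grid))]
        )
        val = (profile.l(x, t) + lam) * np.interp(x, grid, cumulative)
        return val
    return u


def vacuolar_expansion_fraction(l, l0, phi0):
    """Vacuolar fraction when all elongation goes into the vacuole.

    The cytoplasmic area (1 - phi)*l is conserved: phi = 1 - (1 - phi0)*l0/l.
    Rejects lengths that would require a negative vacuole.
    """
    l = np.asarray(l, dtype=float)
    if np.any(l < l0 * (1.0 - phi0)):
        raise ValueError("length below the conserved cytoplasmic area")
    out = 1.0 - (1.0 - phi0) * l0 / l
    return out if out.ndim else float(out)


def average_vacuolar_fraction(lengths, fractions, l_av: Optional[float] = None) -> float:
    """Vacuolar-area-preserving average fraction of a matched identical file.

    Trapezoid weighting (half weight on the two end cells, which sit on
    the domain boundary):
    phi_av = [phi1*l1/2 + sum_{2..N} phi_j*l_j + phi_{N+1}*l_{N+1}/2] / (N*l_av).
    """
    lengths = np.asarray(lengths, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    N = lengths.size - 1
    if l_av is None:
        l_av = (lengths[1:-1].sum() + 0.5 * (lengths[0] + lengths[-1])) / N
    total = (
        fractions[0] * lengths[0] / 2.0
        + float(np.sum(fractions[1:-1] * lengths[1:-1]))
        + fractions[-1] * lengths[-1] / 2.0
    )
    return float(total / (N * l_av))
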