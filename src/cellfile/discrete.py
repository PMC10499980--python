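"""Discrete multicellular ODE model of hormone transport along a cell file.

Each of the N cell units carries five compartments — cytoplasm (c),
vacuole (v) and three apoplastic compartments: transverse (f, the wall
shared with the next cell), corner (g) and longitudinal (h, the wall
running along the cell).  Fluxes are linear in the concentrations:
effective membrane permeabilities between cytoplasm and apoplast/vacuole,
apoplastic diffusion between wall compartments, and plasmodesmatal
diffusion directly between adjacent cytoplasms.

For a file of T tracked cells the unknowns are c_i, h_i for cells 2..T,
v_i for cells 1..T and f_i, g_i for cells 1..T — 5T-2 in total.  The
upstream boundary fixes c_1 = c_up and h_1 = Upsilon = P_a * c_up (the
quasi-static apoplastic value); the downstream end is closed by ghost
reflection about the last tracked cell, c_{T+1} = c_{T-1},
h_{T+1} = h_{T-1}.  The continuum domain x in [0, 1] runs between the
centres of the first and last cells, so a file of N cell units
(eps = 1/N) tracks T = N+1 cells and the no-flux reflection sits exactly
at the domain end, matching the continuum boundary condition.

For growing files the equations evolve the conserved *amounts*
(1-phi_i) l_i c_i, phi_i l_i v_i and l_i h_i, so growth dilution enters
through the product rule and the hormone budget is machine-exact; the
time derivatives are Lagrangian (cell-following).  The system is linear
and stiff (the compartment capacitances are O(eps^2)); it is integrated
with a BDF method and the analytic Jacobian of the flux operator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .geometry import (
    CellFileGeometry,
    DivisionSchedule,
    LengthProfile,
    StaticUniformProfile,
    cell_centers,
)
from .membrane import DimensionlessParameters

__all__ = [
    "FileState",
    "BoundaryData",
    "DiscreteTrajectory",
    "DivisionTrajectory",
    "CellFileSystem",
    "equilibrium_state",
    "compartment_fluxes",
    "rhs_static",
    "rhs_growing",
    "simulate_discrete",
    "simulate_with_division",
]


@dataclass
class FileState:
    """Per-cell concentration vectors at one instant.

    Arrays cover cells 1..N.  ``c[0]`` and ``h[0]`` are the prescribed
    upstream boundary values; every other entry is a tracked unknown.
    """

    t: float
    c: np.ndarray
    v: np.ndarray
    f: np.ndarray
    g: np.ndarray
    h: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.c.size


@dataclass(frozen=True)
class BoundaryData:
    """Upstream Dirichlet data; the downstream end is ghost-reflected.

    ``upsilon`` is the upstream longitudinal-apoplast concentration; in the
    quasi-static regime it must equal ratio_a * c_up, which is the default.
    """

    c_up: float = 1.0
    upsilon: Optional[float] = None

    def resolved_upsilon(self, params: DimensionlessParameters) -> float:
        if self.upsilon is not None:
            return self.upsilon
        return params.ratio_a * self.c_up


class CellFileSystem:
    """Assembles and integrates the 5N-2 linear ODE system.

    ``lengths`` / ``fractions`` supply per-cell l_i(t), phi_i(t) for cells
    1..N+1 either as fixed arrays (static files) or callables of t
    (growing files), together with their time derivatives.
    """

    def __init__(
        self,
        params: DimensionlessParameters,
        n_cells: int,
        lengths: Callable[[float], np.ndarray] | np.ndarray | None = None,
        dlengths_dt: Callable[[float], np.ndarray] | np.ndarray | None = None,
        fractions: Callable[[float], np.ndarray] | np.ndarray | None = None,
        dfractions_dt: Callable[[float], np.ndarray] | np.ndarray | None = None,
        boundary: BoundaryData = BoundaryData(),
        downstream: str = "mirror",
    ) -> None:
        self.params = params
        self.N = int(n_cells)
        if self.N < 2:
            raise ValueError("need at least 2 cells")
        if downstream not in ("mirror", "copy"):
            raise ValueError("downstream must be 'mirror' (c_{T+1}=c_{T-1}) or 'copy' (c_{T+1}=c_T)")
        self.downstream = downstream
        self.boundary = boundary
        self.upsilon = boundary.resolved_upsilon(params)

        ones = np.ones(self.N + 1)
        self._l = self._as_fun(lengths, ones)
        self._dl = self._as_fun(dlengths_dt, np.zeros(self.N + 1))
        self._phi = self._as_fun(fractions, ones * params.phi)
        self._dphi = self._as_fun(dfractions_dt, np.zeros(self.N + 1))
        self.time_dependent = callable(lengths) or callable(fractions)
        self.n_state = 5 * self.N - 2

    @staticmethod
    def _as_fun(value, default):
        if value is None:
            arr = np.asarray(default, dtype=float)
            return lambda t, _a=arr: _a
        if callable(value):
            return value
        arr = np.asarray(value, dtype=float)
        return lambda t, _a=arr: _a

    # --- state vector layout -------------------------------------------
    # amounts alpha=(1-phi)l c (cells 2..N), nu=phi l v (cells 1..N),
    # concentrations f, g (cells 1..N), amounts eta=l h (cells 2..N)
    def _slices(self):
        N = self.N
        nb = N - 1
        return (
            slice(0, nb),                      # c amounts, cells 2..N
            slice(nb, nb + N),                 # v amounts, cells 1..N
            slice(nb + N, nb + 2 * N),         # f, cells 1..N
            slice(nb + 2 * N, nb + 3 * N),     # g, cells 1..N
            slice(nb + 3 * N, nb + 3 * N + nb),  # h amounts, cells 2..N
        )

    def concentrations(self, t: float, y: np.ndarray) -> FileState:
        """Unpack the amount-based state vector into concentrations."""
        N = self.N
        sc, sv, sf, sg, sh = self._slices()
        l = self._l(t)
        phi = self._phi(t)
        c = np.empty(N)
        h = np.empty(N)
        c[0] = self.boundary.c_up
        h[0] = self.upsilon
        c[1:] = y[sc] / ((1.0 - phi[1:N]) * l[1:N])
        h[1:] = y[sh] / l[1:N]
        v = y[sv] / (phi[:N] * l[:N])
        return FileState(t=t, c=c, v=v, f=y[sf].copy(), g=y[sg].copy(), h=h)

    def pack(self, state: FileState) -> np.ndarray:
        """Concentrations -> amount-based state vector."""
        N = self.N
        l = self._l(state.t)
        phi = self._phi(state.t)
        y = np.empty(self.n_state)
        sc, sv, sf, sg, sh = self._slices()
        y[sc] = state.c[1:] * (1.0 - phi[1:N]) * l[1:N]
        y[sv] = state.v * phi[:N] * l[:N]
        y[sf] = state.f
        y[sg] = state.g
        y[sh] = state.h[1:] * l[1:N]
        return y

    # --- physics --------------------------------------------------------
    def fluxes(self, t: float, state: FileState) -> dict:
        """All compartment fluxes for the current concentrations.

        Index convention of the returned arrays: J_cf, J_cv, J_fg, J_hg,
        J_cc cover cells 1..N; J_fc and J_gh cover cells 2..N+1; J_ch
        covers cells 2..N.
        """
        p = self.params
        N = self.N
        l = self._l(t)
        c_full = np.empty(N + 1)  # cells 1..N+1 (last = ghost)
        h_full = np.empty(N + 1)
        c_full[:N] = state.c
        h_full[:N] = state.h
        ghost = N - 2 if self.downstream == "mirror" else N - 1
        c_full[N] = c_full[ghost]
        h_full[N] = h_full[ghost]
        f, g = state.f, state.g
        lam, om = p.lam, p.omega
        k_fg = 2.0 * (1.0 + lam) / (om + lam)
        k_l = 2.0 * (1.0 + lam) / (l + lam)  # per-cell, cells 1..N+1
        return {
            "J_cf": p.P_ca * c_full[:N] - p.P_ac * f,
            "J_cv": p.P_cv * c_full[:N] - p.P_vc * np.asarray(state.v),
            "J_fc": p.P_ac * f - p.P_ca * c_full[1:],
            "J_ch": p.P_ca * c_full[1:N] - p.P_ac * h_full[1:N],
            "J_fg": k_fg * (f - g),
            "J_gh": k_l[1:] * (g - h_full[1:]),
            "J_hg": k_l[:N] * (h_full[:N] - g),
            "J_cc": p.P_plas * (c_full[1:] - c_full[:N]),
        }

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Time derivatives of the amount-based state vector."""
        p = self.params
        N = self.N
        l = self._l(t)
        phi = self._phi(t)
        state = self.concentrations(t, y)
        J = self.fluxes(t, state)
        lam, om, eps = p.lam, p.omega, p.eps
        pre = (1.0 + lam) / eps**2

        dy = np.empty(self.n_state)
        sc, sv, sf, sg, sh = self._slices()
        li = l[1:N]       # cells 2..N
        sphi = 2.0 * np.sqrt(phi[:N]) * (l[:N] + om)  # cells 1..N
        Jcv = J["J_cv"]
        # cytoplasm amounts, cells 2..N
        dy[sc] = (pre / om) * (
            om * (J["J_fc"][:-1] - J["J_cf"][1:] + J["J_cc"][1:] - J["J_cc"][:-1])
            - li * J["J_ch"]
            - sphi[1:] * Jcv[1:]
        )
        # vacuole amounts, cells 1..N (cell 1 fed by the fixed upstream c)
        dy[sv] = (pre / om) * sphi * Jcv
        # transverse apoplast concentrations, cells 1..N
        dy[sf] = (pre / (lam * om)) * (om * (J["J_cf"] - J["J_fc"]) - lam * J["J_fg"])
        # corner apoplast concentrations, cells 1..N
        dy[sg] = (pre / lam**2) * lam * (J["J_hg"] - J["J_gh"] + J["J_fg"])
        # longitudinal apoplast amounts, cells 2..N
        dy[sh] = (pre / lam) * (li * J["J_ch"] + lam * (J["J_gh"][:-1] - J["J_hg"][1:]))
        return dy

    def operator(self, t: float = 0.0):
        """Matrix form rhs(t, y) = A y + b of the linear system."""
        n = self.n_state
        b = self.rhs(t, np.zeros(n))
        A = np.empty((n, n))
        e = np.zeros(n)
        for j in range(n):
            e[j] = 1.0
            A[:, j] = self.rhs(t, e) - b
            e[j] = 0.0
        return A, b

    def boundary_influx(self, t: float, state: FileState) -> float:
        """Net hormone influx through the file boundaries (budget weighting).

        Summing the governing equations telescopes every interior flux;
        what remains involves only the fixed boundary values c_1, h_1 and
        the downstream ghosts.
        """
        p = self.params
        N = self.N
        l = self._l(t)
        phi = self._phi(t)
        lam, om = p.lam, p.omega
        gi = N - 2 if self.downstream == "mirror" else N - 1
        c_ghost = state.c[gi]
        h_ghost = state.h[gi]
        influx = 0.0
        # plasmodesmata through the upstream face; downstream ghost flux
        influx += om * p.P_plas * (state.c[0] - state.c[1])
        influx += om * p.P_plas * (c_ghost - state.c[N - 1])
        # transverse-wall exchange with the boundary cells
        influx += om * (p.P_ca * state.c[0] - p.P_ac * state.f[0])       # J_cf_1
        influx -= om * (p.P_ac * state.f[N - 1] - p.P_ca * c_ghost)      # J_fc_{N+1}
        # corner/longitudinal exchange with the boundary walls
        influx += lam * 2.0 * (1.0 + lam) / (l[0] + lam) * (state.h[0] - state.g[0])
        influx -= lam * 2.0 * (1.0 + lam) / (l[N] + lam) * (state.g[N - 1] - h_ghost)
        # the boundary cell's vacuole fills from the fixed upstream cytoplasm
        influx += (
            2.0 * np.sqrt(phi[0]) * (l[0] + om)
            * (p.P_cv * state.c[0] - p.P_vc * state.v[0])
        )
        return float(influx)

    def total_amount(self, t: float, y: np.ndarray) -> float:
        """Capacitance-weighted hormone content of the tracked compartments."""
        p = self.params
        sc, sv, sf, sg, sh = self._slices()
        w = p.eps**2 / (1.0 + p.lam)
        return float(
            w
            * (
                p.omega * (y[sc].sum() + y[sv].sum() + p.lam * y[sf].sum())
                + p.lam**2 * y[sg].sum()
                + p.lam * y[sh].sum()
            )
        )

    # --- integration ----------------------------------------------------
    def simulate(
        self,
        t_eval: Sequence[float],
        y0: Optional[np.ndarray] = None,
        rtol: float = 1e-8,
        atol: float = 1e-10,
    ):
        t_eval = np.asarray(t_eval, dtype=float)
        if y0 is None:
            y0 = np.zeros(self.n_state)
        t_span = (float(t_eval[0]), float(t_eval[-1]))
        if self.time_dependent:
            fun = self.rhs
            jac = lambda t, y: self.operator(t)[0]  # noqa: E731
        else:
            A, b = self.operator(0.0)
            fun = lambda t, y: A @ y + b  # noqa: E731
            jac = lambda t, y: A  # noqa: E731
        sol = solve_ivp(
            fun,
            t_span,
            y0,
            method="BDF",
            t_eval=t_eval,
            jac=jac,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:  # pragma: no cover - surfaced solver diagnostics
            raise RuntimeError(f"discrete integration failed: {sol.message}")
        return sol


@dataclass
class DiscreteTrajectory:
    """Concentration time courses of a discrete simulation.

    Arrays are (n_times, N) over cells 1..N; column 0 of ``c`` and ``h``
    holds the upstream boundary values.
    """

    t: np.ndarray
    c: np.ndarray
    v: np.ndarray
    f: np.ndarray
    g: np.ndarray
    h: np.ndarray
    params: DimensionlessParameters
    system: CellFileSystem

    @property
    def n_cells(self) -> int:
        return self.c.shape[1]

    def state(self, k: int) -> FileState:
        return FileState(
            t=float(self.t[k]), c=self.c[k], v=self.v[k],
            f=self.f[k], g=self.g[k], h=self.h[k],
        )

    def positions(self, k: int = 0) -> np.ndarray:
        """Cell-centre coordinates x_i of the tracked cells at output index k.

        Coordinates are in units of the *initial* file length, so for
        growing files they extend beyond 1 once the file has grown; for a
        static file the last tracked cell sits at x = 1.
        """
        lengths = self.system._l(float(self.t[k]))[: self.n_cells]
        return cell_centers(lengths, self.params.lam, self.n_cells - 1)

    def to_frame(self):
        """Long-format table (time, cell, compartment, concentration)."""
        import pandas as pd

        frames = []
        for name in ("c", "v", "f", "g", "h"):
            arr = getattr(self, name)
            for j in range(arr.shape[1]):
                frames.append(
                    pd.DataFrame(
                        {
                            "time": self.t,
                            "cell": j + 1,
                            "compartment": name,
                            "concentration": arr[:, j],
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)


def _trajectory(system: CellFileSystem, sol) -> DiscreteTrajectory:
    N = system.N
    nt = sol.t.size
    arrays = {k: np.empty((nt, N)) for k in ("c", "v", "f", "g", "h")}
    for k in range(nt):
        st = system.concentrations(sol.t[k], sol.y[:, k])
        for name in arrays:
            arrays[name][k] = getattr(st, name)
    return DiscreteTrajectory(
        t=sol.t.copy(), params=system.params, system=system, **arrays
    )


def equilibrium_state(params: DimensionlessParameters, n_cells: int, c: float = 1.0) -> FileState:
    """Quasi-static equilibrium: uniform c with f = g = h = P_a c, v = P_v c."""
    N = n_cells
    return FileState(
        t=0.0,
        c=np.full(N, c),
        v=np.full(N, params.ratio_v * c),
        f=np.full(N, params.ratio_a * c),
        g=np.full(N, params.ratio_a * c),
        h=np.full(N, params.ratio_a * c),
    )


def compartment_fluxes(
    state: FileState,
    params: DimensionlessParameters,
    lengths: Optional[np.ndarray] = None,
    boundary: BoundaryData = BoundaryData(),
) -> dict:
    """Flux set J_cf, J_cv, J_fc, J_ch, J_fg, J_gh, J_hg, J_cc.

    ``lengths`` are per-cell dimensionless l_i for cells 1..N+1 (defaults
    to the static value 1).
    """
    system = CellFileSystem(
        params, state.n_cells, lengths=lengths, boundary=boundary
    )
    return system.fluxes(state.t, state)


def _concentration_rhs(system: CellFileSystem, state: FileState) -> FileState:
    """Amount derivatives converted back to concentration derivatives."""
    N = system.N
    t = state.t
    y = system.pack(state)
    dy = system.rhs(t, y)
    l = system._l(t)
    dl = system._dl(t)
    phi = system._phi(t)
    dphi = system._dphi(t)
    sc, sv, sf, sg, sh = system._slices()
    cap_c = (1.0 - phi[1:N]) * l[1:N]
    dcap_c = -dphi[1:N] * l[1:N] + (1.0 - phi[1:N]) * dl[1:N]
    cap_v = phi[:N] * l[:N]
    dcap_v = dphi[:N] * l[:N] + phi[:N] * dl[:N]
    dc = np.zeros(N)
    dh = np.zeros(N)
    dc[1:] = (dy[sc] - state.c[1:] * dcap_c) / cap_c
    dv = (dy[sv] - state.v * dcap_v) / cap_v
    dh[1:] = (dy[sh] - state.h[1:] * dl[1:N]) / l[1:N]
    return FileState(t=t, c=dc, v=dv, f=dy[sf], g=dy[sg], h=dh)


def rhs_static(
    state: FileState,
    params: DimensionlessParameters,
    boundary: BoundaryData = BoundaryData(),
) -> FileState:
    """Concentration time derivatives for the identical static file."""
    system = CellFileSystem(params, state.n_cells, boundary=boundary)
    return _concentration_rhs(system, state)


def rhs_growing(
    state: FileState,
    params: DimensionlessParameters,
    profile: LengthProfile,
    boundary: BoundaryData = BoundaryData(),
) -> FileState:
    """Concentration time derivatives for an identical growing file.

    The derivatives are Lagrangian (cell-following); dilution enters via
    the product rule on the conserved amounts.
    """
    system = _system_for_profile(params, state.n_cells - 1, profile, boundary)
    return _concentration_rhs(system, state)


def _mirror(values: np.ndarray) -> np.ndarray:
    """Append the ghost-cell value mirrored about the last entry."""
    values = np.asarray(values, dtype=float)
    return np.concatenate([values, [values[-2]]])


def _system_for_profile(
    params: DimensionlessParameters,
    n_units: int,
    profile: Optional[LengthProfile],
    boundary: BoundaryData,
    geometry: Optional[CellFileGeometry] = None,
) -> CellFileSystem:
    """Build the tracked system for a file of ``n_units`` cell units.

    Tracked cells are 1..N+1 (domain ends at their centres); per-cell
    arrays carry one extra mirrored ghost entry for the downstream
    reflection.
    """
    T = n_units + 1
    if geometry is not None:
        return CellFileSystem(
            params,
            T,
            lengths=_mirror(geometry.lengths_dimless),
            fractions=_mirror(geometry.fractions),
            boundary=boundary,
        )
    if profile is None or isinstance(profile, StaticUniformProfile):
        phi0 = params.phi if profile is None else profile.phi0
        return CellFileSystem(
            params, T, fractions=np.full(T + 1, phi0), boundary=boundary
        )
    if profile.is_static:
        x = _self_consistent_centers(profile, params.lam, n_units)
        return CellFileSystem(
            params,
            T,
            lengths=_mirror(profile.l(x, 0.0)),
            fractions=_mirror(profile.phi(x, 0.0)),
            boundary=boundary,
        )
    if not profile.is_uniform:
        raise NotImplementedError(
            "discrete simulation supports uniform (possibly growing) or static "
            "spatially varying profiles"
        )
    zeros = np.zeros(T + 1)
    return CellFileSystem(
        params,
        T,
        lengths=lambda t: zeros + profile.l(zeros, t),
        dlengths_dt=lambda t: zeros + profile.dl_dt(zeros, t),
        fractions=lambda t: zeros + profile.phi(zeros, t),
        dfractions_dt=lambda t: zeros + profile.dphi_dt(zeros, t),
        boundary=boundary,
    )


def _self_consistent_centers(profile: LengthProfile, lam: float, N: int) -> np.ndarray:
    """Cell centres for a static spatial profile (fixed-point iteration)."""
    x = np.arange(N + 1) / N
    for _ in range(500):
        lengths = profile.l(x, 0.0)
        x_new = cell_centers(lengths, lam, N)
        if np.max(np.abs(x_new - x)) < 1e-13:
            return x_new
        x = x_new
    return x


def simulate_discrete(
    params: DimensionlessParameters,
    t_eval: Sequence[float],
    profile: Optional[LengthProfile] = None,
    geometry: Optional[CellFileGeometry] = None,
    n_cells: Optional[int] = None,
    boundary: BoundaryData = BoundaryData(),
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> DiscreteTrajectory:
    """Integrate the discrete model from hormone-free initial conditions.

    ``profile`` selects the file kinematics (default: identical static
    cells with the parameter set's phi); ``geometry`` may instead supply
    explicit per-cell lengths/fractions (e.g. a fitted linear file).
    ``n_cells`` is the number of cell units N (default 1/eps); the
    trajectory reports the N+1 tracked cells.
    """
    N = n_cells if n_cells is not None else round(1.0 / params.eps)
    if geometry is not None:
        N = geometry.n_cells
    system = _system_for_profile(params, N, profile, boundary, geometry)
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval[0] > 0.0:
        t_eval = np.concatenate([[0.0], t_eval])
    sol = system.simulate(t_eval, rtol=rtol, atol=atol)
    return _trajectory(system, sol)


@dataclass
class DivisionTrajectory:
    """Piecewise trajectory of a synchronously dividing file.

    One :class:`DiscreteTrajectory` per inter-division interval; the cell
    count doubles at each event.
    """

    segments: List[DiscreteTrajectory]
    event_times: np.ndarray
    sched: DivisionSchedule

    def cell_counts(self) -> np.ndarray:
        """Number of cell *units* in each inter-division segment."""
        return np.array([seg.n_cells - 1 for seg in self.segments])

    def file_length(self, segment: int, k: int = -1) -> float:
        """Dimensionless domain length (units of L0) at an output point.

        The domain spans centre of cell 1 to centre of the last tracked
        cell: n_units cell units of current length l_d plus walls.
        """
        seg = self.segments[segment]
        t = float(seg.t[k])
        l_d = float(seg.system._l(t)[0])
        n_units = seg.n_cells - 1
        n0 = self.segments[0].n_cells - 1
        lam = seg.params.lam
        return n_units * (l_d + lam) / (n0 * (1.0 + lam))

    def final_state(self) -> FileState:
        seg = self.segments[-1]
        return seg.state(len(seg.t) - 1)


def _divide_state(state: FileState, params: DimensionlessParameters) -> FileState:
    """Split every cell in two, inserting a new apoplast wall between daughters.

    Daughters inherit the mother's c, v and h; the new transverse/corner
    wall compartments between the daughters start at the quasi-static
    value P_a * c_mother.  The hormone content of the new walls is the
    only budget error of the event, O(lam * c).

    T tracked cells (N = T-1 units) become 2T-1: both daughters of cells
    1..T-1 plus the first daughter of the end cell T, whose centre is the
    new domain end (its second half is restored by the mirror ghost).
    """
    T = state.n_cells
    c = np.repeat(state.c, 2)[: 2 * T - 1]
    v = np.repeat(state.v, 2)[: 2 * T - 1]
    h = np.repeat(state.h, 2)[: 2 * T - 1]
    f = np.empty(2 * T - 1)
    g = np.empty(2 * T - 1)
    # wall j sits between new cells j and j+1: even j -> new wall inside
    # old cell j/2, odd j -> old cell j//2's downstream wall
    f[0::2] = params.ratio_a * state.c
    g[0::2] = params.ratio_a * state.c
    f[1::2] = state.f[: T - 1]
    g[1::2] = state.g[: T - 1]
    return FileState(t=state.t, c=c, v=v, f=f, g=g, h=h)


def simulate_with_division(
    params: DimensionlessParameters,
    sched: DivisionSchedule,
    n_events: int,
    initial_n: int = 2,
    points_per_segment: int = 9,
    final_fraction: float = 0.5,
    boundary: BoundaryData = BoundaryData(),
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> DivisionTrajectory:
    """Simulate exponential growth with synchronous divisions at t = nT.

    All cells (including the upstream boundary cell) grow and divide
    identically; every event doubles the cell count and re-initialises the
    state per the daughter-inheritance rule.  phi is held constant
    (meristem-like growth).  After the last event the run continues for
    ``final_fraction`` of an inter-division period.
    """
    lam = params.lam
    T_div = sched.T_div
    mu = sched.mu
    segments: List[DiscreteTrajectory] = []
    event_times = T_div * np.arange(1, n_events + 1)
    n_tracked = initial_n + 1
    carried: Optional[FileState] = None

    for k in range(n_events + 1):
        t0 = k * T_div
        t1 = (k + 1) * T_div if k < n_events else (k + final_fraction) * T_div

        def l_fun(t, _n=k, _T=n_tracked):
            val = (1.0 - lam * (1.0 - 2.0 ** (-_n))) * np.exp(mu * (t - T_div * _n))
            return np.full(_T + 1, val)

        def dl_fun(t, _n=k, _T=n_tracked):
            val = (1.0 - lam * (1.0 - 2.0 ** (-_n))) * np.exp(mu * (t - T_div * _n))
            return np.full(_T + 1, mu * val)

        system = CellFileSystem(
            params,
            n_tracked,
            lengths=l_fun,
            dlengths_dt=dl_fun,
            fractions=np.full(n_tracked + 1, params.phi),
            boundary=boundary,
        )
        t_eval = np.linspace(t0, t1, points_per_segment)
        if carried is None:
            y0 = np.zeros(system.n_state)
        else:
            carried.t = t0
            y0 = system.pack(carried)
        sol = system.simulate(t_eval, y0=y0, rtol=rtol, atol=atol)
        segments.append(_trajectory(system, sol))
        if k < n_events:
            end = segments[-1].state(points_per_segment - 1)
            carried = _divide_state(end, params)
            n_tracked = carried.n_cells
    return DivisionTrajectory(segments=segments, event_times=event_times, sched=sched)
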