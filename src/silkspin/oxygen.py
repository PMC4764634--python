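"""Transient oxygen transport through a wound-dressing + skin bilayer.

Depth-resolved 1-D model: oxygen diffuses through the dressing
(no consumption),

    dc/dt = D_wd d2c/dx2,                 0 < x < L1,

and diffuses while being consumed by cells in the skin,

    dc/dt = D_skin d2c/dx2 - R(c),        L1 < x < L1 + L2,

with Michaelis-Menten kinetics R(c) = vm*c/(km + c) or its first-order
limit R(c) = k_spec*c (c << km).  Boundary conditions: c = C_atm at the
dressing surface (x = 0), zero flux at the bottom of the skin, and flux
continuity D_wd*dc/dx = D_skin*dc/dx at the layer interface.  Lateral
boundaries are zero-flux, which makes the problem one-dimensional in
depth.

Discretization: node-centered finite volumes with a node pinned at the
interface, backward-Euler time stepping (unconditionally stable), and a
Newton solve of the nonlinear sink each step with an analytic tridiagonal
Jacobian.  The finite-volume flux balance enforces interface flux
continuity exactly at steady state.

Defaults follow the silk-mat wound-dressing scenario: D = 2.54e-5 cm^2/s
for both layers (the electrospun mat is not a diffusion barrier), a
specific consumption rate of 3.33e-5 1/s, a ~100 um mat over 2 mm of
skin, atmospheric boundary concentration 0.2 (concentration units are
arbitrary: the first-order problem is linear in c).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "OxygenSystem",
    "GridSpec",
    "OxygenProfile",
    "solve_oxygen",
    "solve_to_steady",
    "steady_state_first_order_oracle",
    "interface_flux_residual",
    "min_concentration",
    "OxygenSolverError",
]


class OxygenSolverError(RuntimeError):
    """Newton non-convergence or an invariant-violating numerical state."""


@dataclass(frozen=True)
class OxygenSystem:
    """Bilayer geometry, diffusivities, kinetics and boundary data.

    Lengths in cm, diffusivities in cm^2/s, rates in 1/s (first-order) or
    concentration/s (``vm``); concentrations share the units of
    ``C_atm``.
    """

    L1: float = 0.01          # dressing thickness, cm (~100 um mat)
    L2: float = 0.2           # skin thickness, cm
    D_wd: float = 2.54e-5     # dressing diffusivity, cm^2/s
    D_skin: float = 2.54e-5   # skin diffusivity, cm^2/s
    C_atm: float = 0.2        # surface oxygen concentration
    kinetics_mode: str = "first_order"  # or "michaelis_menten"
    k_spec: float = 3.33e-5   # 1/s, first-order specific consumption
    vm: float | None = None   # max consumption rate, conc/s (MM mode)
    km: float | None = None   # half-saturation concentration (MM mode)

    def __post_init__(self) -> None:
        for name in ("L1", "L2", "D_wd", "D_skin", "C_atm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.kinetics_mode == "first_order":
            if self.k_spec < 0:
                raise ValueError("k_spec must be >= 0 in first_order mode (0 = no sink)")
        elif self.kinetics_mode == "michaelis_menten":
            if self.vm is None or self.km is None or self.vm < 0 or self.km <= 0:
                raise ValueError("michaelis_menten mode requires vm >= 0 and km > 0")
        else:
            raise ValueError(f"unknown kinetics_mode {self.kinetics_mode!r}")

    def sink(self, c: np.ndarray) -> np.ndarray:
        if self.kinetics_mode == "first_order":
            return self.k_spec * c
        return self.vm * c / (self.km + c)

    def sink_derivative(self, c: np.ndarray) -> np.ndarray:
        if self.kinetics_mode == "first_order":
            return np.full_like(c, self.k_spec)
        return self.vm * self.km / (self.km + c) ** 2


@dataclass(frozen=True)
class GridSpec:
    """Space-time discretization: ``nx`` nodes over [0, L1+L2] with one
    pinned at the interface, backward-Euler step ``dt``."""

    nx: int = 201
    dt: float = 60.0          # s
    t_end: float = 86400.0    # s (1 day)
    newton_tol: float = 1e-10  # relative to C_atm, on the Newton update
    newton_max_iter: int = 50

    def __post_init__(self) -> None:
        if self.nx < 5:
            raise ValueError("nx must be >= 5")
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be > 0")
        if self.newton_tol <= 0 or self.newton_max_iter < 1:
            raise ValueError("newton_tol > 0 and newton_max_iter >= 1 required")


@dataclass(frozen=True)
class OxygenProfile:
    """Space-time oxygen concentration field; x = 0 is the dressing
    surface, times in seconds, C indexed (time, space)."""

    x: np.ndarray
    times: np.ndarray
    C: np.ndarray
    interface_index: int

    def at_time(self, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.times - t)))
        return self.C[i]


def _build_grid(system: OxygenSystem, nx: int):
    """Node positions with one node exactly at x = L1, plus per-node
    volumes, face conductances and skin reaction volumes."""
    total = system.L1 + system.L2
    n1 = int(round((nx - 1) * system.L1 / total))
    n1 = min(max(n1, 1), nx - 2)  # >= 2 nodes in each layer
    h1 = system.L1 / n1
    h2 = system.L2 / (nx - 1 - n1)
    x = np.concatenate([
        np.linspace(0.0, system.L1, n1 + 1),
        system.L1 + h2 * np.arange(1, nx - n1),
    ])
    vol = np.empty(nx)
    vol[0] = h1 / 2
    vol[1:n1] = h1
    vol[n1] = (h1 + h2) / 2
    vol[n1 + 1 : nx - 1] = h2
    vol[nx - 1] = h2 / 2
    cond = np.empty(nx - 1)  # face conductance D/h between i and i+1
    cond[:n1] = system.D_wd / h1
    cond[n1:] = system.D_skin / h2
    rvol = np.zeros(nx)      # portion of each volume subject to consumption
    rvol[n1] = h2 / 2
    rvol[n1 + 1 : nx - 1] = h2
    rvol[nx - 1] = h2 / 2
    return x, vol, cond, rvol, n1


def _step_residual(c, c_old, system, vol, cond, rvol, dt):
    nx = c.size
    flux_in = np.zeros(nx)
    flux_in[1:] += cond * (c[:-1] - c[1:])
    flux_in[:-1] += cond * (c[1:] - c[:-1])
    resid = vol * (c - c_old) / dt - flux_in + rvol * system.sink(c)
    resid[0] = c[0] - system.C_atm
    return resid


def _backward_euler_step(c_old, system, grid, vol, cond, rvol, dt, step_index):
    """One implicit step solved by damped Newton with a tridiagonal
    Jacobian.  Step halving guards the stiff Michaelis-Menten regime
    (km much smaller than the ambient concentration)."""
    nx = c_old.size
    c = c_old.copy()
    c[0] = system.C_atm
    resid = _step_residual(c, c_old, system, vol, cond, rvol, dt)
    for _ in range(grid.newton_max_iter):
        diag = vol / dt + rvol * system.sink_derivative(c)
        diag[1:] += cond
        diag[:-1] += cond
        lower = -cond.copy()
        upper = -cond.copy()
        diag[0], upper[0] = 1.0, 0.0
        ab = np.zeros((3, nx))
        ab[0, 1:] = upper
        ab[1, :] = diag
        ab[2, :-1] = lower
        delta = solve_banded((1, 1), ab, resid)
        norm = float(np.max(np.abs(resid)))
        scale = 1.0
        for _halving in range(30):
            trial = c - scale * delta
            trial_resid = _step_residual(trial, c_old, system, vol, cond, rvol, dt)
            if float(np.max(np.abs(trial_resid))) < norm or scale < 1e-6:
                break
            scale *= 0.5
        c, resid = trial, trial_resid
        if np.max(np.abs(delta)) <= grid.newton_tol * system.C_atm:
            break
    else:
        raise OxygenSolverError(
            f"Newton failed to converge at step {step_index} "
            f"(residual {np.max(np.abs(resid)):.3e})"
        )
    return c


def _advance(c_old, system, grid, vol, cond, rvol, dt, step_index, depth=0):
    """Take one backward-Euler step of size dt, recursively halving the
    step when Newton stalls (strongly saturated Michaelis-Menten sinks
    make the residual non-smooth near c = 0)."""
    try:
        return _backward_euler_step(c_old, system, grid, vol, cond, rvol, dt, step_index)
    except OxygenSolverError:
        if depth >= 12:
            raise
        half = _advance(c_old, system, grid, vol, cond, rvol, dt / 2, step_index,
                        depth + 1)
        return _advance(half, system, grid, vol, cond, rvol, dt / 2, step_index,
                        depth + 1)


def _check_bounds(c, system, step_index):
    tol = 1e-6 * system.C_atm
    if np.min(c) < -tol or np.max(c) > system.C_atm + tol:
        raise OxygenSolverError(
            f"concentration left [0, C_atm] at step {step_index}: "
            f"range [{np.min(c):.3e}, {np.max(c):.3e}]"
        )


def solve_oxygen(system: OxygenSystem, grid: GridSpec, initial=0.0) -> OxygenProfile:
    """Integrate the bilayer transport problem to ``grid.t_end``.

    ``initial`` is a scalar or per-node field in [0, C_atm] describing
    the oxygen concentration when the dressing is first applied (default:
    anoxic, C = 0 below the surface).  Returns the full space-time field
    including t = 0.
    """
    x, vol, cond, rvol, n1 = _build_grid(system, grid.nx)
    c = np.broadcast_to(np.asarray(initial, dtype=float), x.shape).copy()
    if np.min(c) < 0 or np.max(c) > system.C_atm * (1 + 1e-12):
        raise ValueError("initial condition must lie within [0, C_atm]")
    n_steps = int(np.ceil(grid.t_end / grid.dt))
    times = [0.0]
    fields = [c.copy()]
    t = 0.0
    for step in range(1, n_steps + 1):
        dt = min(grid.dt, grid.t_end - t)
        c = _advance(c, system, grid, vol, cond, rvol, dt, step)
        _check_bounds(c, system, step)
        t += dt
        times.append(t)
        fields.append(c.copy())
    return OxygenProfile(
        x=x, times=np.array(times), C=np.array(fields), interface_index=n1
    )


def solve_to_steady(
    system: OxygenSystem,
    grid: GridSpec,
    initial=0.0,
    rate_tol: float = 1e-12,
    max_steps: int = 500,
):
    """March to steady state with geometrically growing time steps.

    Stops when the rate of change max|dC/dt| falls below
    ``rate_tol * C_atm`` per second (backward Euler is unconditionally
    stable, so the step may grow without bound).  Returns (x, C_steady,
    interface_index).
    """
    x, vol, cond, rvol, n1 = _build_grid(system, grid.nx)
    c = np.broadcast_to(np.asarray(initial, dtype=float), x.shape).copy()
    dt = grid.dt
    for step in range(1, max_steps + 1):
        c_new = _advance(c, system, grid, vol, cond, rvol, dt, step)
        _check_bounds(c_new, system, step)
        rate = np.max(np.abs(c_new - c)) / dt
        c = c_new
        if rate < rate_tol * system.C_atm:
            return x, c, n1
        dt = min(dt * 2.0, 1e10)
    raise OxygenSolverError(
        f"steady state not reached in {max_steps} steps (rate {rate:.3e})"
    )


def steady_state_first_order_oracle(system: OxygenSystem, x) -> np.ndarray:
    """Closed-form steady profile for first-order consumption.

    In the dressing the steady profile is linear (constant flux q); in
    the skin it is a cosh with decay length sqrt(D_skin/k_spec) and zero
    slope at the bottom:

        C(x) = B*cosh(phi*(L1+L2-x)),  phi = sqrt(k_spec/D_skin),

    with B fixed by matching concentration and flux at the interface.
    Used as the independent verification oracle for the time stepper.
    """
    if system.kinetics_mode != "first_order":
        raise ValueError("oracle applies to first_order kinetics only")
    x = np.asarray(x, dtype=float)
    phi = np.sqrt(system.k_spec / system.D_skin)
    L = system.L1 + system.L2
    ch, sh = np.cosh(phi * system.L2), np.sinh(phi * system.L2)
    B = system.C_atm / (ch + system.D_skin * phi * system.L1 / system.D_wd * sh)
    q = system.D_skin * phi * sh * B  # steady flux through the dressing
    dressing = system.C_atm - q * x / system.D_wd
    skin = B * np.cosh(phi * (L - x))
    return np.where(x <= system.L1, dressing, skin)


def _one_sided_gradient(c: np.ndarray, x: np.ndarray, i: int, side: str) -> float:
    """Second-order one-sided dC/dx at node i (three-point where possible)."""
    if side == "above":
        if i >= 2:
            h = x[i] - x[i - 1]
            return float((3 * c[i] - 4 * c[i - 1] + c[i - 2]) / (2 * h))
        return float((c[i] - c[i - 1]) / (x[i] - x[i - 1]))
    if i + 2 < c.size:
        h = x[i + 1] - x[i]
        return float((-3 * c[i] + 4 * c[i + 1] - c[i + 2]) / (2 * h))
    return float((c[i + 1] - c[i]) / (x[i + 1] - x[i]))


def interface_flux_residual(profile: OxygenProfile, system: OxygenSystem) -> np.ndarray:
    """Relative mismatch of D*dC/dx across the interface, per saved time.

    One-sided second-order differences approximate the gradient on each
    side; the residual is the absolute flux difference normalized by the
    larger flux magnitude (defined as 0 for a uniform field).
    """
    i = profile.interface_index
    span = profile.x[-1] - profile.x[0]
    # fluxes below this scale are numerically zero (uniform fields)
    floor = 1e-9 * max(system.D_wd, system.D_skin) * np.max(np.abs(profile.C)) / span
    out = np.empty(profile.times.size)
    for k, c in enumerate(profile.C):
        g_above = system.D_wd * _one_sided_gradient(c, profile.x, i, "above")
        g_below = system.D_skin * _one_sided_gradient(c, profile.x, i, "below")
        denom = max(abs(g_above), abs(g_below))
        out[k] = 0.0 if denom <= floor else abs(g_above - g_below) / denom
    return out


def min_concentration(
    profile: OxygenProfile, after_time: float = 0.0
) -> tuple[float, float, float]:
    """Global minimum of the field and where/when it occurs:
    (value, x_cm, time_s).

    ``after_time`` restricts the search to saved times >= that value —
    useful to ask about the developed profile rather than the initial
    transient (an anoxic start is minimal everywhere at t = 0).
    """
    if profile.C.size == 0:
        raise ValueError("empty profile")
    mask = profile.times >= after_time
    if not np.any(mask):
        raise ValueError(f"no saved times at or after t = {after_time}")
    sub = profile.C[mask]
    k, i = np.unravel_index(np.argmin(sub), sub.shape)
    return float(sub[k, i]), float(profile.x[i]), float(profile.times[mask][k])
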