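"""D3Q19 BGK lattice-Boltzmann solver with forcing and pressure driving.

The collision is single-relaxation-time with a per-site relaxation-time map
(tau_map) so the cell interior can carry a different viscosity from the
suspending fluid.  Forcing uses the second-order Guo scheme with the
half-force velocity shift; walls are half-way bounce-back; the flow is
driven by a constant density (pressure) difference between equilibrium
inlet/outlet layers, calibrated cell-free to the pump flow rate.  Constant
head rather than imposed flux is essential: an entering cell occludes the
constriction and the flow rate must be free to drop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import EX, EY, EZ, W, OPP  # re-export for tests/inspection
from .geometry import DeviceGeometry
from .units import LatticeUnits

#: D3Q19 velocity vectors, shape (19, 3), integer components.
E = np.stack([_kernels.EXI, _kernels.EYI, _kernels.EZI], axis=1)

MAX_LATTICE_SPEED = 0.3  # |u| beyond this is flagged as numerical blow-up


class InstabilityError(RuntimeError):
    pass


class CalibrationError(RuntimeError):
    pass


def equilibrium(rho, u):
    """Second-order low-Mach equilibrium distribution.

    Parameters are broadcastable: ``rho`` (...,), ``u`` (..., 3).  Returns
    populations with a leading axis of length 19.  The zeroth and first
    moments match ``rho`` and ``rho*u`` exactly.
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    eu = np.tensordot(E.astype(float), np.moveaxis(u, -1, 0), axes=(1, 0))
    usq = np.sum(u * u, axis=-1)
    return W.reshape((19,) + (1,) * rho.ndim) * rho * (
        1.0 + 3.0 * eu + 4.5 * eu**2 - 1.5 * usq)


@dataclass
class LatticeState:
    """Distributions plus macroscopic fields on the device lattice."""

    n: np.ndarray          # (19, nx, ny, nz)
    rho: np.ndarray        # (nx, ny, nz)
    u: np.ndarray          # (3, nx, ny, nz)
    tau_map: np.ndarray    # (nx, ny, nz)
    force: np.ndarray      # (3, nx, ny, nz) body-force density
    scratch: np.ndarray = field(repr=False, default=None)
    time_step: int = 0

    @classmethod
    def initialize(cls, shape: tuple[int, int, int], tau: float,
                   rho0: float = 1.0) -> "LatticeState":
        nx, ny, nz = shape
        rho = np.full(shape, rho0)
        u = np.zeros((3,) + shape)
        n = np.ascontiguousarray(
            W[:, None, None, None] * rho[None] * np.ones((19,) + shape))
        return cls(n=n, rho=rho, u=u,
                   tau_map=np.full(shape, tau),
                   force=np.zeros((3,) + shape),
                   scratch=np.empty_like(n))


def step(state: LatticeState, geometry_or_solid,
         driving: tuple[float, float] | None = None,
         periodic_x: bool = False,
         check_every: int = 0) -> LatticeState:
    """Advance one collide-force-stream cycle (in place; returns state).

    ``driving`` is an (rho_in, rho_out) pair applied at the open x ends;
    ``periodic_x`` wraps the x axis instead (used for validation boxes).
    When ``check_every`` > 0, a low-Mach stability guard runs every that
    many steps and raises :class:`InstabilityError` on blow-up.
    """
    solid = (geometry_or_solid.solid
             if isinstance(geometry_or_solid, DeviceGeometry)
             else geometry_or_solid)
    _kernels.macro_collide(state.n, state.rho, state.u, state.tau_map,
                           state.force, solid)
    _kernels.stream(state.n, state.scratch, solid, periodic_x)
    state.n, state.scratch = state.scratch, state.n
    if driving is not None:
        _kernels.pressure_bc(state.n, solid, driving[0], driving[1])
    state.time_step += 1
    if check_every and state.time_step % check_every == 0:
        assert_stable(state, solid)
    return state


def assert_stable(state: LatticeState, solid: np.ndarray) -> None:
    speed = np.sqrt(np.sum(state.u**2, axis=0))
    speed[solid] = 0.0
    m = float(speed.max())
    if not np.isfinite(m) or m > MAX_LATTICE_SPEED:
        site = np.unravel_index(np.argmax(np.nan_to_num(speed, nan=np.inf)),
                                speed.shape)
        raise InstabilityError(
            f"lattice velocity |u|={m:.3g} at site {site} exceeds "
            f"{MAX_LATTICE_SPEED} at step {state.time_step}; the run is "
            "numerically unstable (reduce driving or time step)")


def measure_flow_rate(state: LatticeState, geometry: DeviceGeometry,
                      x_plane: float, units: LatticeUnits) -> float:
    """Volumetric flow rate (uL/h) through the transverse plane at x (um)."""
    i = int(math.floor(x_plane / geometry.dx))
    nx = geometry.shape[0]
    if not (0 <= i < nx):
        raise ValueError(f"plane x={x_plane} um outside domain")
    fluid = geometry.fluid[i]
    if not fluid.any():
        raise ValueError(f"plane x={x_plane} um is fully solid")
    q_lat = float(np.sum(state.u[0, i][fluid]))
    return units.flow_to_physical(q_lat)


def run_to_steady(state: LatticeState, geometry: DeviceGeometry,
                  driving: tuple[float, float], units: LatticeUnits,
                  x_plane: float | None = None,
                  tol_per_step: float = 1e-8, chunk: int = 200,
                  max_steps: int = 400_000) -> float:
    """Run until the monitored flow rate is steady; returns the flow rate.

    Steadiness: relative flow-rate change per step below ``tol_per_step``.
    """
    if x_plane is None:
        x_plane = (geometry.shape[0] - 2) * geometry.dx
    q_prev = None
    steps = 0
    while steps < max_steps:
        for _ in range(chunk):
            step(state, geometry, driving=driving)
        steps += chunk
        q = measure_flow_rate(state, geometry, x_plane, units)
        assert_stable(state, geometry.solid)
        if q_prev is not None and abs(q) > 0:
            if abs(q - q_prev) / (abs(q) * chunk) < tol_per_step:
                return q
        q_prev = q
    raise CalibrationError(
        f"flow did not reach steady state within {max_steps} steps")


def calibrate_driving(geometry: DeviceGeometry, units: LatticeUnits,
                      target_q: float,
                      drho_guess: float = 2e-3,
                      rel_tol: float = 0.01,
                      max_iter: int = 8,
                      steady_kwargs: dict | None = None,
                      ) -> tuple[float, float]:
    """Find the inlet/outlet density difference giving the target flow rate.

    Returns ``(drho, q)`` with ``q`` the achieved cell-free steady flow rate
    (uL/h), within ``rel_tol`` of ``target_q``.  In the Stokes regime the
    flow rate is linear in the head difference, so a proportional update
    (secant through the origin) converges in one or two iterations.
    """
    if target_q == 0:
        return 0.0, 0.0
    steady_kwargs = steady_kwargs or {}
    drho = drho_guess * math.copysign(1.0, target_q)
    for _ in range(max_iter):
        state = LatticeState.initialize(geometry.shape, units.tau_fluid)
        state.tau_map[:] = units.tau_fluid
        q = run_to_steady(state, geometry,
                          (1.0 + drho / 2, 1.0 - drho / 2), units,
                          **steady_kwargs)
        if q == 0:
            raise CalibrationError("zero flow at nonzero driving")
        if abs(q - target_q) / abs(target_q) < rel_tol:
            return drho, q
        drho *= target_q / q
    raise CalibrationError(
        f"driving calibration did not converge to {target_q} uL/h "
        f"within {max_iter} iterations (last {q:.3g} uL/h)")


def analytic_duct_velocity(y, z, a, b, g, nu, nterms: int = 100):
    """Steady axial velocity of pressure-driven flow in a rectangular duct.

    Classic Fourier-series solution for a duct spanning |y| <= a, |z| <= b,
    driven by a constant axial body acceleration ``g`` (equivalently a
    pressure gradient -dp/dx = rho*g) in a fluid of kinematic viscosity
    ``nu``:

        u(y,z) = (16 a^2 g / (nu pi^3)) * sum_{n odd} (-1)^((n-1)/2)/n^3 *
                 [1 - cosh(n pi z / 2a)/cosh(n pi b / 2a)] cos(n pi y / 2a)

    Truncated at ``nterms`` odd terms.  Units are whatever consistent set
    the caller uses (lattice units in the validation tests).
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    u = np.zeros(np.broadcast(y, z).shape)
    pref = 16.0 * a**2 * g / (nu * math.pi**3)
    for m in range(nterms):
        nodd = 2 * m + 1
        sgn = -1.0 if (m % 2) else 1.0
        arg = nodd * math.pi / (2.0 * a)
        u = u + sgn / nodd**3 * (
            1.0 - np.cosh(arg * z) / math.cosh(arg * b)) * np.cos(arg * y)
    return pref * u
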