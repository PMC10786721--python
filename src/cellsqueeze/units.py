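"""Physical constants, run configuration, and physical<->lattice unit conversion.

All internal computation happens in lattice units (dx = dt = rho_fluid = 1);
conversion to and from physical units (um, us, kg/m^3, uL/h) occurs only at
I/O boundaries.  The conversion factors live in :class:`LatticeUnits` so that
mixed-unit force bugs cannot arise inside the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from scipy.constants import k as BOLTZMANN  # J/K


class UnitError(ValueError):
    """Raised when a configuration produces an unusable lattice mapping."""


@dataclass
class SimulationConfig:
    """Run configuration in physical units.

    Parameters
    ----------
    dt : float
        Time step in microseconds.
    dx : float
        Lattice spacing in micrometres.
    nu : float
        Fluid kinematic viscosity in m^2/s.
    rho : float
        Fluid density in kg/m^3.
    d_cut : float
        Cell-wall repulsion activation distance in micrometres.
    kappa_rep : float
        Dimensionless repulsion scale coefficient.
    temperature : float
        Temperature in kelvin.  It enters only through the thermal energy
        k_B*T that scales the membrane moduli; the identified dimensionless
        moduli absorb the choice, but it must be pinned for parameter values
        to be meaningful, so it is recorded in every output header.
    flow_rate : float
        Nominal volumetric flow rate in uL/h.
    seed : int
        RNG seed recorded in run manifests.
    """

    dt: float = 0.01          # us
    dx: float = 1.0           # um
    nu: float = 1.1e-6        # m^2/s
    rho: float = 1025.0       # kg/m^3
    d_cut: float = 0.8        # um
    kappa_rep: float = 0.004  # dimensionless
    temperature: float = 300.0  # K
    flow_rate: float = 20.0   # uL/h
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dt", "dx", "nu", "rho", "d_cut", "temperature"):
            if getattr(self, name) <= 0:
                raise UnitError(f"SimulationConfig.{name} must be positive, "
                                f"got {getattr(self, name)!r}")
        if self.kappa_rep < 0:
            raise UnitError("kappa_rep must be non-negative")

    def asdict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LatticeUnits:
    """Conversion factors between physical and lattice units.

    One lattice length unit is ``dx`` um, one lattice time unit is ``dt`` us,
    and the lattice rest density 1 corresponds to the physical fluid density.
    """

    dx: float                 # um per lattice length
    dt: float                 # us per lattice time
    tau_fluid: float          # BGK relaxation time of the suspending fluid
    nu_lattice: float         # kinematic viscosity in lattice units
    velocity_scale: float     # m/s per lattice velocity (dx/dt)
    density_scale: float      # kg/m^3 per lattice density
    force_scale: float        # N per lattice force
    energy_scale: float       # J per lattice energy
    kBT_lattice: float        # thermal energy in lattice units
    flow_scale: float         # uL/h per lattice volumetric flux

    # -- physical -> lattice -------------------------------------------------
    def length_to_lattice(self, um: float) -> float:
        return um / self.dx

    def time_to_lattice(self, us: float) -> float:
        return us / self.dt

    def velocity_to_lattice(self, m_per_s: float) -> float:
        return m_per_s / self.velocity_scale

    # -- lattice -> physical -------------------------------------------------
    def length_to_physical(self, lat: float) -> float:
        return lat * self.dx

    def time_to_physical_ms(self, lat: float) -> float:
        return lat * self.dt * 1e-3  # us -> ms

    def flow_to_physical(self, q_lat: float) -> float:
        """Lattice volumetric flux (dx^3/dt) -> uL/h."""
        return q_lat * self.flow_scale


def to_lattice(config: SimulationConfig) -> LatticeUnits:
    """Build the lattice-unit bridge from a physical configuration.

    The BGK relation ties the lattice viscosity to the relaxation time,
    tau = 3*nu_lat + 1/2 with nu_lat = nu*dt/dx^2 (in consistent units).
    Configurations whose tau falls outside (0.5, 2) are rejected: tau <= 0.5
    gives a non-positive viscosity (unconditionally unstable), and tau >= 2
    degrades the accuracy of the bounce-back wall location.
    """
    dx_m = config.dx * 1e-6
    dt_s = config.dt * 1e-6
    nu_lat = config.nu * dt_s / dx_m**2
    tau = 3.0 * nu_lat + 0.5
    if tau <= 0.5:
        raise UnitError(
            f"lattice relaxation time tau={tau:.4f} <= 0.5: the implied "
            "lattice viscosity is non-positive and the BGK collision is "
            "unstable; increase dt or nu, or decrease dx")
    if tau >= 2.0:
        raise UnitError(
            f"lattice relaxation time tau={tau:.4f} >= 2: over-relaxed "
            "regime with inaccurate wall placement; decrease dt or nu, "
            "or increase dx")
    mass_scale = config.rho * dx_m**3
    force_scale = mass_scale * dx_m / dt_s**2
    energy_scale = force_scale * dx_m
    # dx^3/dt in um^3/us = 1e-12 m^3/s; 1 uL/h = 1e-9/3600 m^3/s
    flow_scale = (config.dx**3 / config.dt) * 3.6
    return LatticeUnits(
        dx=config.dx,
        dt=config.dt,
        tau_fluid=tau,
        nu_lattice=nu_lat,
        velocity_scale=dx_m / dt_s,
        density_scale=config.rho,
        force_scale=force_scale,
        energy_scale=energy_scale,
        kBT_lattice=BOLTZMANN * config.temperature / energy_scale,
        flow_scale=flow_scale,
    )


def interior_tau(units: LatticeUnits, vr: float) -> float:
    """Relaxation time for the cell-interior fluid.

    The interior viscosity is VR times the suspending-fluid viscosity, so
    tau_in = 3*VR*nu_lat + 1/2.  VR = 1 recovers the exterior tau exactly.
    """
    if vr <= 0:
        raise UnitError(f"viscosity ratio must be positive, got {vr!r}")
    return 3.0 * vr * units.nu_lattice + 0.5
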