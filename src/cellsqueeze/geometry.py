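"""Voxelized numerical domains of the constricted microfluidic devices.

Each device is a straight channel of rectangular cross-section with a single
constriction: a wide upstream segment (3x the constriction width by default),
a 45-degree tapered entrance, and the narrow constricted segment.  The domain
is voxelized on the fluid lattice: a site is fluid when its voxel centre lies
strictly inside the fluid region (half-open intervals along each axis), which
makes voxel counts reproducible.  Lattice indices are 0-based; the physical
position of site ``i`` along an axis is ``(i + 0.5) * dx``.

The flow axis is x; the constriction width is measured along y and the
channel height along z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .units import LatticeUnits


class GeometryError(ValueError):
    pass


@dataclass
class DeviceSpec:
    """Physical description of one constricted device (all lengths in um)."""

    constriction_width: float
    constriction_length: float = 40.0
    height: float = 28.0
    taper_angle: float = 45.0      # degrees, per side
    upstream_width: float | None = None   # default: 3x constriction width
    upstream_length: float = 40.0
    downstream_length: float = 0.0  # extra wide section after the constriction

    def __post_init__(self) -> None:
        if self.upstream_width is None:
            self.upstream_width = 3.0 * self.constriction_width
        if self.constriction_width <= 0 or self.height <= 0:
            raise GeometryError("device dimensions must be positive")
        if self.upstream_width < self.constriction_width:
            raise GeometryError("upstream width must be >= constriction width")
        if not (0 < self.taper_angle < 90):
            raise GeometryError("taper angle must lie in (0, 90) degrees")

    @property
    def taper_length(self) -> float:
        """Axial extent of the tapered entrance (um)."""
        half_step = 0.5 * (self.upstream_width - self.constriction_width)
        return half_step / math.tan(math.radians(self.taper_angle))


#: The three fabricated devices: 8/10/12 um constrictions, 28 um tall.
DEVICE_PRESETS: dict[str, DeviceSpec] = {
    "device1": DeviceSpec(constriction_width=8.0),
    "device2": DeviceSpec(constriction_width=10.0),
    "device3": DeviceSpec(constriction_width=12.0),
}


def device_preset(name: str) -> DeviceSpec:
    try:
        spec = DEVICE_PRESETS[name]
    except KeyError:
        raise GeometryError(
            f"unknown device preset {name!r}; valid presets: "
            + ", ".join(sorted(DEVICE_PRESETS))) from None
    return DeviceSpec(**{k: getattr(spec, k) for k in (
        "constriction_width", "constriction_length", "height", "taper_angle",
        "upstream_width", "upstream_length", "downstream_length")})


@dataclass
class DeviceGeometry:
    """Voxelized device with constriction landmarks.

    Attributes
    ----------
    solid : (Nx, Ny, Nz) bool array, True at wall sites.
    wall_sites : (M, 3) int array of wall-surface lattice sites (solid sites
        with at least one fluid 6-neighbour), used for cell-wall repulsion.
    x_entrance : axial position (um) of the constriction entrance plane
        (the downstream end of the taper).
    x_taper_start : axial position (um) where the taper begins.
    """

    spec: DeviceSpec
    dx: float
    solid: np.ndarray
    wall_sites: np.ndarray
    x_entrance: float
    x_taper_start: float
    flow_axis: str = "x"

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.solid.shape

    @property
    def fluid(self) -> np.ndarray:
        return ~self.solid


def _width_profile(spec: DeviceSpec, x: np.ndarray) -> np.ndarray:
    """Open channel width (um) as a function of axial position (um)."""
    x0 = spec.upstream_length
    x1 = x0 + spec.taper_length
    x2 = x1 + spec.constriction_length
    w = np.empty_like(x)
    w[x < x0] = spec.upstream_width
    in_taper = (x >= x0) & (x < x1)
    frac = (x[in_taper] - x0) / max(spec.taper_length, 1e-300)
    w[in_taper] = spec.upstream_width - frac * (
        spec.upstream_width - spec.constriction_width)
    in_constr = (x >= x1) & (x < x2)
    w[in_constr] = spec.constriction_width
    w[x >= x2] = (spec.upstream_width if spec.downstream_length > 0
                  else spec.constriction_width)
    return w


def build_device(spec: DeviceSpec, units: LatticeUnits) -> DeviceGeometry:
    """Voxelize a device onto the lattice.

    The y extent includes one solid wall layer on each side of the upstream
    width, and similarly in z around the channel height.  The x boundaries
    (inlet/outlet) are open.
    """
    dx = units.dx
    for name, val in (("constriction_width", spec.constriction_width),
                      ("height", spec.height),
                      ("constriction_length", spec.constriction_length),
                      ("upstream_length", spec.upstream_length)):
        if val < 2.0 * dx:
            raise GeometryError(
                f"{name} = {val} um is below the lattice resolution "
                f"(need >= 2*dx = {2*dx} um)")

    length = (spec.upstream_length + spec.taper_length
              + spec.constriction_length + spec.downstream_length)
    nx = int(round(length / dx))
    ny = int(round(spec.upstream_width / dx)) + 2
    nz = int(round(spec.height / dx)) + 2

    xc = (np.arange(nx) + 0.5) * dx
    yc = (np.arange(ny) + 0.5) * dx
    zc = (np.arange(nz) + 0.5) * dx
    y_mid = ny * dx / 2.0
    z_lo, z_hi = dx, dx + spec.height

    w = _width_profile(spec, xc)                      # (nx,)
    half = 0.5 * w
    open_y = np.abs(yc[None, :] - y_mid) < half[:, None] - 1e-12  # (nx, ny)
    open_z = (zc >= z_lo - 1e-12) & (zc < z_hi - 1e-12)           # (nz,)
    fluid = open_y[:, :, None] & open_z[None, None, :]
    solid = ~fluid

    wall_sites = _surface_sites(solid)
    return DeviceGeometry(
        spec=spec,
        dx=dx,
        solid=solid,
        wall_sites=wall_sites,
        x_entrance=spec.upstream_length + spec.taper_length,
        x_taper_start=spec.upstream_length,
    )


def _near_fluid(solid: np.ndarray) -> np.ndarray:
    """Sites with at least one fluid 6-neighbour (no wrap across ends)."""
    fluid = ~solid
    near = np.zeros_like(solid)
    near[:-1] |= fluid[1:]
    near[1:] |= fluid[:-1]
    near[:, :-1] |= fluid[:, 1:]
    near[:, 1:] |= fluid[:, :-1]
    near[:, :, :-1] |= fluid[:, :, 1:]
    near[:, :, 1:] |= fluid[:, :, :-1]
    return near


def _surface_sites(solid: np.ndarray) -> np.ndarray:
    """Solid sites with at least one fluid 6-neighbour."""
    return np.argwhere(solid & _near_fluid(solid))


def open_area(geometry: DeviceGeometry, x: float) -> float:
    """Open cross-sectional area (um^2) of the transverse plane at x (um)."""
    nx = geometry.shape[0]
    i = int(math.floor(x / geometry.dx))
    if not (0 <= i < nx):
        raise GeometryError(f"x = {x} um lies outside the domain "
                            f"[0, {nx * geometry.dx}) um")
    return float(np.count_nonzero(geometry.fluid[i])) * geometry.dx**2
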