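"""Single-cell transit orchestration: placement, time stepping, metrics.

A run proceeds in three phases:

1. the cell-free flow is driven to steady state (the driving head is
   calibrated so the cell-free flow rate matches the pump setting);
2. the cell is inserted on the channel axis, its centroid 1.5 radii
   upstream of the taper start, and the two-way-coupled loop runs:
   fluid step -> velocity interpolation -> vertex advection (forward
   Euler, massless membrane) -> membrane + wall forces -> force spreading;
3. the run terminates at full entry (plus a short post-entry margin so the
   flow-rate recovery is visible), at a time cap, or on instability.

Entry metrics follow the experimental definitions: the entry time starts
when the cell's leading vertex crosses the constriction entrance plane and
ends when its trailing vertex does; the elongation index is the ratio of
the axial cell length at full entry to the undeformed length just before
entry starts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coupling, lbm, membrane
from .geometry import DeviceGeometry, DeviceSpec, build_device, device_preset
from .membrane import CellModelParams, MembraneLimitError
from .units import LatticeUnits, SimulationConfig, interior_tau, to_lattice


@dataclass
class EntryTrace:
    """Time series of one transit attempt (physical units)."""

    time_ms: np.ndarray
    x_centroid_um: np.ndarray
    lead_x_um: np.ndarray     # maximum vertex x
    trail_x_um: np.ndarray    # minimum vertex x
    length_um: np.ndarray
    flow_rate: np.ndarray     # uL/h
    volume_um3: np.ndarray
    complete: bool
    meta: dict = field(default_factory=dict)
    snapshots: list = field(default_factory=list)  # (time_ms, vertices_um)
    #: per-frame maximum nodal force magnitude of each constitutive family
    #: (lattice units), columns link/bending/area/volume; empty unless the
    #: run recorded force histories
    force_maxima: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.time_ms)


@dataclass
class EntryMetrics:
    """Entry time, elongation index, and flow-rate summary of a trace."""

    entry_time_ms: float
    elongation_index: float
    L0_um: float
    L1_um: float
    min_flow_rate: float
    t_start_ms: float
    t_end_ms: float
    no_entry: bool = False


def _resolve_device(device, units: LatticeUnits) -> DeviceGeometry:
    if isinstance(device, DeviceGeometry):
        return device
    if isinstance(device, DeviceSpec):
        return build_device(device, units)
    return build_device(device_preset(device), units)


def run_entry(device, diameter_um: float, params: CellModelParams,
              config: SimulationConfig, *,
              driving: tuple[float, float] | None = None,
              time_cap_ms: float | None = None,
              record_stride: int = 20,
              retag_stride: int = 10,
              post_entry_factor: float = 0.25,
              kernel: coupling.IBMKernel = coupling.PESKIN_4PT,
              mesh_nodes: int = 642,
              snapshot_stride: int = 0,
              record_forces: bool = False,
              max_steps: int = 2_000_000) -> EntryTrace:
    """Simulate one cell's approach and entry into the constriction.

    ``driving`` is the precomputed inlet/outlet density pair; when omitted
    it is calibrated cell-free to ``config.flow_rate``.  Returns a trace
    flagged ``complete`` once the trailing vertex has passed the entrance
    plane (the run continues for ``post_entry_factor`` of the elapsed time
    so the flow-rate recovery is recorded).
    """
    units = to_lattice(config)
    geometry = _resolve_device(device, units)
    spec = geometry.spec
    if not (diameter_um < spec.upstream_width and diameter_um < spec.height):
        raise ValueError(
            f"cell diameter {diameter_um} um does not fit the upstream "
            f"channel ({spec.upstream_width} x {spec.height} um)")

    if driving is None:
        driving, _ = lbm.calibrate_driving(geometry, units, config.flow_rate)
        driving = (1.0 + driving / 2, 1.0 - driving / 2)

    # phase 1: steady cell-free flow
    state = lbm.LatticeState.initialize(geometry.shape, units.tau_fluid)
    lbm.run_to_steady(state, geometry, driving, units)

    # phase 2: insert the cell (lattice units; site i at coordinate i)
    dx = units.dx
    r_lat = diameter_um / dx / 2.0
    mesh = membrane.make_cell_mesh(diameter_um, mesh_nodes)
    mesh = mesh.scaled(1.0 / dx)
    ny, nz = geometry.shape[1], geometry.shape[2]
    center = np.array([
        geometry.x_taper_start / dx - 0.5 - 1.5 * r_lat,
        (ny - 1) / 2.0,
        (nz - 1) / 2.0,
    ])
    mesh = mesh.translated(center)
    X = mesh.vertices.copy()

    kBT = units.kBT_lattice
    tau_in = interior_tau(units, params.VR)
    wall_mask = coupling.wall_surface_mask(geometry.solid)
    d_cut_lat = config.d_cut / dx
    x_entrance_lat = geometry.x_entrance / dx - 0.5
    q_plane = (geometry.shape[0] - 2) * dx

    times, cent, lead, trail, length, qs, vols = ([] for _ in range(7))
    snapshots: list = []
    force_rows: list = []
    entry_step: int | None = None
    complete = False
    cap_steps = (math.inf if time_cap_ms is None
                 else time_cap_ms * 1e3 / config.dt)
    step_idx = 0
    stop_at = math.inf

    def record() -> None:
        t_ms = units.time_to_physical_ms(step_idx)
        times.append(t_ms)
        xs = X[:, 0]
        cent.append((xs.mean() + 0.5) * dx)
        lead.append((xs.max() + 0.5) * dx)
        trail.append((xs.min() + 0.5) * dx)
        length.append((xs.max() - xs.min()) * dx)
        qs.append(lbm.measure_flow_rate(state, geometry, q_plane, units))
        vols.append(membrane.enclosed_volume(X, mesh.faces) * dx**3)
        if snapshot_stride and (len(times) - 1) % snapshot_stride == 0:
            snapshots.append((t_ms, (X + 0.5) * dx))
        if record_forces:
            try:
                force_rows.append([
                    np.linalg.norm(fn(mesh, X, params, kBT), axis=1).max()
                    for fn in (membrane.link_forces,
                               membrane.bending_forces,
                               membrane.area_forces,
                               membrane.volume_force)])
            except MembraneLimitError:
                force_rows.append([math.nan] * 4)

    record()
    while step_idx < max_steps:
        if step_idx % retag_stride == 0:
            inside = coupling.tag_interior_sites(
                _mesh_view(mesh, X), geometry.shape)
            state.tau_map[:] = units.tau_fluid
            state.tau_map[inside & geometry.fluid] = tau_in

        F = membrane.total_forces_fast(mesh, X, params, kBT)
        F += coupling.wall_repulsion(X, wall_mask, d_cut_lat,
                                     config.kappa_rep)
        state.force[:] = 0.0
        coupling.spread_forces(F, X, state.force, kernel)
        lbm.step(state, geometry, driving=driving)
        U = coupling.interpolate_velocity(state.u, X, kernel)
        X += U
        step_idx += 1

        if step_idx % 100 == 0:
            lbm.assert_stable(state, geometry.solid)
        if step_idx % record_stride == 0:
            record()
            if entry_step is None and X[:, 0].min() > x_entrance_lat:
                entry_step = step_idx
                complete = True
                stop_at = step_idx * (1.0 + post_entry_factor) + record_stride
        if step_idx >= stop_at or step_idx >= cap_steps:
            break

    trace = EntryTrace(
        time_ms=np.array(times), x_centroid_um=np.array(cent),
        lead_x_um=np.array(lead), trail_x_um=np.array(trail),
        length_um=np.array(length), flow_rate=np.array(qs),
        volume_um3=np.array(vols), complete=complete,
        snapshots=snapshots,
        force_maxima=(np.array(force_rows) if record_forces else None),
        meta={
            "device": {
                "constriction_width": spec.constriction_width,
                "height": spec.height,
                "upstream_width": spec.upstream_width,
            },
            "diameter_um": diameter_um,
            "params": params.as_array().tolist(),
            "config": config.asdict(),
            "driving": tuple(driving),
            "steps": step_idx,
            "x_entrance_um": geometry.x_entrance,
        })
    return trace


def _mesh_view(mesh: membrane.MembraneMesh, X: np.ndarray):
    """Lightweight view of the mesh at positions X (for interior tagging)."""
    view = mesh.copy()
    view.vertices = X
    return view


def detect_entry(trace: EntryTrace, geometry: DeviceGeometry | float,
                 ) -> EntryMetrics:
    """Extract entry metrics from a trace.

    ``geometry`` may be the device or directly the entrance-plane axial
    position in um.  Crossing instants are found by linear interpolation of
    the extreme-vertex coordinates between recorded frames, the undeformed
    length L0 is taken at the last frame before the entry starts, and L1 at
    the completion instant.  A cell that never starts or never completes
    yields an explicit no-entry result rather than an exception.
    """
    x_ent = (geometry if isinstance(geometry, (int, float))
             else geometry.x_entrance)
    t = trace.time_ms
    no_entry = EntryMetrics(
        entry_time_ms=math.nan, elongation_index=math.nan,
        L0_um=math.nan, L1_um=math.nan, min_flow_rate=math.nan,
        t_start_ms=math.nan, t_end_ms=math.nan, no_entry=True)
    t_start = _first_crossing(t, trace.lead_x_um, x_ent)
    if t_start is None:
        return no_entry
    t_end = _first_crossing(t, trace.trail_x_um, x_ent)
    if t_end is None:
        return no_entry
    before = np.nonzero(t < t_start)[0]
    L0 = trace.length_um[before[-1]] if len(before) else trace.length_um[0]
    L1 = float(np.interp(t_end, t, trace.length_um))
    window = (t >= t_start) & (t <= t_end)
    min_q = float(trace.flow_rate[window].min()) if window.any() else math.nan
    return EntryMetrics(
        entry_time_ms=t_end - t_start,
        elongation_index=L1 / L0,
        L0_um=float(L0), L1_um=L1, min_flow_rate=min_q,
        t_start_ms=t_start, t_end_ms=t_end)


def _first_crossing(t: np.ndarray, x: np.ndarray, level: float):
    """First instant x(t) rises through ``level`` (linear interpolation)."""
    above = x >= level
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    f = (level - x[i - 1]) / (x[i] - x[i - 1])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


def sweep(devices, diameters, params_by_diameter, config: SimulationConfig,
          flow_rates=None, heights=None, **run_kwargs) -> pd.DataFrame:
    """Batch entry runs over device/diameter/flow-rate/height combinations.

    ``params_by_diameter`` maps diameter -> CellModelParams (or a single
    CellModelParams used throughout).  Individual failures are recorded
    per row; the batch continues.
    """
    flow_rates = flow_rates if flow_rates is not None else [config.flow_rate]
    heights = heights if heights is not None else [None]
    rows = []
    for dev, d, q, h in itertools.product(devices, diameters,
                                          flow_rates, heights):
        params = (params_by_diameter[d]
                  if isinstance(params_by_diameter, dict)
                  else params_by_diameter)
        cfg = SimulationConfig(**{**config.asdict(), "flow_rate": q})
        spec = dev if isinstance(dev, DeviceSpec) else device_preset(dev)
        if h is not None:
            spec = DeviceSpec(**{**{k: getattr(spec, k) for k in (
                "constriction_width", "constriction_length", "height",
                "taper_angle", "upstream_width", "upstream_length",
                "downstream_length")}, "height": h})
        row = {"device_width_um": spec.constriction_width,
               "height_um": spec.height, "diameter_um": d,
               "flow_rate_uL_h": q}
        try:
            trace = run_entry(spec, d, params, cfg, **run_kwargs)
            m = detect_entry(trace, build_device(spec, to_lattice(cfg)))
            row.update(entry_time_ms=m.entry_time_ms,
                       elongation_index=m.elongation_index,
                       min_flow_rate=m.min_flow_rate,
                       delta_length_um=m.L1_um - m.L0_um,
                       volume_drift=abs(trace.volume_um3[-1]
                                        / trace.volume_um3[0] - 1.0),
                       status="ok" if not m.no_entry else "no_entry")
        except (MembraneLimitError, lbm.InstabilityError, ValueError) as exc:
            row.update(entry_time_ms=math.nan, elongation_index=math.nan,
                       min_flow_rate=math.nan, delta_length_um=math.nan,
                       volume_drift=math.nan, status=f"failed: {exc}")
        rows.append(row)
    return pd.DataFrame(rows)
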