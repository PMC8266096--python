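"""Time-stepping driver, run-level metrics, objective and sensitivity.

Each time step executes, in fixed order: flow solve; oxygen field; GF
field; sprout spawning; tip steering and elongation/connection (with a
flow re-solve if the topology changed); tension-induced node migration;
metabolic signals and diameter adaptation; pruning. A run integrates
10 simulated days of 0.05-day steps by default, stopping early once the
network is stable (no GF above the sprouting threshold, no topology
change, and diameters converged for 10 consecutive steps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import remodeling, transport
from .angiogenesis import RNGStreams, elongate_and_connect, spawn_sprouts
from .geometry import HexDomain, build_hex_domain, generate_tissue_grid
from .hemodynamics import iterate_flow
from .network import (VesselNetwork, classify_segments,
                      distance_to_nearest_flowing_vessel,
                      make_initial_network, FLOWING, SPROUT)
from .parameters import Parameters

__all__ = [
    "SimulationState", "RunResult", "initialize", "step", "run",
    "compute_metrics", "objective", "sensitivity_coefficient",
]

#: diameter (um) beyond which growth is considered unbounded (instability)
D_RUNAWAY = 150.0


@dataclass
class SimulationState:
    params: Parameters
    domain: HexDomain
    net: VesselNetwork
    grid: "transport.FieldCache"
    tissue_points: np.ndarray
    point_volume: float
    rng: RNGStreams
    time: float = 0.0
    step_index: int = 0
    flow = None
    blood = None
    tissue = None
    gf = None
    signals = None
    flow_audit: dict = field(default_factory=dict)
    warm_sinks: np.ndarray | None = None
    events: list = field(default_factory=list)
    history: list = field(default_factory=list)
    pial_segment_ids: tuple = ()
    quiet_steps: int = 0
    topology_changed: bool = False


def initialize(params: Parameters, seed: int = 1,
               net: VesselNetwork | None = None) -> SimulationState:
    """Build the initial simulation state (network, grid, RNG streams)."""
    domain = build_hex_domain(params.hex_side, params.hex_height)
    if net is None:
        net = make_initial_network(params, domain)
    grid = generate_tissue_grid(domain, params.grid_spacing)
    pial = tuple(s.id for s in net.segments_by_status(FLOWING))
    return SimulationState(
        params=params, domain=domain, net=net,
        grid=transport.FieldCache(),
        tissue_points=grid.points, point_volume=grid.point_volume,
        rng=RNGStreams(seed), pial_segment_ids=pial)


def _segment_midpoints(state: SimulationState, segments):
    ids = [s.id for s in segments]
    if not ids:
        return ids, np.zeros((0, 3))
    net = state.net
    mids = np.array([net.segment_midpoint(net.segments[i]) for i in ids])
    return ids, mids


def _gf_at_segments(state: SimulationState) -> dict[int, float]:
    ids, mids = _segment_midpoints(state, state.net.segments.values())
    if not ids:
        return {}
    c = state.gf.concentration(mids)
    return dict(zip(ids, c.tolist()))


def step(state: SimulationState) -> SimulationState:
    """Advance the simulation by one time step (in place)."""
    params, net = state.params, state.net

    def audit_flow(sol):
        """Conservation residuals of a solution against the network it
        was solved on (recorded now; later stages change topology)."""
        state.flow_audit = {
            "volumetric": sol.max_conservation_residual(net),
            "rbc": sol.max_rbc_residual(net),
        }

    # (1) flow
    state.flow = iterate_flow(net, params)
    audit_flow(state.flow)
    # (2) oxygen
    state.blood, state.tissue = transport.solve_oxygen_field(
        net, state.tissue_points, state.point_volume, params,
        domain=state.domain, cache=state.grid,
        warm_sinks=state.warm_sinks)
    state.warm_sinks = (state.tissue.consumption
                        * state.point_volume / 1.0e12 / 100.0)
    # (3) growth factor
    state.gf = transport.solve_gf_field(
        state.tissue.po2, state.tissue_points, state.point_volume, params,
        domain=state.domain, cache=state.grid)
    gf_at_seg = _gf_at_segments(state)
    # (4) sprout spawning
    sprout_events = spawn_sprouts(net, gf_at_seg, state.rng, params)
    for ev in sprout_events:
        state.events.append((state.step_index, "sprout", ev.segment_id,
                             ev.node_id, *np.round(ev.position, 3)))
    # (5) steering + elongation + connection
    conn_events = elongate_and_connect(net, state.gf, state.rng, params)
    for ev in conn_events:
        state.events.append((state.step_index, "connect", ev.tip_segment,
                             ev.node_id, *np.round(ev.position, 3)))
    state.topology_changed = bool(conn_events)
    if conn_events:
        state.flow = iterate_flow(net, params)  # new pathways carry flow
        audit_flow(state.flow)
    # (6) node migration
    remodeling.migrate_nodes(net, params)
    # (7) metabolic signals + adaptation
    gf_cond = {s.id: gf_at_seg.get(s.id, 0.0)
               for s in net.conducting_segments()}
    signals = remodeling.convected_flux(net, gf_cond, params)
    signals = remodeling.conducted_signal(net, params, signals)
    diameters_before = {s.id: s.diameter for s in net.segments.values()}
    state.signals = remodeling.total_signal_and_adapt(net, params, signals)
    # (8) pruning
    pruned = remodeling.prune(net, params)
    for sid in pruned:
        state.events.append((state.step_index, "prune", sid, -1,
                             0.0, 0.0, 0.0))
    state.topology_changed |= bool(pruned)
    # bookkeeping for the stability criteria
    max_rel_dd = 0.0
    for sid, d0 in diameters_before.items():
        s = net.segments.get(sid)
        if s is not None and s.status == FLOWING:
            max_rel_dd = max(max_rel_dd, abs(s.diameter - d0) / d0)
    max_cgf = float(np.max(state.gf.at_tissue)) if len(
        state.gf.at_tissue) else 0.0
    quiet = (max_cgf < params.c_th and not state.topology_changed
             and not sprout_events and max_rel_dd < 1e-4)
    state.quiet_steps = state.quiet_steps + 1 if quiet else 0
    state.step_index += 1
    state.time = state.step_index * params.dt
    state.history.append(compute_metrics(state, full=False))
    return state


def pial_av_connected(state: SimulationState) -> bool:
    """Whether the initial pial A-V shunt still carries a complete path.

    The bridge is the set of initially flowing pial segments, with
    membership propagated through segment splits (``tracked_groups``).
    It counts as pruned once those segments no longer connect the
    inflow side to the outflow boundary.
    """
    net = state.net
    bridge = {sid for sid in net.tracked_groups.get("pial_bridge", ())
              if sid in net.segments}
    if not bridge:
        return False
    adj: dict[int, list[int]] = {}
    for sid in bridge:
        s = net.segments[sid]
        adj.setdefault(s.from_node, []).append(s.to_node)
        adj.setdefault(s.to_node, []).append(s.from_node)
    # start from nodes adjacent to the inflow stub (fixed segment) or
    # the inflow boundary itself
    sources = set(net.boundary_nodes("inflow_pressure"))
    for s in net.segments.values():
        if s.status == "fixed_resistance":
            sources.update((s.from_node, s.to_node))
    targets = set(net.boundary_nodes("outflow_pressure"))
    seen = {n for n in adj if n in sources}
    queue = list(seen)
    while queue:
        n = queue.pop()
        if n in targets:
            return True
        for m in adj.get(n, []):
            if m not in seen:
                seen.add(m)
                queue.append(m)
    return False


def compute_metrics(state: SimulationState, full: bool = True) -> dict:
    """Run-level metrics of the current state.

    ``full`` adds the tissue-to-vessel distance statistics (the one
    expensive metric). Lengths in mm; densities in mm^-2 (flowing
    length per tissue volume); perfusion in cm^3 (100 cm^3)^-1 min^-1;
    extraction and fractions in percent.
    """
    net, params = state.net, state.params
    vol_mm3 = state.domain.volume / 1.0e9
    lengths = {"arteriolar": 0.0, "venular": 0.0, "capillary": 0.0,
               "mesh": 0.0, "unclassified": 0.0}
    classify_segments(net)
    total_flowing = 0.0
    for s in net.conducting_segments():
        length = net.segment_length(s) / 1000.0  # mm
        total_flowing += length
        lengths[s.classification] = lengths.get(s.classification, 0.0) \
            + length
    sprout_length = sum(net.segment_length(s) for s in
                        net.segments_by_status(SPROUT)) / 1000.0
    inflow = 0.0
    for nid in net.boundary_nodes("inflow_pressure"):
        for s in net.conducting_segments():
            if s.from_node == nid:
                inflow += max(s.flow, 0.0)
            elif s.to_node == nid:
                inflow += max(-s.flow, 0.0)
    perfusion = inflow * 1.0e-6 / (vol_mm3 * 1.0e-3) * 100.0 \
        if vol_mm3 > 0 else 0.0
    blood, tissue = state.blood, state.tissue
    extraction = np.nan
    if blood is not None and blood.inflow_flux > 0.0:
        extraction = 100.0 * (blood.inflow_flux - blood.outflow_flux) \
            / blood.inflow_flux
    out = {
        "time": state.time,
        "total_length": total_flowing + sprout_length,
        "flowing_length": total_flowing,
        "sprout_length": sprout_length,
        "length_arteriolar": lengths["arteriolar"],
        "length_venular": lengths["venular"],
        "length_capillary": lengths["capillary"],
        "length_mesh": lengths["mesh"],
        "length_density": total_flowing / vol_mm3,
        "total_inflow": inflow,
        "effective_perfusion": perfusion,
        "oxygen_extraction": extraction,
        "n_segments": len(net.segments),
        "n_tips": len(net.tips),
    }
    if tissue is not None:
        po2 = tissue.po2
        out["hypoxic_fraction"] = 100.0 * float(
            np.mean(po2 < params.hypoxia_threshold))
        out["mean_tissue_po2"] = float(np.mean(po2))
        out["sd_tissue_po2"] = float(np.std(po2))
    if blood is not None and len(blood.po2):
        out["mean_vessel_po2"] = blood.mean_po2()
        out["sd_vessel_po2"] = blood.sd_po2()
    if state.gf is not None and len(state.gf.at_tissue):
        cgf = state.gf.at_tissue
        out["max_cgf"] = float(np.max(cgf))
        out["gf_fraction"] = 100.0 * float(np.mean(cgf > params.c_th))
    if full:
        d = distance_to_nearest_flowing_vessel(state.tissue_points, net)
        finite = d[np.isfinite(d)]
        out["mean_vessel_distance"] = float(np.mean(finite)) \
            if len(finite) else np.nan
        out["sd_vessel_distance"] = float(np.std(finite)) \
            if len(finite) else np.nan
    return out


@dataclass
class RunResult:
    state: SimulationState
    metrics: pd.DataFrame
    final_metrics: dict
    events: list
    stable: bool
    failure: str | None = None
    stopped_at_step: int = 0

    @property
    def pial_av_connected(self) -> bool:
        return pial_av_connected(self.state)


def run(params: Parameters, seed: int = 1, n_steps: int | None = None,
        early_stop: bool = True, quiet_steps_required: int = 10,
        callback=None) -> RunResult:
    """Run a full simulation from the standard initial configuration.

    Returns the final state, the per-step metrics time series and the
    event log. Instability (runaway diameters or solver failure) does
    not raise; it terminates the run with a labeled failure record,
    since loss of stability is itself an experimental outcome.
    """
    state = initialize(params, seed)
    if n_steps is None:
        n_steps = params.n_steps
    failure = None
    stable = False
    i = 0
    for i in range(n_steps):
        try:
            step(state)
        except Exception as exc:  # solver failure ends the run, labeled
            failure = f"step {i}: {type(exc).__name__}: {exc}"
            break
        if callback is not None:
            callback(state)
        dmax = max((s.diameter for s in state.net.segments.values()),
                   default=0.0)
        if dmax > D_RUNAWAY:
            failure = f"step {i}: unbounded diameter growth ({dmax:.1f} um)"
            break
        if early_stop and state.quiet_steps >= quiet_steps_required:
            stable = True
            break
    if failure is None and not stable:
        # stable if the quiet criteria hold at the end of the window
        stable = state.quiet_steps > 0
    final = compute_metrics(state, full=True) if failure is None \
        else (state.history[-1] if state.history else {})
    return RunResult(state=state, metrics=pd.DataFrame(state.history),
                     final_metrics=final, events=list(state.events),
                     stable=stable, failure=failure, stopped_at_step=i + 1)


def objective(metrics: dict, l_0: float = 19.2, e_ox0: float = 26.2) -> float:
    """Calibration objective E = F_GF^2 + F_H^2 + (L_t-L_0)^2 + (E_OX-E_OX0)^2.

    F_GF and F_H are the percent of tissue points with C_GF above the
    sprouting threshold and P_O2 below the hypoxia threshold; L_t is
    total vessel length in mm and E_OX the percent oxygen extraction.
    """
    f_gf = metrics.get("gf_fraction", 0.0)
    f_h = metrics.get("hypoxic_fraction", 0.0)
    l_t = metrics.get("total_length", 0.0)
    e_ox = metrics.get("oxygen_extraction", 0.0)
    return float(f_gf ** 2 + f_h ** 2 + (l_t - l_0) ** 2
                 + (e_ox - e_ox0) ** 2)


def sensitivity_coefficient(x_low: float, x_high: float, x_ref: float,
                            p_low: float, p_high: float,
                            p_ref: float) -> float:
    """Normalized sensitivity (dX/X_ref)/(dp/p_ref) from a two-point sweep."""
    if x_ref == 0.0 or p_ref == 0.0 or p_high == p_low:
        return math.nan
    return ((x_high - x_low) / x_ref) / ((p_high - p_low) / p_ref)
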