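"""Tension-induced node migration, metabolic signals, diameter
adaptation and pruning.

Vessels are under longitudinal tension proportional to diameter; the
normalized imbalance at a node drives migration above a threshold,
smoothing branch angles. Tissue-derived growth factor enters flowing
vessels, is convected downstream (S_m) and triggers a conducted
response propagating upstream along vessel walls with exponential decay
(S_c). Diameters adapt to the combined shear, pressure and metabolic
stimulus; vessels below the red-cell passage minimum are pruned along
with any segments whose flow consequently ceases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hemodynamics import Q_FLOOR
from .network import VesselNetwork, FLOWING, FIXED, SPROUT
from .parameters import Parameters

__all__ = [
    "tension_force", "migrate_nodes", "convected_flux", "conducted_signal",
    "total_signal_and_adapt", "prune", "SegmentSignals", "expected_shear",
]


def tension_force(net: VesselNetwork, node_id: int) -> np.ndarray:
    """Normalized tension imbalance f_t = (sum D_i e_i)(sum D_i)/(sum l_i D_i).

    e_i are unit vectors from the node along each attached segment
    (periodic minimal image). At an unbranched node |f_t| estimates the
    dimensionless local curvature (diameter / radius of curvature).
    """
    vec_sum = np.zeros(3)
    d_sum = 0.0
    ld_sum = 0.0
    for s in net.segments.values():
        if node_id == s.from_node:
            e = net.segment_vector(s)
        elif node_id == s.to_node:
            e = -net.segment_vector(s)
        else:
            continue
        length = np.linalg.norm(e)
        if length < 1e-12:
            continue
        vec_sum += s.diameter * e / length
        d_sum += s.diameter
        ld_sum += length * s.diameter
    if ld_sum == 0.0:
        return np.zeros(3)
    return vec_sum * d_sum / ld_sum


def migrate_nodes(net: VesselNetwork, params: Parameters) -> int:
    """Move interior nodes down their tension imbalance; returns count moved.

    Nodes migrate at speed v_max (1 - lambda_t/|f_t|) along f_t when
    |f_t| exceeds the threshold, so speed rises continuously from zero
    at threshold and saturates at v_max. Boundary nodes, nodes touching
    the fixed-resistance segment, and degree-1 nodes (tips, blind ends)
    do not migrate. Positions re-wrap; segment lengths follow.
    """
    fixed_nodes = set()
    degree: dict[int, int] = {}
    for s in net.segments.values():
        degree[s.from_node] = degree.get(s.from_node, 0) + 1
        degree[s.to_node] = degree.get(s.to_node, 0) + 1
        if s.status == FIXED:
            fixed_nodes.update((s.from_node, s.to_node))
    moved = 0
    updates: dict[int, np.ndarray] = {}
    for nid in sorted(net.nodes):
        node = net.nodes[nid]
        if node.boundary_kind != "none" or nid in fixed_nodes:
            continue
        if degree.get(nid, 0) < 2:
            continue
        f_t = tension_force(net, nid)
        mag = float(np.linalg.norm(f_t))
        if mag <= params.lambda_t:
            continue
        speed = params.v_max * (1.0 - params.lambda_t / mag)
        step = speed * params.dt * f_t / mag
        updates[nid] = net.domain.wrap(node.position + step)
        moved += 1
    for nid, pos in updates.items():
        net.nodes[nid].position = pos
    return moved


@dataclass
class SegmentSignals:
    """Per-segment metabolic signals and the total adaptive stimulus."""
    j_gf: dict[int, float] = field(default_factory=dict)    # convected GF flux
    c_gfv: dict[int, float] = field(default_factory=dict)   # vessel GF conc.
    s_m: dict[int, float] = field(default_factory=dict)     # convected signal
    j_c: dict[int, float] = field(default_factory=dict)     # conducted flux
    s_c: dict[int, float] = field(default_factory=dict)     # conducted signal
    s_tot: dict[int, float] = field(default_factory=dict)   # total stimulus


def _flow_orientation(net: VesselNetwork):
    """Conducting segments with |Q| > 0, their up/down nodes and order."""
    segs = [s for s in net.conducting_segments() if abs(s.flow) > Q_FLOOR]
    up, down = {}, {}
    for s in segs:
        if s.flow >= 0.0:
            up[s.id], down[s.id] = s.from_node, s.to_node
        else:
            up[s.id], down[s.id] = s.to_node, s.from_node
    nodes = sorted({n for s in segs for n in (s.from_node, s.to_node)},
                   key=lambda nid: -net.nodes[nid].pressure)
    return segs, up, down, nodes


def convected_flux(net: VesselNetwork, gf_at_segments: dict[int, float],
                   params: Parameters,
                   signals: SegmentSignals | None = None) -> SegmentSignals:
    """Downstream-convected GF flux and the convected signal S_m.

    dJ_GF/ds = kappa_GF C_GF along the flow, zero at network inflows;
    at converging nodes fluxes sum, at diverging nodes the flux splits
    in proportion to volumetric flow (a convected quantity follows the
    blood). C_GFv = J_GF(midpoint)/(Q + Q_ref); S_m saturates in C_GFv.
    """
    if signals is None:
        signals = SegmentSignals()
    segs, up, down, order = _flow_orientation(net)
    if any(np.isnan(net.nodes[s.from_node].pressure) for s in segs):
        raise RuntimeError("convected signals require solved flows")
    flux_at: dict[int, float] = {}
    outs_by: dict[int, list] = {}
    for s in segs:
        outs_by.setdefault(up[s.id], []).append(s)
    for nid in order:
        outs = outs_by.get(nid, [])
        if not outs:
            continue
        if net.nodes[nid].boundary_kind == "inflow_pressure":
            f_node = 0.0
        else:
            f_node = flux_at.get(nid, 0.0)
        q_tot = sum(abs(s.flow) for s in outs)
        for s in outs:
            share = abs(s.flow) / q_tot if q_tot > 0 else 0.0
            j_in = f_node * share
            length = net.segment_length(s)
            c = gf_at_segments.get(s.id, 0.0)
            j_mid = j_in + params.kappa_gf * c * length / 2.0
            j_out = j_in + params.kappa_gf * c * length
            flux_at[down[s.id]] = flux_at.get(down[s.id], 0.0) + j_out
            c_gfv = j_mid / (abs(s.flow) + params.q_ref)
            signals.j_gf[s.id] = j_mid
            signals.c_gfv[s.id] = c_gfv
            signals.s_m[s.id] = c_gfv / (c_gfv + params.c_gf50v)
    return signals


def conducted_signal(net: VesselNetwork, params: Parameters,
                     signals: SegmentSignals) -> SegmentSignals:
    """Upstream-conducted metabolic signal J_c and its response S_c.

    dJ_c/ds = S_m - J_c/L_c integrated against the flow direction from
    zero at network outflows, with the exact exponential update per
    segment. At junctions the conducted quantity behaves as a wall
    signal flux F = J_c D: where conduction paths converge (a
    flow-diverging bifurcation) the incoming signals are weighted by
    their diameters and summed, so the metabolic need of the whole
    downstream bed accumulates up the feeding tree; where one
    conduction path serves several upstream vessels (a flow-converging
    node) the flux divides among them in proportion to diameter.
    S_c = S_c^max J_c/(J_c + J_c50) at the segment midpoint.
    """
    segs, up, down, order = _flow_orientation(net)
    by_id = {s.id: s for s in segs}
    ins_by: dict[int, list] = {}   # segments whose downstream end is nid
    for s in segs:
        ins_by.setdefault(down[s.id], []).append(s)
    # conduction marches upstream: process nodes by increasing pressure
    arriving: dict[int, float] = {}  # nid -> accumulated signal flux J_c D
    for nid in reversed(order):
        node = net.nodes[nid]
        if node.boundary_kind == "outflow_pressure":
            flux = 0.0
        else:
            flux = arriving.get(nid, 0.0)
        feeders = ins_by.get(nid, [])  # flow into nid = conduction out of it
        d_tot = sum(s.diameter for s in feeders)
        for s in feeders:
            # flux share D_s/D_tot, converted back to a per-wall signal
            j_in = flux / d_tot if d_tot > 0 else 0.0
            length = net.segment_length(s)
            s_m = signals.s_m.get(s.id, 0.0)
            e_half = np.exp(-0.5 * length / params.l_c)
            e_full = e_half * e_half
            j_mid = j_in * e_half + s_m * params.l_c * (1.0 - e_half)
            j_up = j_in * e_full + s_m * params.l_c * (1.0 - e_full)
            signals.j_c[s.id] = j_mid
            signals.s_c[s.id] = params.s_c_max * j_mid / (j_mid + params.j_c50)
            arriving[up[s.id]] = arriving.get(up[s.id], 0.0) \
                + s.diameter * j_up
    # stagnant conducting segments carry no signal
    for s in net.conducting_segments():
        if s.id not in by_id:
            signals.s_m.setdefault(s.id, 0.0)
            signals.s_c.setdefault(s.id, 0.0)
            signals.j_c.setdefault(s.id, 0.0)
    return signals


def expected_shear(p_mmhg: float, params: Parameters) -> float:
    """Expected wall shear stress tau_e(P) = 14 + 86 P^5/(P^5 + P_tau^5)."""
    p = max(p_mmhg, 0.0)
    p5 = p ** 5
    return params.tau_e_base + params.tau_e_amp * p5 / (
        p5 + params.p_tau ** 5)


def total_signal_and_adapt(net: VesselNetwork, params: Parameters,
                           signals: SegmentSignals) -> SegmentSignals:
    """Total adaptive stimulus and the diameter update.

    S_tot = ln(tau_w + tau_ref) - ln tau_e(P) + k_m (S_m + S_c)/D - k_s,
    with P the mean of the endpoint pressures; each flowing segment
    updates D <- D + S_tot D dt/T. Sprouts and the fixed-resistance
    segment do not adapt.
    """
    for s in net.segments.values():
        if s.status != FLOWING:
            continue
        p_mean = 0.5 * (net.nodes[s.from_node].pressure
                        + net.nodes[s.to_node].pressure)
        if np.isnan(p_mean):
            continue
        s_m = signals.s_m.get(s.id, 0.0)
        s_c = signals.s_c.get(s.id, 0.0)
        s_tot = (np.log(s.wss + params.tau_ref)
                 - np.log(expected_shear(p_mean, params))
                 + params.k_m * (s_m + s_c) / s.diameter - params.k_s)
        signals.s_tot[s.id] = float(s_tot)
        s.diameter = s.diameter * (1.0 + s_tot * params.dt / params.t_adapt)
        if s.diameter <= 0.0:
            s.diameter = 1e-3  # collapses below pruning threshold anyway
    return signals


def prune(net: VesselNetwork, params: Parameters) -> list[int]:
    """Remove collapsed vessels and everything their loss disconnects.

    Flowing segments with D below the red-cell passage minimum are
    removed; then any previously flowing segment left without a path
    between inflow and outflow, and any sprout chain no longer attached
    to the surviving network, is removed as well. Returns the removed
    segment ids.
    """
    removed = [s.id for s in net.segments_by_status(FLOWING)
               if s.diameter < params.pruning_diameter]
    net.remove_segments(removed)
    # flowing segments must retain an inflow-outflow path
    core = net.flow_core()
    dead_flow = [s.id for s in net.segments_by_status(FLOWING)
                 if s.id not in core]
    removed.extend(dead_flow)
    net.remove_segments(dead_flow)
    # sprout chains must stay attached (possibly via other sprouts) to
    # the conducting network
    keep_nodes = {n for s in net.conducting_segments()
                  for n in (s.from_node, s.to_node)}
    if keep_nodes:
        changed = True
        attached: set[int] = set()
        while changed:
            changed = False
            for s in net.segments_by_status(SPROUT):
                if s.id in attached:
                    continue
                if s.from_node in keep_nodes or s.to_node in keep_nodes:
                    attached.add(s.id)
                    keep_nodes.update((s.from_node, s.to_node))
                    changed = True
        dead_sprouts = [s.id for s in net.segments_by_status(SPROUT)
                        if s.id not in attached]
    else:
        dead_sprouts = [s.id for s in net.segments_by_status(SPROUT)]
    removed.extend(dead_sprouts)
    net.remove_segments(dead_sprouts)
    return removed
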