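"""Steady-state network hemodynamics.

Nodal pressures are solved from flow conservation with Poiseuille
segment resistances. The apparent viscosity of blood depends on vessel
diameter and discharge hematocrit (Fahraeus-Lindqvist effect) through
the empirical in-vivo law of Pries & Secomb, with the in-vitro variant
available as a configuration alternative. Red cells partition unequally
at diverging bifurcations (phase separation / plasma skimming), so
hematocrits depend on the flow split and the whole system is iterated
to a joint fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import units
from .network import VesselNetwork, FLOWING, FIXED
from .parameters import Parameters

__all__ = [
    "apparent_viscosity", "segment_resistance", "solve_pressures",
    "phase_separation", "iterate_flow", "FlowSolution",
]

#: smallest diameter at which the empirical viscosity laws are evaluated
#: (the in-vivo law is singular at 1.1 um; vessels below the red-cell
#: minimum are pruned anyway)
_D_FLOOR = 1.5

#: flows below this magnitude (nl/min) are treated as stagnant
Q_FLOOR = 1e-10


def _eta_45_vivo(d: np.ndarray) -> np.ndarray:
    return 6.0 * np.exp(-0.085 * d) + 3.2 - 2.44 * np.exp(-0.06 * d ** 0.645)


def _eta_45_vitro(d: np.ndarray) -> np.ndarray:
    return 220.0 * np.exp(-1.3 * d) + 3.2 - 2.44 * np.exp(-0.06 * d ** 0.645)


def _shape_exponent(d: np.ndarray) -> np.ndarray:
    f = 1.0 / (1.0 + 1e-11 * d ** 12)
    return (0.8 + np.exp(-0.075 * d)) * (-1.0 + f) + f


def apparent_viscosity(diameter: float | np.ndarray,
                       hd: float | np.ndarray,
                       law: str = "in_vivo",
                       plasma_viscosity: float = 1.0) -> np.ndarray:
    """Apparent blood viscosity in cP for tube diameter (um) and H_D.

    ``law`` selects the in-vivo parameterization (with the endothelial
    surface layer built in) or the bare in-vitro glass-tube law.
    """
    d = np.maximum(np.asarray(diameter, dtype=float), _D_FLOOR)
    h = np.asarray(hd, dtype=float)
    if np.any(d <= 0.0) or np.any(np.asarray(diameter, float) <= 0.0):
        raise ValueError("diameter must be positive")
    if np.any((h < 0.0) | (h > 1.0)):
        raise ValueError("hematocrit must lie in [0, 1]")
    c = _shape_exponent(d)
    hterm = (np.power(1.0 - h, c) - 1.0) / (np.power(1.0 - 0.45, c) - 1.0)
    if law == "in_vivo":
        w = (d / (d - 1.1)) ** 2
        rel = (1.0 + (_eta_45_vivo(d) - 1.0) * hterm * w) * w
    elif law == "in_vitro":
        rel = 1.0 + (_eta_45_vitro(d) - 1.0) * hterm
    else:
        raise ValueError(f"unknown viscosity law {law!r}")
    return rel * plasma_viscosity


def segment_resistance(length: float, diameter: float,
                       viscosity: float) -> float:
    """Poiseuille resistance in mmHg/(nl/min); see Eq in units module."""
    return units.poiseuille_resistance(length, diameter, viscosity)


@dataclass
class FlowSolution:
    """Converged flow state of a network."""
    pressures: dict[int, float]  # node id -> mmHg
    flows: dict[int, float]      # segment id -> nl/min (from -> to)
    hematocrits: dict[int, float]
    wss: dict[int, float]        # dyn/cm^2
    iterations: int = 0
    residual: float = 0.0
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def max_conservation_residual(self, net: VesselNetwork) -> float:
        """Max interior-node volumetric imbalance relative to max |Q|."""
        acc: dict[int, float] = {}
        qmax = 0.0
        for sid, q in self.flows.items():
            s = net.segments.get(sid)
            if s is None:  # pruned after this solution was computed
                continue
            acc[s.from_node] = acc.get(s.from_node, 0.0) - q
            acc[s.to_node] = acc.get(s.to_node, 0.0) + q
            qmax = max(qmax, abs(q))
        worst = 0.0
        for nid, v in acc.items():
            if net.nodes[nid].boundary_kind == "none":
                worst = max(worst, abs(v))
        return worst / qmax if qmax > 0 else worst

    def max_rbc_residual(self, net: VesselNetwork) -> float:
        """Max interior-node RBC-flux imbalance relative to max RBC flux."""
        acc: dict[int, float] = {}
        fmax = 0.0
        for sid, q in self.flows.items():
            s = net.segments.get(sid)
            if s is None:  # pruned after this solution was computed
                continue
            f = q * self.hematocrits[sid]
            acc[s.from_node] = acc.get(s.from_node, 0.0) - f
            acc[s.to_node] = acc.get(s.to_node, 0.0) + f
            fmax = max(fmax, abs(f))
        worst = 0.0
        for nid, v in acc.items():
            if net.nodes[nid].boundary_kind == "none":
                worst = max(worst, abs(v))
        return worst / fmax if fmax > 0 else worst


def solve_pressures(net: VesselNetwork,
                    viscosities: dict[int, float]) -> FlowSolution:
    """Solve nodal pressures and segment flows for given viscosities.

    Builds the symmetric nodal conductance system over conducting
    segments with Dirichlet pressure boundary nodes and solves it
    directly. Raises if a conducting component has no pressure boundary.
    """
    segs = net.conducting_segments()
    if not segs:
        raise ValueError("network has no conducting segments")
    node_ids = sorted({s.from_node for s in segs} | {s.to_node for s in segs})
    index = {nid: i for i, nid in enumerate(node_ids)}
    n = len(node_ids)
    fixed = {nid: net.nodes[nid].boundary_pressure for nid in node_ids
             if net.nodes[nid].boundary_kind != "none"}
    if not fixed:
        raise ValueError("no pressure boundary node in conducting network")

    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    diag = np.zeros(n)
    for s in segs:
        g = 1.0 / segment_resistance(net.segment_length(s), s.diameter,
                                     viscosities[s.id])
        i, j = index[s.from_node], index[s.to_node]
        diag[i] += g
        diag[j] += g
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([-g, -g])
    a = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    a = a + sp.diags(diag)
    # Dirichlet rows
    a = a.tolil()
    for nid, p in fixed.items():
        i = index[nid]
        a.rows[i] = [i]
        a.data[i] = [1.0]
        rhs[i] = p
    a = a.tocsr()
    p = spla.spsolve(a, rhs)
    if not np.all(np.isfinite(p)):
        raise RuntimeError("singular pressure system: conducting component "
                           "without a pressure boundary")
    pressures = {nid: float(p[index[nid]]) for nid in node_ids}
    flows, wss = {}, {}
    for s in segs:
        length = net.segment_length(s)
        r = segment_resistance(length, s.diameter, viscosities[s.id])
        dp = pressures[s.from_node] - pressures[s.to_node]
        flows[s.id] = dp / r
        wss[s.id] = units.wall_shear_stress(s.diameter, dp, length)
    return FlowSolution(pressures=pressures, flows=flows,
                        hematocrits={s.id: s.hd for s in segs}, wss=wss)


def phase_separation(parent_flow: float, parent_hd: float, parent_d: float,
                     daughter_flows, daughter_ds) -> np.ndarray:
    """Discharge hematocrits of two daughters at a diverging bifurcation.

    Empirical red-cell partition law (Pries et al.): the fractional RBC
    flux into a daughter is a logit-linear function of its fractional
    blood flow, with diameter- and hematocrit-dependent coefficients.
    RBC flux is conserved exactly; saturation of the law is resolved by
    conservative redistribution with each H_D clamped to [0, 1].
    """
    qd = np.asarray(daughter_flows, dtype=float)
    dd = np.asarray(daughter_ds, dtype=float)
    if qd.shape != (2,) or dd.shape != (2,):
        raise ValueError("phase separation applies to two daughters")
    if parent_flow <= 0.0 or np.any(qd < 0.0):
        raise ValueError("diverging bifurcation requires positive flows")
    if abs(qd.sum() - parent_flow) > 1e-6 * max(parent_flow, 1e-30):
        raise ValueError("daughter flows must sum to the parent flow")
    rbc = parent_flow * parent_hd
    if rbc == 0.0:
        return np.zeros(2)
    if qd[0] <= Q_FLOOR:
        return np.array([0.0, min(1.0, rbc / qd[1])])
    if qd[1] <= Q_FLOOR:
        return np.array([min(1.0, rbc / qd[0]), 0.0])
    fqb = qd[0] / parent_flow
    x0 = 0.4 / parent_d
    if fqb <= x0:
        fqe = 0.0
    elif fqb >= 1.0 - x0:
        fqe = 1.0
    else:
        a_coef = -6.96 / parent_d * np.log(dd[0] / dd[1])
        b_coef = 1.0 + 6.98 * (1.0 - parent_hd) / parent_d
        x = (fqb - x0) / (1.0 - 2.0 * x0)
        logit = a_coef + b_coef * np.log(x / (1.0 - x))
        fqe = 1.0 / (1.0 + np.exp(-logit))
    h = np.array([fqe * rbc / qd[0], (1.0 - fqe) * rbc / qd[1]])
    # clamp with conservation-preserving redistribution
    for i, j in ((0, 1), (1, 0)):
        if h[i] > 1.0:
            h[i] = 1.0
            h[j] = (rbc - qd[i]) / qd[j]
    h = np.clip(h, 0.0, 1.0)
    return h


def _propagate_hematocrit(net: VesselNetwork, sol: FlowSolution,
                          inlet_hd: float) -> dict[int, float]:
    """Propagate discharge hematocrit from inflows along flow directions.

    Nodes are processed in order of decreasing pressure (flow always
    descends the pressure field, so this is a topological order). At
    converging nodes the RBC-flux-weighted mixture is used; at diverging
    nodes with two outflows the empirical partition law applies; with
    three or more outflows the hematocrit passes unchanged. Stagnant
    segments keep their previous hematocrit.
    """
    segs = {s.id: s for s in net.conducting_segments()}
    hd = {sid: segs[sid].hd for sid in segs}
    adj: dict[int, list[int]] = {}
    for s in segs.values():
        adj.setdefault(s.from_node, []).append(s.id)
        adj.setdefault(s.to_node, []).append(s.id)
    order = sorted(adj, key=lambda nid: -sol.pressures[nid])
    for nid in order:
        outs, ins = [], []
        for sid in adj[nid]:
            s = segs[sid]
            q = sol.flows[sid] if s.from_node == nid else -sol.flows[sid]
            if q > Q_FLOOR:
                outs.append((sid, q))
            elif q < -Q_FLOOR:
                ins.append((sid, -q))
        if not outs:
            continue
        q_in = sum(q for _, q in ins)
        if net.nodes[nid].boundary_kind == "inflow_pressure":
            h_mix = inlet_hd
        elif q_in > 0.0:
            h_mix = sum(q * hd[sid] for sid, q in ins) / q_in
        else:
            continue  # isolated stagnant cluster
        if len(outs) == 2:
            q_tot = sum(q for _, q in outs)
            feed_d = (max(segs[s].diameter for s, _ in ins)
                      if ins else max(segs[s].diameter for s, _ in outs))
            h = phase_separation(q_tot, h_mix, feed_d,
                                 [outs[0][1], outs[1][1]],
                                 [segs[outs[0][0]].diameter,
                                  segs[outs[1][0]].diameter])
            hd[outs[0][0]], hd[outs[1][0]] = float(h[0]), float(h[1])
        else:
            for sid, _ in outs:
                hd[sid] = h_mix
    return hd


def iterate_flow(net: VesselNetwork, params: Parameters,
                 tol: float = 1e-6, max_iter: int = 200,
                 relax: float = 0.5) -> FlowSolution:
    """Iterate pressures, flows and hematocrits to a joint fixed point.

    Successive substitution with under-relaxation on hematocrits.
    Updates segment ``flow``, ``hd``, ``wss`` and node ``pressure``
    in place and returns the converged :class:`FlowSolution`.
    """
    segs = net.conducting_segments()
    prev_flows = None
    sol = None
    for it in range(1, max_iter + 1):
        visc = {s.id: float(apparent_viscosity(
            s.diameter, s.hd, params.viscosity_law, params.plasma_viscosity))
            for s in segs}
        sol = solve_pressures(net, visc)
        hd_new = _propagate_hematocrit(net, sol, params.inlet_hd)
        dh = 0.0
        for s in segs:
            h_relaxed = (1.0 - relax) * s.hd + relax * hd_new[s.id]
            dh = max(dh, abs(h_relaxed - s.hd))
            s.hd = h_relaxed
        dq = 0.0
        if prev_flows is not None:
            qmax = max((abs(q) for q in sol.flows.values()), default=0.0)
            scale = max(qmax, Q_FLOOR)
            dq = max(abs(sol.flows[sid] - prev_flows[sid]) / scale
                     for sid in sol.flows)
        prev_flows = dict(sol.flows)
        converged = it > 1 and dq < tol and dh < tol
        if converged or it == max_iter:
            sol.iterations = it
            sol.residual = max(dq, dh)
            sol.converged = converged
            break
    # final hematocrit pass without relaxation so node RBC balance is exact
    hd_final = _propagate_hematocrit(net, sol, params.inlet_hd)
    for s in segs:
        s.hd = hd_final[s.id]
        s.flow = sol.flows[s.id]
        s.wss = sol.wss[s.id]
    sol.hematocrits = {s.id: s.hd for s in segs}
    for nid, p in sol.pressures.items():
        net.nodes[nid].pressure = p
    for s in net.segments_by_status("sprout"):
        s.flow = 0.0
        s.wss = 0.0
    return sol
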