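"""Sprout formation, tip steering, elongation and connection.

Sprouts form stochastically on existing segments where the local GF
level exceeds a threshold, grow at fixed speed with randomized
direction, home onto nearby vessels sensed within a forward cone
(filopodial sensing), climb GF gradients, and connect to form new flow
pathways when a tip approaches another segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import VesselNetwork, SproutTip, SPROUT, FIXED
from .parameters import Parameters

__all__ = [
    "RNGStreams", "sprout_probability", "spawn_sprouts", "homing_vector",
    "update_direction", "elongate_and_connect",
]


class RNGStreams:
    """Named, seeded random substreams for reproducible event sequences."""

    _NAMES = ("sprout_placement", "sprout_direction", "steering")

    def __init__(self, seed: int):
        self.seed = seed
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(len(self._NAMES))
        self._streams = {name: np.random.default_rng(child)
                         for name, child in zip(self._NAMES, children)}

    def __getitem__(self, name: str) -> np.random.Generator:
        return self._streams[name]


def sprout_probability(c_gf: float, l_seg: float, dt: float,
                       params: Parameters) -> float:
    """Per-step sprout formation probability of a segment.

    Zero at or below the GF threshold; above it, saturating in C_GF with
    supremum k_p * l_seg * dt, capped at 1.
    """
    if l_seg <= 0.0 or dt <= 0.0:
        raise ValueError("l_seg and dt must be positive")
    if c_gf <= params.c_th:
        return 0.0
    excess = c_gf - params.c_th
    p = params.k_p * l_seg * dt * excess / (params.c_th50 + excess)
    return min(p, 1.0)


@dataclass
class SproutEvent:
    segment_id: int
    node_id: int
    position: np.ndarray
    direction: np.ndarray


def _perpendicular_direction(axis: np.ndarray,
                             rng: np.random.Generator) -> np.ndarray:
    """Uniform random unit vector in the plane perpendicular to ``axis``."""
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.cos(phi) * u + np.sin(phi) * v


def spawn_sprouts(net: VesselNetwork, c_gf_at_segments: dict[int, float],
                  rng: RNGStreams, params: Parameters) -> list[SproutEvent]:
    """Draw sprout formation events and attach new tips to the network.

    Each segment (except the fixed-resistance inlet stub) undergoes a
    Bernoulli draw at the GF-dependent probability. The attachment
    location is uniform along the parent; within 10 um of an endpoint it
    snaps to that node, and draws landing on boundary nodes or existing
    branch points are suppressed. The initial growth direction is
    uniform on the circle perpendicular to the parent axis.
    """
    events: list[SproutEvent] = []
    place = rng["sprout_placement"]
    direc = rng["sprout_direction"]
    degree = {}
    for s in net.segments.values():
        degree[s.from_node] = degree.get(s.from_node, 0) + 1
        degree[s.to_node] = degree.get(s.to_node, 0) + 1
    # iterate over a sorted snapshot: new segments must not be re-drawn
    for sid in sorted(net.segments):
        seg = net.segments[sid]
        if seg.status == FIXED:
            continue
        length = net.segment_length(seg)
        p = sprout_probability(c_gf_at_segments.get(sid, 0.0), length,
                               params.dt, params)
        if p <= 0.0 or place.uniform() >= p:
            continue
        t = place.uniform()
        axis = net.segment_vector(seg)
        snap = params.node_merge_tol / length
        node_id = None
        if t < snap:
            node_id = seg.from_node
        elif t > 1.0 - snap:
            node_id = seg.to_node
        if node_id is not None:
            if net.nodes[node_id].boundary_kind != "none":
                continue  # suppressed at boundary nodes
            if degree.get(node_id, 0) >= 3:
                continue  # suppressed at existing branch points
        else:
            node_id = net.split_segment(sid, t)
            degree[node_id] = 2
        direction = _perpendicular_direction(axis, direc)
        base = net.nodes[node_id].position
        # first advance happens during elongation; lay a minimal stub so
        # the tip has a segment (grown to full step length immediately)
        stub = params.growth_increment
        tip_node = net.add_node(base + stub * direction)
        tip_seg = net.add_segment(node_id, tip_node, params.d_sprout,
                                  status=SPROUT)
        tip = SproutTip(position=net.nodes[tip_node].position.copy(),
                        direction=direction.copy(), tip_node=tip_node,
                        tip_segment=tip_seg, chain=[tip_seg])
        net.tips.append(tip)
        events.append(SproutEvent(segment_id=sid, node_id=node_id,
                                  position=base.copy(),
                                  direction=direction.copy()))
        degree[node_id] = degree.get(node_id, 0) + 1
    return events


def _cone_weights(rel: np.ndarray, axis: np.ndarray,
                  params: Parameters):
    """Distance and angle weights f(r) g(theta) for points in the cone."""
    r = np.linalg.norm(rel, axis=-1)
    r_safe = np.maximum(r, 1e-12)
    cos_t = (rel @ axis) / r_safe
    cos_t = np.clip(cos_t, -1.0, 1.0)
    f = np.clip(1.0 - r / params.r_max, 0.0, None)
    g = 1.0 - (1.0 - cos_t) / (1.0 - np.cos(params.theta_max))
    g = np.clip(g, 0.0, None)
    return r_safe, f, g


# 8-point Gauss-Legendre nodes/weights on [0, 1]
_GL_X, _GL_W = np.polynomial.legendre.leggauss(8)
_GL_T = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


def homing_vector(tip_position: np.ndarray, direction: np.ndarray,
                  net: VesselNetwork, params: Parameters,
                  exclude: set[int] = frozenset(),
                  arrays=None) -> np.ndarray:
    """Attraction vector toward segments inside the sensing cone.

    Sum over segments of the line integral of e_r f(r) g(theta) ds,
    where e_r points from the tip to the segment, f decays linearly to
    zero at R_max and g to zero at the cone half-angle. Fixed-order
    Gauss quadrature along each (periodic minimal-image) segment.
    ``exclude`` removes the tip's own chain and parent segments;
    ``arrays`` may carry a precomputed ``net.segment_arrays()``.
    """
    tip = np.asarray(tip_position, dtype=float)
    axis = np.asarray(direction, dtype=float)
    axis = axis / np.linalg.norm(axis)
    sids, a, vec, lengths = arrays if arrays is not None \
        else net.segment_arrays()
    if not len(sids):
        return np.zeros(3)
    rel_a = net.domain.displacement_many(tip, a)
    # cheap reject: closest possible approach beyond R_max
    near = np.linalg.norm(rel_a, axis=1) - lengths <= params.r_max
    if exclude:
        near &= ~np.isin(sids, list(exclude))
    if not np.any(near):
        return np.zeros(3)
    rel_a, vec_n, len_n = rel_a[near], vec[near], lengths[near]
    pts = rel_a[:, None, :] + _GL_T[None, :, None] * vec_n[:, None, :]
    r, f, g = _cone_weights(pts, axis, params)
    w = f * g * _GL_W[None, :] * len_n[:, None]
    e_r = pts / r[..., None]
    return np.einsum("ij,ijk->k", w, e_r)


def _random_rotation(d: np.ndarray, sigma2: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Rotate d about a uniform axis in its normal plane by N(0, sigma2)."""
    angle = rng.normal(0.0, np.sqrt(sigma2)) if sigma2 > 0.0 else 0.0
    axis = _perpendicular_direction(d, rng)
    # Rodrigues rotation; axis is perpendicular to d
    return (np.cos(angle) * d + np.sin(angle) * np.cross(axis, d))


def update_direction(d: np.ndarray, d_v: np.ndarray, grad_gf: np.ndarray,
                     rng: np.random.Generator,
                     params: Parameters) -> np.ndarray:
    """New unit growth direction from randomization, homing and chemotaxis.

    d' is a random rotation of d (axis uniform in the plane normal to d,
    angle ~ N(0, sigma_s)); the steering cues are added as
    d'' = d' + k_V d_V + k_GF grad C_GF and the result renormalized.
    A vanishing resultant falls back to d'.
    """
    d = np.asarray(d, dtype=float)
    d = d / np.linalg.norm(d)
    d_prime = _random_rotation(d, params.sigma_s, rng)
    d_new = d_prime + params.k_v * np.asarray(d_v) \
        + params.k_gf_dir * np.asarray(grad_gf)
    n = np.linalg.norm(d_new)
    if n < 1e-12:
        return d_prime
    return d_new / n


@dataclass
class ConnectionEvent:
    tip_segment: int
    target_segment: int | None
    node_id: int
    position: np.ndarray


def _nearest_foreign_segment(net: VesselNetwork, point: np.ndarray,
                             exclude: set[int], arrays=None):
    """Closest segment to a point (periodic): (seg id, parameter t, dist)."""
    sids, a, vec, lengths = arrays if arrays is not None \
        else net.segment_arrays()
    if not len(sids):
        return None, 0.0, np.inf
    keep = np.ones(len(sids), dtype=bool)
    if exclude:
        keep = ~np.isin(sids, list(exclude))
    if not np.any(keep):
        return None, 0.0, np.inf
    sids, a, vec = sids[keep], a[keep], vec[keep]
    rel_a = net.domain.displacement_many(point, a)  # point -> segment start
    ap = -rel_a
    len2 = np.maximum(np.einsum("ij,ij->i", vec, vec), 1e-18)
    t = np.clip(np.einsum("ij,ij->i", ap, vec) / len2, 0.0, 1.0)
    d = np.linalg.norm(ap - t[:, None] * vec, axis=1)
    i = int(np.argmin(d))
    return int(sids[i]), float(t[i]), float(d[i])


def _chain_exclusion(net: VesselNetwork, tip: SproutTip) -> set[int]:
    """The tip's own chain plus segments sharing its root node."""
    excl = set(tip.chain)
    if tip.chain:
        root_seg = net.segments.get(tip.chain[0])
        if root_seg is not None:
            root = root_seg.from_node
            for sid, s in net.segments.items():
                if root in (s.from_node, s.to_node):
                    excl.add(sid)
    return excl


def elongate_and_connect(net: VesselNetwork, gf_state, rng: RNGStreams,
                         params: Parameters) -> list[ConnectionEvent]:
    """Advance every tip one time step; create connections within reach.

    Each tip first updates its direction (random rotation, homing,
    GF gradient), then advances V_g * dt along it in 5 um increments.
    After each increment the tip checks for a foreign segment within the
    connection distance; if found, a junction node is created at the
    closest point (splitting the target unless an existing node is
    within the merge snap), the sprout connects and the tip retires.
    Two tips within reach of each other fuse. At most one connection
    forms per tip per step. Positions wrap periodically.
    """
    events: list[ConnectionEvent] = []
    steer = rng["steering"]
    advance_total = params.v_g * params.dt
    tips_done: list[SproutTip] = []
    boundary_nodes = set(net.boundary_nodes())
    for tip in list(net.tips):
        if tip.tip_segment not in net.segments:
            continue
        arrays = net.segment_arrays()
        excl = _chain_exclusion(net, tip)
        # never connect onto the fixed-resistance inlet stub: it stands
        # for upstream vasculature outside the domain
        excl |= {s.id for s in net.segments.values() if s.status == FIXED}
        d_v = homing_vector(tip.position, tip.direction, net, params,
                            exclude=excl, arrays=arrays)
        grad = gf_state.gradient(tip.position[None, :])[0] \
            if gf_state is not None else np.zeros(3)
        direction = update_direction(tip.direction, d_v, grad, steer, params)
        remaining = advance_total
        pos = tip.position.copy()
        connected = False
        while remaining > 1e-9 and not connected:
            inc = min(params.growth_increment, remaining)
            pos = pos + inc * direction
            remaining -= inc
            sid, t, dist = _nearest_foreign_segment(
                net, net.domain.wrap(pos), excl, arrays=arrays)
            if sid is not None and dist <= params.connect_distance:
                seg = net.segments[sid]
                length = net.segment_length(seg)
                snap = params.connect_distance / max(length, 1e-9)
                if t < snap:
                    junction = seg.from_node
                elif t > 1.0 - snap:
                    junction = seg.to_node
                else:
                    junction = None
                if junction is not None and junction in boundary_nodes:
                    continue  # a shunt straight into a pressure boundary
                if junction is None:
                    junction = net.split_segment(sid, t)
                if junction == tip.tip_node or net.domain.distance(
                        net.nodes[junction].position,
                        net.nodes[tip.tip_node].position) < 1e-6:
                    # target already touches the tip node (e.g. another
                    # sprout connected onto it earlier): nothing to add
                    connected = True
                    events.append(ConnectionEvent(
                        tip_segment=tip.tip_segment, target_segment=sid,
                        node_id=junction,
                        position=net.nodes[junction].position.copy()))
                    break
                new_seg = net.add_segment(tip.tip_node, junction,
                                          params.d_sprout, status=SPROUT)
                tip.chain.append(new_seg)
                events.append(ConnectionEvent(
                    tip_segment=tip.tip_segment, target_segment=sid,
                    node_id=junction,
                    position=net.nodes[junction].position.copy()))
                connected = True
        if not connected:
            # lay down the step's growth as one new segment
            new_node = net.add_node(pos)
            new_seg = net.add_segment(tip.tip_node, new_node,
                                      params.d_sprout, status=SPROUT)
            tip.chain.append(new_seg)
            tip.tip_node = new_node
            tip.tip_segment = new_seg
            tip.position = net.nodes[new_node].position.copy()
            tip.direction = direction
            tip.age += params.dt
        else:
            tips_done.append(tip)
    for tip in tips_done:
        if tip in net.tips:
            net.tips.remove(tip)
    if events:
        net.update_statuses()
    return events
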