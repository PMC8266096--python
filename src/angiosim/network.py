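"""Vascular graph data model, initial configuration and fixtures.

A :class:`VesselNetwork` is a graph of :class:`Node` and :class:`Segment`
objects embedded in a periodic :class:`~angiosim.geometry.HexDomain`.
Node positions are stored in canonical (wrapped) coordinates; segment
geometry is always interpreted through the minimal-image displacement of
its endpoints, so segments must be shorter than half the cell width
(guaranteed by the ~20 um discretization).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .geometry import HexDomain, build_hex_domain, point_segment_distance
from .parameters import Parameters

__all__ = [
    "Node", "Segment", "SproutTip", "VesselNetwork",
    "make_initial_network", "classify_segments",
    "distance_to_nearest_flowing_vessel",
    "single_vessel_network", "y_bifurcation_network", "seven_segment_tree",
]

FLOWING = "flowing"
SPROUT = "sprout"
FIXED = "fixed_resistance"


@dataclass(eq=False)
class Node:
    id: int
    position: np.ndarray  # canonical, um
    boundary_kind: str = "none"  # none | inflow_pressure | outflow_pressure
    boundary_pressure: float = 0.0  # mmHg
    boundary_po2: float = 0.0  # mmHg (inflow only)
    pressure: float = np.nan  # mmHg, set by the flow solver


@dataclass(eq=False)
class Segment:
    id: int
    from_node: int
    to_node: int
    diameter: float  # um
    status: str = FLOWING  # flowing | sprout | fixed_resistance
    flow: float = 0.0  # nl/min, signed from_node -> to_node
    hd: float = 0.0  # discharge hematocrit
    wss: float = 0.0  # dyn/cm^2
    classification: str = "unclassified"


@dataclass(eq=False)
class SproutTip:
    """A growing sprout tip and its bookkeeping.

    ``chain`` lists the segment ids laid down by this sprout in growth
    order; ``tip_node`` is the current blind end.
    """
    position: np.ndarray
    direction: np.ndarray  # unit vector
    tip_node: int
    tip_segment: int
    age: float = 0.0  # days
    chain: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            self.direction = self.direction / n


class VesselNetwork:
    """Mutable vessel network over a periodic hexagonal domain."""

    def __init__(self, domain: HexDomain):
        self.domain = domain
        self.nodes: dict[int, Node] = {}
        self.segments: dict[int, Segment] = {}
        self.tips: list[SproutTip] = []
        #: named segment-id sets whose membership survives splitting
        #: (e.g. the initial pial A-V bridge)
        self.tracked_groups: dict[str, set[int]] = {}
        self._node_counter = itertools.count()
        self._seg_counter = itertools.count()

    # -- construction ----------------------------------------------------

    def add_node(self, position, **kw) -> int:
        nid = next(self._node_counter)
        pos = self.domain.wrap(np.asarray(position, dtype=float))
        self.nodes[nid] = Node(id=nid, position=pos, **kw)
        return nid

    def add_segment(self, from_node: int, to_node: int, diameter: float,
                    status: str = FLOWING, **kw) -> int:
        if from_node not in self.nodes or to_node not in self.nodes:
            raise KeyError("segment endpoints must exist")
        if from_node == to_node:
            raise ValueError("self-loop segments are not allowed")
        if diameter <= 0.0:
            raise ValueError("diameter must be positive")
        sid = next(self._seg_counter)
        self.segments[sid] = Segment(id=sid, from_node=from_node,
                                     to_node=to_node, diameter=diameter,
                                     status=status, **kw)
        return sid

    # -- geometry ----------------------------------------------------------

    def segment_vector(self, seg: Segment) -> np.ndarray:
        """Minimal-image displacement from from_node to to_node (um)."""
        return self.domain.displacement(self.nodes[seg.from_node].position,
                                        self.nodes[seg.to_node].position)

    def segment_length(self, seg: Segment) -> float:
        return float(np.linalg.norm(self.segment_vector(seg)))

    def segment_midpoint(self, seg: Segment) -> np.ndarray:
        a = self.nodes[seg.from_node].position
        return self.domain.wrap(a + 0.5 * self.segment_vector(seg))

    def segment_point(self, seg: Segment, t: float) -> np.ndarray:
        a = self.nodes[seg.from_node].position
        return self.domain.wrap(a + t * self.segment_vector(seg))

    # -- topology ----------------------------------------------------------

    def node_segments(self, statuses=None) -> dict[int, list[int]]:
        """Map node id -> incident segment ids (optionally filtered)."""
        adj: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for sid, seg in self.segments.items():
            if statuses is not None and seg.status not in statuses:
                continue
            adj[seg.from_node].append(sid)
            adj[seg.to_node].append(sid)
        return adj

    def degree(self, node_id: int) -> int:
        return sum(1 for s in self.segments.values()
                   if node_id in (s.from_node, s.to_node))

    def boundary_nodes(self, kind: str | None = None) -> list[int]:
        out = []
        for nid, n in self.nodes.items():
            if n.boundary_kind == "none":
                continue
            if kind is None or n.boundary_kind == kind:
                out.append(nid)
        return out

    def segments_by_status(self, *statuses: str) -> list[Segment]:
        return [s for s in self.segments.values() if s.status in statuses]

    def conducting_segments(self) -> list[Segment]:
        """Segments that carry blood: flowing plus fixed-resistance."""
        return self.segments_by_status(FLOWING, FIXED)

    def split_segment(self, seg_id: int, t: float) -> int:
        """Split a segment at parameter t in (0, 1); return the new node id.

        The original segment keeps its id on the from-side; a new segment
        with the same attributes covers the to-side.
        """
        seg = self.segments[seg_id]
        if not 0.0 < t < 1.0:
            raise ValueError("split parameter must be strictly inside (0, 1)")
        pos = self.segment_point(seg, t)
        new_node = self.add_node(pos)
        old_to = seg.to_node
        new_seg = self.add_segment(new_node, old_to, seg.diameter,
                                   status=seg.status, flow=seg.flow,
                                   hd=seg.hd, wss=seg.wss,
                                   classification=seg.classification)
        seg.to_node = new_node
        for tip in self.tips:
            if seg_id in tip.chain:
                i = tip.chain.index(seg_id)
                tip.chain[i:i + 1] = [seg_id, new_seg]
        for group in self.tracked_groups.values():
            if seg_id in group:
                group.add(new_seg)
        return new_node

    def remove_segments(self, seg_ids) -> None:
        for sid in seg_ids:
            self.segments.pop(sid, None)
            for group in self.tracked_groups.values():
                group.discard(sid)
        used = set()
        for s in self.segments.values():
            used.add(s.from_node)
            used.add(s.to_node)
        for nid in [n for n in self.nodes if n not in used]:
            del self.nodes[nid]
        self.tips = [t for t in self.tips
                     if t.tip_segment in self.segments]

    # -- flow-core computation --------------------------------------------

    def flow_core(self) -> set[int]:
        """Segment ids lying on some simple inflow-to-outflow path.

        Only these segments can carry flow. Computed by keeping the
        connected components containing both boundary kinds, then
        iteratively peeling dangling nodes and pendant biconnected
        blocks (blocks touching the rest of the graph at a single
        articulation node and containing no boundary node): what
        survives is exactly the union of simple paths between the
        pressure boundaries.
        """
        import networkx as nx

        g = nx.Graph()
        pair_segments: dict[frozenset, list[int]] = {}
        for sid, s in self.segments.items():
            g.add_edge(s.from_node, s.to_node)
            pair_segments.setdefault(
                frozenset((s.from_node, s.to_node)), []).append(sid)
        sources = set(self.boundary_nodes("inflow_pressure"))
        sinks = set(self.boundary_nodes("outflow_pressure"))
        keep: set[int] = set()
        for comp in list(nx.connected_components(g)):
            if not (sources & comp and sinks & comp):
                continue
            h = g.subgraph(comp).copy()
            terminals = (sources | sinks) & comp
            while True:
                leaves = [n for n in h
                          if h.degree(n) <= 1 and n not in terminals]
                if leaves:
                    h.remove_nodes_from(leaves)
                    continue
                arts = set(nx.articulation_points(h))
                peeled = False
                for block in nx.biconnected_components(h):
                    touch = block & arts
                    inner = block - touch
                    if len(touch) == 1 and not (inner & terminals):
                        h.remove_nodes_from(inner)
                        peeled = True
                        break
                if not peeled:
                    break
            for u, v in h.edges:
                keep.update(pair_segments.get(frozenset((u, v)), []))
        return keep

    def update_statuses(self) -> bool:
        """Promote sprout segments that joined the flow core to flowing.

        Returns True if any status changed.
        """
        core = self.flow_core()
        changed = False
        for sid in core:
            seg = self.segments[sid]
            if seg.status == SPROUT:
                seg.status = FLOWING
                changed = True
        if changed:
            # tips whose chain became flowing are retired
            self.tips = [t for t in self.tips
                         if self.segments[t.tip_segment].status == SPROUT]
        return changed

    def segment_arrays(self):
        """Array view of segment geometry for vectorized queries.

        Returns (seg_ids, start_positions, minimal-image vectors,
        lengths) over all segments, in sorted id order.
        """
        sids = sorted(self.segments)
        if not sids:
            z = np.zeros((0, 3))
            return np.array([], dtype=int), z, z, np.zeros(0)
        a = np.array([self.nodes[self.segments[s].from_node].position
                      for s in sids])
        b = np.array([self.nodes[self.segments[s].to_node].position
                      for s in sids])
        vec = self.domain.reduce_displacements(b - a)
        lengths = np.linalg.norm(vec, axis=1)
        return np.array(sids, dtype=int), a, vec, lengths

    def check_consistent(self) -> None:
        """Raise AssertionError on graph inconsistencies."""
        for s in self.segments.values():
            assert s.from_node in self.nodes and s.to_node in self.nodes
            assert self.segment_length(s) > 1e-9, "zero-length segment"
            assert s.diameter > 0.0
        for t in self.tips:
            assert t.tip_segment in self.segments
            assert t.tip_node in self.nodes
            assert abs(np.linalg.norm(t.direction) - 1.0) < 1e-9


# -- initial configuration and fixtures ----------------------------------


def make_initial_network(params: Parameters,
                         domain: HexDomain | None = None) -> VesselNetwork:
    """Build the initial state: one pial vessel plus two sprouts.

    The pial vessel runs along x through the domain center on the top
    face (z = 0), between a pressure inflow node (on the -x side) and a
    pressure outflow node, closed periodically so the flow path spans
    the full cell width. It contains the narrow fixed-resistance inlet
    segment (7 um x 35 um by default). Two straight sprouts of length
    400 um and diameter ``d_sprout`` extend perpendicular to the pial
    surface into the tissue, one from the arteriolar side and one from
    the venular side. Deterministic: consumes no randomness.
    """
    if domain is None:
        domain = build_hex_domain(params.hex_side, params.hex_height)
    net = VesselNetwork(domain)
    a = domain.side
    # Pial path spans the top face from vertex (-a) to vertex (+a) along x.
    # Inflow at x = -a; the fixed-resistance segment immediately downstream.
    inflow = net.add_node([-a, 0.0, 0.0], boundary_kind="inflow_pressure",
                          boundary_pressure=params.inflow_pressure,
                          boundary_po2=params.inflow_po2)
    outflow = net.add_node([a - 1e-9, 0.0, 0.0],
                           boundary_kind="outflow_pressure",
                           boundary_pressure=params.outflow_pressure)
    x0 = -a + params.fixed_segment_length
    post_fixed = net.add_node([x0, 0.0, 0.0])
    net.add_segment(inflow, post_fixed, params.fixed_segment_diameter,
                    status=FIXED)
    # remaining pial run split into ~seg_target_length pieces
    remaining = 2.0 * a - params.fixed_segment_length
    n_sub = max(1, int(round(remaining / params.seg_target_length)))
    xs = np.linspace(x0, a, n_sub + 1)[1:]
    prev = post_fixed
    sprout_anchor_art = post_fixed  # sprout off the arteriolar side
    sprout_anchor_ven = None
    for i, x in enumerate(xs):
        if i == len(xs) - 1:
            nid = outflow
        else:
            nid = net.add_node([x, 0.0, 0.0])
        net.add_segment(prev, nid, params.pial_vessel_diameter,
                        status=FLOWING)
        if sprout_anchor_ven is None and x >= a - params.seg_target_length * 1.5:
            sprout_anchor_ven = prev
        prev = nid
    if sprout_anchor_ven is None:
        sprout_anchor_ven = prev
    # two perpendicular sprouts descending into the tissue (+z)
    down = np.array([0.0, 0.0, 1.0])
    for anchor in (sprout_anchor_art, sprout_anchor_ven):
        base = net.nodes[anchor].position
        n_sub_s = max(1, int(round(params.sprout_initial_length
                                   / params.seg_target_length)))
        zs = np.linspace(0.0, params.sprout_initial_length, n_sub_s + 1)[1:]
        prev_n = anchor
        chain = []
        tip_node = anchor
        tip_seg = None
        for z in zs:
            tip_node = net.add_node(base + z * down)
            tip_seg = net.add_segment(prev_n, tip_node, params.d_sprout,
                                      status=SPROUT)
            chain.append(tip_seg)
            prev_n = tip_node
        net.tips.append(SproutTip(position=net.nodes[tip_node].position.copy(),
                                  direction=down.copy(), tip_node=tip_node,
                                  tip_segment=tip_seg, chain=chain))
    net.tracked_groups["pial_bridge"] = {
        s.id for s in net.segments_by_status(FLOWING)}
    return net


def single_vessel_network(length: float = 300.0, diameter: float = 10.0,
                          n_sub: int = 15,
                          domain: HexDomain | None = None,
                          inflow_pressure: float = 100.0,
                          outflow_pressure: float = 20.0,
                          inflow_po2: float = 100.0,
                          axis: int = 2, offset=None) -> VesselNetwork:
    """A single straight vessel, optionally along any axis (Krogh fixture)."""
    if domain is None:
        domain = build_hex_domain(150.0, max(500.0, length + 20.0))
    net = VesselNetwork(domain)
    direction = np.zeros(3)
    direction[axis] = 1.0
    start = np.zeros(3) if offset is None else np.asarray(offset, float)
    ts = np.linspace(0.0, length, n_sub + 1)
    prev = net.add_node(start, boundary_kind="inflow_pressure",
                        boundary_pressure=inflow_pressure,
                        boundary_po2=inflow_po2)
    for i, t in enumerate(ts[1:]):
        if i == n_sub - 1:
            nid = net.add_node(start + t * direction,
                               boundary_kind="outflow_pressure",
                               boundary_pressure=outflow_pressure)
        else:
            nid = net.add_node(start + t * direction)
        net.add_segment(prev, nid, diameter)
        prev = nid
    return net


def y_bifurcation_network(parent_d: float = 12.0, daughter_d: float = 8.0,
                          seg_len: float = 100.0,
                          asymmetric: bool = False) -> VesselNetwork:
    """A diverging Y with two daughters reconverging on paper: open tree.

    Parent from an inflow node splits at a junction into two daughters,
    each ending at an outflow node.
    """
    domain = build_hex_domain(300.0, 600.0)
    net = VesselNetwork(domain)
    n_in = net.add_node([0, 0, 50], boundary_kind="inflow_pressure",
                        boundary_pressure=100.0, boundary_po2=100.0)
    n_j = net.add_node([0, 0, 50 + seg_len])
    net.add_segment(n_in, n_j, parent_d)
    d2 = daughter_d * (0.75 if asymmetric else 1.0)
    n_o1 = net.add_node([60, 0, 50 + seg_len + 80],
                        boundary_kind="outflow_pressure",
                        boundary_pressure=20.0)
    n_o2 = net.add_node([-60, 0, 50 + seg_len + 80],
                        boundary_kind="outflow_pressure",
                        boundary_pressure=20.0)
    net.add_segment(n_j, n_o1, daughter_d)
    net.add_segment(n_j, n_o2, d2)
    return net


def seven_segment_tree() -> VesselNetwork:
    """Hand-built 7-segment diverging/converging tree for classification.

    Topology: inflow - s0 - (split) - s1/s2 - each splits/merges so the
    tree exercises all four bifurcation-type combinations.
    """
    domain = build_hex_domain(400.0, 800.0)
    net = VesselNetwork(domain)
    n_in = net.add_node([-150, 0, 100], boundary_kind="inflow_pressure",
                        boundary_pressure=100.0, boundary_po2=100.0)
    n_a = net.add_node([-90, 0, 100])
    n_b = net.add_node([-30, 50, 100])
    n_c = net.add_node([-30, -50, 100])
    n_d = net.add_node([30, 0, 100])
    n_out = net.add_node([150, 0, 100], boundary_kind="outflow_pressure",
                         boundary_pressure=20.0)
    net.add_segment(n_in, n_a, 14.0)   # s0: inflow -> diverging
    net.add_segment(n_a, n_b, 9.0)     # s1: diverging -> converging
    net.add_segment(n_a, n_c, 9.0)     # s2: diverging -> converging
    net.add_segment(n_b, n_d, 8.0)     # s3
    net.add_segment(n_c, n_d, 8.0)     # s4
    net.add_segment(n_d, n_out, 13.0)  # s5: converging -> outflow
    # extra capillary bridging b -> c to create mixed node types
    net.add_segment(n_b, n_c, 6.0)     # s6
    return net


# -- classification -------------------------------------------------------


def classify_segments(net: VesselNetwork) -> None:
    """Label flowing segments by their end-bifurcation types.

    Node types follow the flow solution: a node is *diverging* if flow
    splits there (one or more inflows, several outflows) and *converging*
    if flows merge. Labels: arteriolar (diverging -> diverging), venular
    (converging -> converging), capillary (diverging -> converging) and
    mesh (converging -> diverging). Unbranched interior nodes transmit
    the type seen at the nearest true bifurcation upstream/downstream;
    pressure inflow boundaries count as diverging ends and outflow
    boundaries as converging ends.
    """
    conducting = {s.id: s for s in net.conducting_segments()}
    if any(np.isnan(net.nodes[s.from_node].pressure) for s in
           conducting.values()):
        raise RuntimeError("classification requires solved flows")

    adj: dict[int, list[int]] = {}
    for s in conducting.values():
        adj.setdefault(s.from_node, []).append(s.id)
        adj.setdefault(s.to_node, []).append(s.id)

    def outflows(nid):
        out = []
        for sid in adj.get(nid, []):
            s = conducting[sid]
            q = s.flow if s.from_node == nid else -s.flow
            if q > 1e-12:
                out.append(sid)
        return out

    def inflows(nid):
        return [sid for sid in adj.get(nid, []) if sid not in outflows(nid)
                and abs(conducting[sid].flow) > 1e-12]

    def node_type(nid):
        node = net.nodes[nid]
        if node.boundary_kind == "inflow_pressure":
            return "diverging"
        if node.boundary_kind == "outflow_pressure":
            return "converging"
        n_in = len(inflows(nid))
        n_out = len(outflows(nid))
        if n_in <= 1 and n_out <= 1:
            return "transit"  # unbranched: transmits neighbor type
        if n_out > 1:
            return "diverging"
        return "converging"

    def upstream_type(seg):
        """Type at the upstream end, walking through transit nodes."""
        seen = set()
        s = seg
        while True:
            nid = s.from_node if s.flow >= 0 else s.to_node
            t = node_type(nid)
            if t != "transit":
                return t
            ins = inflows(nid)
            ins = [i for i in ins if i != s.id and i not in seen]
            if not ins:
                return "diverging"
            seen.add(s.id)
            s = conducting[ins[0]]

    def downstream_type(seg):
        seen = set()
        s = seg
        while True:
            nid = s.to_node if s.flow >= 0 else s.from_node
            t = node_type(nid)
            if t != "transit":
                return t
            outs = [o for o in outflows(nid) if o != s.id and o not in seen]
            if not outs:
                return "converging"
            seen.add(s.id)
            s = conducting[outs[0]]

    label = {("diverging", "diverging"): "arteriolar",
             ("converging", "converging"): "venular",
             ("diverging", "converging"): "capillary",
             ("converging", "diverging"): "mesh"}
    for s in conducting.values():
        if abs(s.flow) <= 1e-12:
            s.classification = "unclassified"
            continue
        s.classification = label[(upstream_type(s), downstream_type(s))]


def distance_to_nearest_flowing_vessel(points, net: VesselNetwork
                                       ) -> np.ndarray:
    """Periodic-aware distance of points to the nearest flowing segment.

    Returns +inf where the network has no conducting segments.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    best = np.full(len(points), np.inf)
    for s in net.conducting_segments():
        a = net.nodes[s.from_node].position
        b = net.nodes[s.to_node].position
        d = point_segment_distance(points, a, b, net.domain)
        best = np.minimum(best, d)
    return best
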