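"""Network and field snapshots: CSV tables and legacy-VTK polydata.

The interchange surface is a pair of plain-text CSV tables:

``nodes.csv``
    id, x, y, z (um), boundary_kind, boundary_pressure (mmHg),
    boundary_po2 (mmHg), pressure (mmHg)
``segments.csv``
    id, from_node, to_node, diameter (um), length (um), status,
    flow (nl/min), hematocrit, wss (dyn/cm2), classification

VTK output is ASCII legacy polydata with one line cell per segment
(two for segments crossing a periodic boundary, drawn through ghost
points) and per-cell scalars for diameter, flow and classification.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import HexDomain
from .network import VesselNetwork

__all__ = ["export_network", "import_network", "export_vtk",
           "export_fields_csv"]

_CLASS_CODE = {"unclassified": 0, "arteriolar": 1, "venular": 2,
               "capillary": 3, "mesh": 4}


def export_network(net: VesselNetwork, directory: str | Path) -> None:
    """Write nodes.csv and segments.csv into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame([
        dict(id=n.id, x=n.position[0], y=n.position[1], z=n.position[2],
             boundary_kind=n.boundary_kind,
             boundary_pressure=n.boundary_pressure,
             boundary_po2=n.boundary_po2, pressure=n.pressure)
        for n in net.nodes.values()]).sort_values("id")
    segments = pd.DataFrame([
        dict(id=s.id, from_node=s.from_node, to_node=s.to_node,
             diameter=s.diameter, length=net.segment_length(s),
             status=s.status, flow=s.flow, hematocrit=s.hd, wss=s.wss,
             classification=s.classification)
        for s in net.segments.values()]).sort_values("id")
    nodes.to_csv(directory / "nodes.csv", index=False)
    segments.to_csv(directory / "segments.csv", index=False)


def import_network(directory: str | Path, domain: HexDomain
                   ) -> VesselNetwork:
    """Rebuild a network from the CSV tables written by export_network."""
    directory = Path(directory)
    nodes = pd.read_csv(directory / "nodes.csv")
    segments = pd.read_csv(directory / "segments.csv")
    net = VesselNetwork(domain)
    id_map = {}
    for row in nodes.itertuples():
        kind = row.boundary_kind if isinstance(row.boundary_kind, str) \
            else "none"
        nid = net.add_node([row.x, row.y, row.z], boundary_kind=kind,
                           boundary_pressure=row.boundary_pressure,
                           boundary_po2=row.boundary_po2)
        net.nodes[nid].pressure = row.pressure
        id_map[row.id] = nid
    for row in segments.itertuples():
        net.add_segment(id_map[row.from_node], id_map[row.to_node],
                        row.diameter, status=row.status, flow=row.flow,
                        hd=row.hematocrit, wss=row.wss,
                        classification=row.classification)
    return net


def export_vtk(net: VesselNetwork, path: str | Path,
               segment_po2: dict[int, float] | None = None,
               s_tot: dict[int, float] | None = None) -> None:
    """Write the network as ASCII legacy VTK polydata.

    Periodic segments are emitted as two half-lines through ghost
    points so the rendering does not draw spurious chords across the
    cell; both halves carry the parent segment's cell data.
    """
    points: list[np.ndarray] = []
    lines: list[tuple[int, int]] = []
    cell_seg: list[int] = []

    def add_point(p) -> int:
        points.append(np.asarray(p, dtype=float))
        return len(points) - 1

    for sid in sorted(net.segments):
        s = net.segments[sid]
        a = net.nodes[s.from_node].position
        b = net.nodes[s.to_node].position
        vec = net.segment_vector(s)
        if np.allclose(a + vec, b, atol=1e-6):
            lines.append((add_point(a), add_point(b)))
            cell_seg.append(sid)
        else:  # crosses a periodic boundary: draw both images
            lines.append((add_point(a), add_point(a + vec)))
            cell_seg.append(sid)
            lines.append((add_point(b - vec), add_point(b)))
            cell_seg.append(sid)

    def cell_values(mapping, default=0.0):
        if mapping is None:
            mapping = {}
        return [mapping.get(sid, default) for sid in cell_seg]

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("angiosim vessel network\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} float\n")
        for p in points:
            fh.write(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
        fh.write(f"\nLINES {len(lines)} {3 * len(lines)}\n")
        for i, j in lines:
            fh.write(f"2 {i} {j}\n")
        fh.write(f"\nCELL_DATA {len(lines)}\n")
        scalars = {
            "diameter": [net.segments[sid].diameter for sid in cell_seg],
            "flow": [net.segments[sid].flow for sid in cell_seg],
            "hematocrit": [net.segments[sid].hd for sid in cell_seg],
            "classification": [
                float(_CLASS_CODE.get(net.segments[sid].classification, 0))
                for sid in cell_seg],
            "po2": cell_values(segment_po2),
            "s_tot": cell_values(s_tot),
        }
        for name, values in scalars.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for v in values:
                fh.write(f"{v:.6g}\n")


def export_fields_csv(points: np.ndarray, po2: np.ndarray,
                      c_gf: np.ndarray, path: str | Path) -> None:
    """Write the tissue point cloud with its fields as CSV."""
    df = pd.DataFrame({
        "x": points[:, 0], "y": points[:, 1], "z": points[:, 2],
        "po2": po2, "c_gf": c_gf,
    })
    df.to_csv(path, index=False)
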