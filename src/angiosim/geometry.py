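"""Hexagonally periodic tissue geometry.

The tissue is a hexagonal prism. The hexagon has a pair of opposite
vertices on the x-axis, so its six vertices sit at angles 0, 60, ...,
300 degrees, at distance ``side`` from the center. Edge normals point
at 30, 90 and 150 degrees, and the apothem (center-to-edge distance) is
``sqrt(3)/2 * side``.

In-plane periodicity is that of the triangular lattice whose Voronoi
cell is exactly this hexagon: the two generating translations have
magnitude ``sqrt(3) * side`` and are 60 degrees apart. Wrapping a point
therefore means picking the lattice translate closest to the hexagon
center (minimal image). The z-axis points from the pial surface (z = 0)
into the tissue (z = height) and is not periodic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HexDomain",
    "TissueGrid",
    "build_hex_domain",
    "wrap_point",
    "generate_tissue_grid",
    "point_segment_distance",
]


@dataclass
class HexDomain:
    """Hexagonal prism with in-plane periodic boundary conditions.

    Parameters
    ----------
    side
        Side length of the hexagon (um). Also the center-to-vertex distance.
    height
        Prism height (um); z runs from 0 (pial surface) to ``height``.
    """

    side: float
    height: float
    lattice_vectors: np.ndarray = field(init=False)
    center: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.side <= 0.0 or self.height <= 0.0:
            raise ValueError("side and height must be positive")
        a = float(self.side)
        m = np.sqrt(3.0) * a
        # translations toward neighbor cell centers at 30 and 90 degrees
        v1 = m * np.array([np.cos(np.pi / 6.0), np.sin(np.pi / 6.0)])
        v2 = m * np.array([0.0, 1.0])
        self.lattice_vectors = np.vstack([v1, v2])
        self.center = np.array([0.0, 0.0, self.height / 2.0])
        # edge normals (unit), apothem
        angles = np.array([np.pi / 6.0, np.pi / 2.0, 5.0 * np.pi / 6.0])
        self._normals = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        self._apothem = np.sqrt(3.0) / 2.0 * a
        # the 6 nearest-neighbor in-plane offsets (3D, z = 0)
        offs = []
        for i, j in ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)):
            o = i * v1 + j * v2
            offs.append([o[0], o[1], 0.0])
        self._neighbor_offsets = np.array(offs)
        self._all_offsets = np.vstack([np.zeros((1, 3)), self._neighbor_offsets])

    # -- basic measures -------------------------------------------------

    @property
    def cross_section_area(self) -> float:
        """Hexagon area, 3*sqrt(3)/2 * side^2 (um^2)."""
        return 3.0 * np.sqrt(3.0) / 2.0 * self.side ** 2

    @property
    def volume(self) -> float:
        """Prism volume (um^3)."""
        return self.cross_section_area * self.height

    @property
    def apothem(self) -> float:
        return self._apothem

    def neighbor_offsets(self) -> np.ndarray:
        """The 6 in-plane translations to neighboring cells, shape (6, 3)."""
        return self._neighbor_offsets.copy()

    def image_offsets(self) -> np.ndarray:
        """Identity plus the 6 neighbor translations, shape (7, 3)."""
        return self._all_offsets.copy()

    # -- periodic wrapping ---------------------------------------------

    def contains_xy(self, p: np.ndarray, tol: float = 1e-9) -> bool:
        """Whether the in-plane projection of ``p`` lies in the hexagon."""
        d = np.abs(self._normals @ np.asarray(p, dtype=float)[:2])
        return bool(np.all(d <= self._apothem + tol))

    def wrap(self, p: np.ndarray) -> np.ndarray:
        """Return the canonical (minimal-image) representative of ``p``.

        Only x and y are wrapped; z is returned unchanged. Points exactly
        on the cell boundary are resolved deterministically (smallest
        wrapped (x, y) in lexicographic order among ties).
        """
        p = np.asarray(p, dtype=float)
        xy = p[:2].copy()
        # reduce to near the origin using fractional lattice coordinates
        m = self.lattice_vectors.T  # columns are v1, v2
        frac = np.linalg.solve(m, xy)
        xy = xy - m @ np.round(frac)
        # minimal image among the 7 candidates
        cand = xy[None, :] - self._all_offsets[:, :2]
        d2 = np.einsum("ij,ij->i", cand, cand)
        d2r = np.round(d2, 6)
        order = np.lexsort((np.round(cand[:, 1], 6), np.round(cand[:, 0], 6), d2r))
        best = cand[order[0]]
        return np.array([best[0], best[1], p[2]])

    def wrap_many(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return np.array([self.wrap(p) for p in pts])

    def displacement(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Minimal-image displacement vector from ``a`` to ``b`` (3D)."""
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        d = b - a
        m = self.lattice_vectors.T
        frac = np.linalg.solve(m, d[:2])
        d2d = d[:2] - m @ np.round(frac)
        cand = d2d[None, :] - self._all_offsets[:, :2]
        n2 = np.einsum("ij,ij->i", cand, cand)
        best = cand[int(np.argmin(n2))]
        return np.array([best[0], best[1], d[2]])

    def distance(self, a: np.ndarray, b: np.ndarray) -> float:
        """Minimal-image distance between two points (um)."""
        return float(np.linalg.norm(self.displacement(a, b)))

    def reduce_displacements(self, d: np.ndarray) -> np.ndarray:
        """Reduce an (n, 3) array of displacements to minimal images."""
        d = np.atleast_2d(np.asarray(d, dtype=float))
        m = self.lattice_vectors.T
        frac = np.linalg.solve(m, d[:, :2].T)
        d2d = d[:, :2] - (m @ np.round(frac)).T
        cand = d2d[:, None, :] - self._all_offsets[None, :, :2]
        n2 = np.einsum("ijk,ijk->ij", cand, cand)
        idx = np.argmin(n2, axis=1)
        best = cand[np.arange(len(d)), idx]
        return np.column_stack([best, d[:, 2]])

    def displacement_many(self, a: np.ndarray, pts: np.ndarray) -> np.ndarray:
        """Minimal-image displacements from point ``a`` to each of ``pts``."""
        a = np.asarray(a, dtype=float)
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return self.reduce_displacements(pts - a[None, :])


def build_hex_domain(side: float, height: float) -> HexDomain:
    """Construct the periodic hexagonal-prism tissue domain."""
    return HexDomain(side=side, height=height)


def wrap_point(p: np.ndarray, domain: HexDomain) -> np.ndarray:
    """Wrap a 3D point into the canonical hexagonal cell (z unchanged)."""
    return domain.wrap(p)


@dataclass
class TissueGrid:
    """Cubic lattice of tissue points inside the hexagonal prism.

    Points are cell-centered in z (planes at spacing/2, 3*spacing/2, ...)
    and laterally registered so that the lattice contains the hexagon
    center. Per-point state (oxygen partial pressure, growth-factor
    concentration) is stored as flat arrays aligned with ``points``.
    """

    spacing: float
    points: np.ndarray  # (n, 3) um
    po2: np.ndarray = field(default=None)  # mmHg
    c_gf: np.ndarray = field(default=None)  # dimensionless

    def __post_init__(self) -> None:
        n = len(self.points)
        if self.po2 is None:
            self.po2 = np.zeros(n)
        if self.c_gf is None:
            self.c_gf = np.zeros(n)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def point_volume(self) -> float:
        """Tissue volume represented by each point (um^3)."""
        return self.spacing ** 3


def generate_tissue_grid(domain: HexDomain, spacing: float) -> TissueGrid:
    """Generate the cubic array of tissue points inside the prism.

    Lateral registration places lattice points at integer multiples of
    ``spacing`` from the hexagon center; z planes are cell-centered.
    For the reference geometry (side 150 um, height 500 um, spacing
    20 um) this yields 147 points per plane x 25 planes = 3675 points.
    """
    if spacing <= 0.0:
        raise ValueError("spacing must be positive")
    if spacing > max(2.0 * domain.side, domain.height):
        raise ValueError("spacing exceeds the domain extent")
    zs = np.arange(spacing / 2.0, domain.height, spacing)
    nmax = int(np.ceil(domain.side / spacing)) + 1
    idx = np.arange(-nmax, nmax + 1)
    xx, yy = np.meshgrid(idx * spacing, idx * spacing, indexing="ij")
    lateral = np.stack([xx.ravel(), yy.ravel()], axis=1)
    d = np.abs(lateral @ domain._normals.T)
    inside = np.all(d <= domain.apothem + 1e-9, axis=1)
    lateral = lateral[inside]
    # deterministic ordering: sort by (x, y)
    order = np.lexsort((lateral[:, 1], lateral[:, 0]))
    lateral = lateral[order]
    pts = np.concatenate(
        [np.column_stack([lateral, np.full(len(lateral), z)]) for z in zs],
        axis=0,
    )
    return TissueGrid(spacing=spacing, points=pts)


def point_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray,
                           domain: HexDomain | None = None) -> np.ndarray:
    """Distance of each point to the straight segment a-b (um).

    With a domain, the minimum over the 7 periodic images of the segment
    is taken; segments are assumed shorter than half the cell width so a
    single minimal image per translate suffices.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    a = np.asarray(a, dtype=float)
    if domain is None:
        ab = np.asarray(b, dtype=float) - a
        offsets = np.zeros((1, 3))
    else:
        ab = domain.displacement(a, np.asarray(b, dtype=float))
        offsets = domain.image_offsets()
    len2 = float(ab @ ab)
    best = np.full(len(points), np.inf)
    for off in offsets:
        ao = a + off
        ap = points - ao[None, :]
        if len2 == 0.0:
            d = np.linalg.norm(ap, axis=1)
        else:
            t = np.clip(ap @ ab / len2, 0.0, 1.0)
            proj = ao[None, :] + t[:, None] * ab[None, :]
            d = np.linalg.norm(points - proj, axis=1)
        best = np.minimum(best, d)
    return best
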