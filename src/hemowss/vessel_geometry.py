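"""Vessel and branch morphometrics.

Quantifies branch take-off geometry and lumen calibre:

* angle α — between a branch (collateral) axis and the main-vessel wall
  tangent plane at the anastomosis, computed as 90° − angle(axis, normal);
* angle β — between the branch axis and a reference axis of the main
  vessel.  Published tables are ambiguous about whether this reference is
  a global vertical axis or the local centerline tangent of a curved
  vessel (the two differ for a curved aorta), so the reference vector is
  an explicit input;
* hydraulic diameter D_h = 4·area/perimeter of a lumen cross-section;
* equivalent-area diameters 2√(area/π), averaged along a branch.

Both angles are reported folded into [0°, 90°]: orientation conventions
of clinical measurements leave the sign undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Centerline",
    "BranchGeometry",
    "CrossSection",
    "branch_angles",
    "hydraulic_diameter",
    "mean_branch_diameter",
    "equivalent_diameter",
    "local_frame",
]


def _unit(v: np.ndarray, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError(f"zero-length {name}")
    return v / n


@dataclass(frozen=True)
class Centerline:
    """Ordered polyline through the vessel lumen, mm, with unit tangents."""

    points: np.ndarray           # (P, 3), mm
    tangents: np.ndarray = None  # (P, 3), unit; computed if omitted

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise ValueError("centerline needs at least 2 points of shape (P, 3)")
        seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seglen == 0):
            raise ValueError("consecutive centerline points must be distinct")
        object.__setattr__(self, "points", pts)
        if self.tangents is None:
            object.__setattr__(self, "tangents", _polyline_tangents(pts))
        else:
            tan = np.asarray(self.tangents, dtype=float)
            if tan.shape != pts.shape:
                raise ValueError("tangents must match points in shape")
            if not np.allclose(np.linalg.norm(tan, axis=1), 1.0, atol=1e-9):
                raise ValueError("tangents must be unit length")
            object.__setattr__(self, "tangents", tan)

    @property
    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at each point, mm, starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


def _polyline_tangents(pts: np.ndarray) -> np.ndarray:
    """Centered finite-difference tangents, one-sided at the ends."""
    tan = np.empty_like(pts)
    tan[1:-1] = pts[2:] - pts[:-2]
    tan[0] = pts[1] - pts[0]
    tan[-1] = pts[-1] - pts[-2]
    return tan / np.linalg.norm(tan, axis=1, keepdims=True)


@dataclass(frozen=True)
class BranchGeometry:
    """Branch take-off geometry at an anastomosis.

    ``reference_axis`` is the axis against which β is measured — either
    the main-vessel centerline tangent at the anastomosis or a global
    vertical axis, at the caller's discretion.
    """

    branch_axis: np.ndarray
    anastomosis: np.ndarray       # mm
    wall_normal: np.ndarray       # tangent-plane normal at the anastomosis
    reference_axis: np.ndarray    # β reference (centerline tangent or vertical)

    def __post_init__(self) -> None:
        object.__setattr__(self, "branch_axis", _unit(self.branch_axis, "branch axis"))
        object.__setattr__(self, "wall_normal", _unit(self.wall_normal, "wall normal"))
        object.__setattr__(self, "reference_axis", _unit(self.reference_axis, "reference axis"))
        object.__setattr__(
            self, "anastomosis", np.asarray(self.anastomosis, dtype=float).reshape(3)
        )


def _folded_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two unit vectors folded into [0°, 90°]."""
    return float(np.degrees(np.arccos(np.clip(abs(float(u @ v)), 0.0, 1.0))))


def branch_angles(geom: BranchGeometry) -> tuple[float, float]:
    """(α, β) in degrees, both folded into [0°, 90°].

    α = 90° − angle(branch axis, wall normal) — the elevation of the
    branch axis above the wall tangent plane.
    β = angle(branch axis, reference axis).
    """
    alpha = 90.0 - _folded_angle(geom.branch_axis, geom.wall_normal)
    beta = _folded_angle(geom.branch_axis, geom.reference_axis)
    return alpha, beta


@dataclass(frozen=True)
class CrossSection:
    """Planar closed lumen polygon, mm.  Vertices ordered around the loop."""

    vertices: np.ndarray  # (V, 3) or (V, 2), mm

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or len(verts) < 3:
            raise ValueError("cross-section needs at least 3 vertices")
        if verts.shape[1] == 2:
            verts = np.column_stack([verts, np.zeros(len(verts))])
        elif verts.shape[1] != 3:
            raise ValueError("vertices must be (V, 2) or (V, 3)")
        object.__setattr__(self, "vertices", verts)
        if self.area <= 0 or self.perimeter <= 0:
            raise ValueError("degenerate polygon (zero area or perimeter)")

    @property
    def _planar(self) -> np.ndarray:
        """Vertices expressed in 2-D coordinates of the best-fit plane."""
        v = self.vertices - self.vertices.mean(axis=0)
        # principal axes of the point cloud; the two largest span the plane
        _, _, vt = np.linalg.svd(v, full_matrices=False)
        return v @ vt[:2].T

    @property
    def area(self) -> float:
        """Shoelace area on the section plane, mm²."""
        p = self._planar
        x, y = p[:, 0], p[:, 1]
        return float(abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)) / 2.0)

    @property
    def perimeter(self) -> float:
        """Closed-polygon perimeter, mm."""
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.linalg.norm(d, axis=1).sum())


def hydraulic_diameter(section: CrossSection) -> float:
    """D_h = 4 · area / perimeter, mm."""
    return 4.0 * section.area / section.perimeter


def equivalent_diameter(section: CrossSection) -> float:
    """Diameter of the circle with the section's area: 2 √(area/π), mm."""
    return 2.0 * float(np.sqrt(section.area / np.pi))


def mean_branch_diameter(sections: list[CrossSection]) -> float:
    """Mean equivalent-area diameter along a branch, mm."""
    if not sections:
        raise ValueError("need at least one cross-section")
    return float(np.mean([equivalent_diameter(s) for s in sections]))


def local_frame(centerline: Centerline, arc_position: float):
    """Right-handed orthonormal (tangent, e1, e2) at an arc-length position.

    The tangent comes from centered finite differences; the transverse
    pair is parallel-transported along the polyline from its start so the
    frame never flips between neighbouring samples (no torsion is added
    beyond what the curve itself requires).
    """
    s = centerline.arc_lengths
    if not (s[0] <= arc_position <= s[-1]):
        raise ValueError("arc position outside the polyline span")
    tangents = centerline.tangents
    # initial transverse pair at the start
    t0 = tangents[0]
    helper = np.array([1.0, 0.0, 0.0])
    if abs(t0 @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(t0, helper)
    e1 /= np.linalg.norm(e1)
    # transport up to the segment containing arc_position
    idx = int(np.searchsorted(s, arc_position, side="right") - 1)
    idx = min(idx, len(s) - 1)
    for i in range(idx):
        e1 = _transport(e1, tangents[i], tangents[i + 1])
    t = tangents[idx]
    e1 = e1 - (e1 @ t) * t
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(t, e1)
    return t, e1, e2


def _transport(v: np.ndarray, t_from: np.ndarray, t_to: np.ndarray) -> np.ndarray:
    """Rotate v by the minimal rotation taking t_from to t_to."""
    c = np.cross(t_from, t_to)
    s = np.linalg.norm(c)
    if s < 1e-15:
        return v
    axis = c / s
    cos = float(np.clip(t_from @ t_to, -1.0, 1.0))
    # Rodrigues rotation
    return v * cos + np.cross(axis, v) * s + axis * (axis @ v) * (1.0 - cos)
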