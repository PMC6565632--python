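"""Triangulated vessel surfaces carrying time-resolved WSS vector fields.

Units follow the conventions of clinical vascular imaging: coordinates in
millimetres, wall shear stress in pascals, time in seconds.  Every output
file records these units in its metadata.

Wall shear stress is tangential by definition; discrete CFD exports may
violate tangency by discretisation noise, so tangency is enforced by
projection at load time rather than by rejection.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "SurfaceMesh",
    "WssSeries",
    "ProbePoint",
    "compute_normals",
    "project_to_tangent",
    "probe_values",
    "read_surface_series",
    "write_surface_series",
    "read_probe_csv",
    "read_vtk_polydata",
    "write_vtk_polydata",
]

#: Relative tangency tolerance: |wss . n| <= TANGENCY_RTOL * (|wss| + 1 Pa).
TANGENCY_RTOL = 1e-6

#: Default off-surface fallback tolerance for probing, mm.
PROBE_TOLERANCE_MM = 2.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated vessel surface with outward unit normals.

    Attributes
    ----------
    nodes : (N, 3) float array, mm
    triangles : (M, 3) int array of node indices
    normals : (N, 3) float array, outward unit vectors
    """

    nodes: np.ndarray
    triangles: np.ndarray
    normals: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        tris = np.asarray(self.triangles, dtype=np.int64)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "triangles", tris)
        if nodes.ndim != 2 or nodes.shape[1] != 3:
            raise ValueError("nodes must be an (N, 3) array")
        if tris.ndim != 2 or tris.shape[1] != 3:
            raise ValueError("triangles must be an (M, 3) array")
        if tris.size and (tris.min() < 0 or tris.max() >= len(nodes)):
            raise ValueError("triangle connectivity references a missing node")
        normals = np.asarray(self.normals, dtype=float)
        if normals.shape != nodes.shape:
            raise ValueError("normals must match nodes in shape")
        lengths = np.linalg.norm(normals, axis=1)
        if not np.allclose(lengths, 1.0, atol=1e-9):
            raise ValueError("normals must have unit length within 1e-9")
        object.__setattr__(self, "normals", normals)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def bounding_box(self, pad: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box (lo, hi), optionally expanded by ``pad`` mm."""
        return self.nodes.min(axis=0) - pad, self.nodes.max(axis=0) + pad

    def check_orientation(self) -> None:
        """Verify consistent triangle orientation.

        Each interior edge must be shared by exactly two triangles traversing
        it in opposite directions; boundary edges belong to one triangle.
        """
        edges: dict[tuple[int, int], int] = {}
        for tri in self.triangles:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (int(a), int(b))
                edges[key] = edges.get(key, 0) + 1
        for (a, b), count in edges.items():
            if count > 1:
                raise ValueError(f"edge ({a},{b}) traversed {count} times in the same direction")
            rev = edges.get((b, a), 0)
            if rev > 1:
                raise ValueError(f"edge ({b},{a}) traversed {rev} times in the same direction")


@dataclass(frozen=True)
class WssSeries:
    """Periodic per-node WSS vector time series over one cardiac cycle.

    Attributes
    ----------
    times : (S,) float array, s, strictly increasing, all within [0, T)
    period : float, heartbeat period T in s
    wss : (S, N, 3) float array, Pa — one vector per node per sample
    """

    times: np.ndarray
    period: float
    wss: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        wss = np.asarray(self.wss, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "wss", wss)
        if times.ndim != 1 or len(times) < 2:
            raise ValueError("need at least 2 time samples")
        if np.any(np.diff(times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if times[0] < 0 or times[-1] >= self.period:
            raise ValueError("sample times must lie within [0, T)")
        if wss.ndim != 3 or wss.shape[0] != len(times) or wss.shape[2] != 3:
            raise ValueError("wss must be an (S, N, 3) array")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def n_nodes(self) -> int:
        return self.wss.shape[1]

    def check_tangency(self, mesh: SurfaceMesh) -> None:
        dots = np.abs(np.einsum("snk,nk->sn", self.wss, mesh.normals))
        bound = TANGENCY_RTOL * (np.linalg.norm(self.wss, axis=2) + 1.0)
        if np.any(dots > bound):
            raise ValueError("WSS series violates tangency beyond tolerance")


@dataclass(frozen=True)
class ProbePoint:
    """A labelled wall location, e.g. a tear projection zone."""

    label: str
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        xyz = np.asarray(self.coordinates, dtype=float).reshape(3)
        object.__setattr__(self, "coordinates", xyz)


# ---------------------------------------------------------------------------
# Normals and tangency
# ---------------------------------------------------------------------------

def compute_normals(nodes: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Area-weighted per-node normals from triangle face normals.

    Face cross products carry the area weighting implicitly; accumulated
    per node and normalised.  Orientation follows the triangle winding, so
    a consistently wound outward mesh yields outward normals.
    """
    nodes = np.asarray(nodes, dtype=float)
    triangles = np.asarray(triangles, dtype=np.int64)
    p0, p1, p2 = (nodes[triangles[:, i]] for i in range(3))
    face = np.cross(p1 - p0, p2 - p0)  # 2*area * unit normal
    acc = np.zeros_like(nodes)
    for i in range(3):
        np.add.at(acc, triangles[:, i], face)
    lengths = np.linalg.norm(acc, axis=1, keepdims=True)
    if np.any(lengths == 0):
        raise ValueError("degenerate node normal (isolated node or zero-area star)")
    return acc / lengths


def project_to_tangent(series: WssSeries, mesh: SurfaceMesh) -> WssSeries:
    """Project every WSS vector onto the local tangent plane: v - (v.n)n."""
    n = mesh.normals
    dots = np.einsum("snk,nk->sn", series.wss, n)
    projected = series.wss - dots[:, :, None] * n[None, :, :]
    return replace(series, wss=projected)


# ---------------------------------------------------------------------------
# Probing
# ---------------------------------------------------------------------------

def _barycentric_on_triangle(point: np.ndarray, tri_pts: np.ndarray):
    """Project point onto the triangle plane and clamp barycentric coords.

    Returns (weights, distance from point to its closest point on the
    triangle).  Weights are the barycentric coordinates of the closest
    point, valid for linear interpolation.
    """
    a, b, c = tri_pts
    ab, ac, ap = b - a, c - a, point - a
    d00, d01, d11 = ab @ ab, ab @ ac, ac @ ac
    d20, d21 = ap @ ab, ap @ ac
    denom = d00 * d11 - d01 * d01
    if denom <= 0:
        return None, np.inf
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    u = 1.0 - v - w
    weights = np.clip([u, v, w], 0.0, None)
    weights = weights / weights.sum()
    closest = weights @ tri_pts
    return weights, float(np.linalg.norm(point - closest))


def probe_values(
    values: np.ndarray,
    mesh: SurfaceMesh,
    probes: Sequence[ProbePoint],
    mode: str = "barycentric",
    tolerance: float = PROBE_TOLERANCE_MM,
    bbox_tolerance: float = 10.0,
) -> pd.DataFrame:
    """Sample a per-node scalar map at labelled probe points.

    Parameters
    ----------
    values : (N,) per-node scalars
    mode : 'nearest_node' or 'barycentric'.  Barycentric interpolates inside
        the nearest triangle and falls back to the nearest node when the
        probe sits farther than ``tolerance`` mm off the surface.
    bbox_tolerance : probes outside the mesh bounding box expanded by this
        many mm are rejected.

    Returns
    -------
    DataFrame with columns label, value, distance_mm, method.
    """
    if mode not in ("nearest_node", "barycentric"):
        raise ValueError(f"unknown probe mode: {mode!r}")
    values = np.asarray(values, dtype=float)
    if values.shape != (mesh.n_nodes,):
        raise ValueError("values must be one scalar per node")
    lo, hi = mesh.bounding_box(pad=bbox_tolerance)
    tree = cKDTree(mesh.nodes)
    centroids = mesh.nodes[mesh.triangles].mean(axis=1)
    tri_tree = cKDTree(centroids)

    rows = []
    for probe in probes:
        p = probe.coordinates
        if np.any(p < lo) or np.any(p > hi):
            raise ValueError(f"probe {probe.label!r} outside the expanded bounding box")
        node_dist, node_idx = tree.query(p)
        if mode == "nearest_node":
            rows.append((probe.label, values[node_idx], float(node_dist), "nearest_node"))
            continue
        # candidate triangles near the probe
        k = min(12, mesh.n_triangles)
        _, cand = tri_tree.query(p, k=k)
        cand = np.atleast_1d(cand)
        best_w, best_tri, best_d = None, None, np.inf
        for ti in cand:
            w, d = _barycentric_on_triangle(p, mesh.nodes[mesh.triangles[ti]])
            if w is not None and d < best_d:
                best_w, best_tri, best_d = w, ti, d
        if best_w is not None and best_d <= tolerance:
            val = float(best_w @ values[mesh.triangles[best_tri]])
            rows.append((probe.label, val, best_d, "barycentric"))
        else:
            rows.append((probe.label, values[node_idx], float(node_dist), "nearest_node"))
    return pd.DataFrame(rows, columns=["label", "value", "distance_mm", "method"])


def read_probe_csv(path: str | Path) -> list[ProbePoint]:
    """Read probe points from CSV with columns label,x,y,z."""
    df = pd.read_csv(path)
    required = {"label", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"probe CSV must have columns {sorted(required)}")
    return [
        ProbePoint(str(r.label), np.array([r.x, r.y, r.z], dtype=float))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Array-archive I/O (primary exchange format)
# ---------------------------------------------------------------------------

_ARCHIVE_KEYS = ("nodes", "triangles", "normals", "times", "period", "wss")


def write_surface_series(path: str | Path, mesh: SurfaceMesh, series: WssSeries) -> None:
    """Write mesh + series to an npz archive.

    Keys: nodes (mm), triangles, normals, times (s), period (s), wss (Pa),
    units (informational string array).
    """
    np.savez(
        path,
        nodes=mesh.nodes,
        triangles=mesh.triangles,
        normals=mesh.normals,
        times=series.times,
        period=np.array(series.period),
        wss=series.wss,
        units=np.array(["nodes:mm", "wss:Pa", "times:s"]),
    )


def _read_archive(path: Path, project: bool) -> tuple[SurfaceMesh, WssSeries]:
    with np.load(path) as npz:
        missing = [k for k in _ARCHIVE_KEYS if k not in npz]
        if missing:
            raise ValueError(f"archive missing keys: {missing}")
        mesh = SurfaceMesh(npz["nodes"], npz["triangles"], npz["normals"])
        series = WssSeries(npz["times"], float(npz["period"]), npz["wss"])
    if project:
        series = project_to_tangent(series, mesh)
    return mesh, series


def read_surface_series(
    source: str | Path | Sequence[str | Path],
    period: float | None = None,
    times: Sequence[float] | None = None,
    field_name: str = "WSS",
    project: bool = True,
) -> tuple[SurfaceMesh, WssSeries]:
    """Read a surface WSS series from an npz archive or a VTK polydata series.

    Parameters
    ----------
    source : a single ``.npz`` archive path, or an ordered list of legacy
        ASCII VTK polydata files (one per time sample, identical topology,
        WSS stored as a 3-component point field named ``field_name``).
    period, times : required for VTK series unless embedded as FIELD data
        (keys ``TIME`` and ``PERIOD``).
    project : enforce tangency by projection (default) after loading.
    """
    if isinstance(source, (str, Path)) and str(source).endswith(".npz"):
        return _read_archive(Path(source), project)
    paths = [Path(p) for p in (
        [source] if isinstance(source, (str, Path)) else list(source)
    )]
    if not paths:
        raise ValueError("empty VTK series")
    snapshots = [read_vtk_polydata(p, field_name=field_name) for p in paths]
    nodes, tris, _, _ = snapshots[0]
    for i, (n_i, t_i, _, _) in enumerate(snapshots[1:], start=1):
        if n_i.shape != nodes.shape or not np.array_equal(t_i, tris):
            raise ValueError(f"topology mismatch at snapshot {i}")
    wss = np.stack([snap[2] for snap in snapshots])
    if times is None:
        meta_times = [snap[3].get("TIME") for snap in snapshots]
        if any(t is None for t in meta_times):
            raise ValueError("supply times explicitly or embed TIME fields")
        times = [float(t) for t in meta_times]
    if period is None:
        period = snapshots[0][3].get("PERIOD")
        if period is None:
            raise ValueError("supply the period explicitly or embed a PERIOD field")
        period = float(period)
    mesh = SurfaceMesh(nodes, tris, compute_normals(nodes, tris))
    series = WssSeries(np.asarray(times, dtype=float), period, wss)
    if project:
        series = project_to_tangent(series, mesh)
    return mesh, series


# ---------------------------------------------------------------------------
# Minimal legacy-ASCII VTK polydata I/O
# ---------------------------------------------------------------------------
# Covers the POINTS / POLYGONS / POINT_DATA (VECTORS, SCALARS, FIELD) subset
# needed to exchange wall fields with visualisation tools.

def write_vtk_polydata(
    path: str | Path,
    nodes: np.ndarray,
    triangles: np.ndarray,
    point_vectors: dict[str, np.ndarray] | None = None,
    point_scalars: dict[str, np.ndarray] | None = None,
    field_data: dict[str, float] | None = None,
) -> None:
    nodes = np.asarray(nodes, dtype=float)
    triangles = np.asarray(triangles, dtype=np.int64)
    lines = [
        "# vtk DataFile Version 3.0",
        "hemowss surface (units: mm, Pa, s)",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(nodes)} double",
    ]
    lines += [" ".join(f"{v:.17g}" for v in row) for row in nodes]
    lines.append(f"POLYGONS {len(triangles)} {4 * len(triangles)}")
    lines += [f"3 {a} {b} {c}" for a, b, c in triangles]
    n_attrs = len(point_vectors or {}) + len(point_scalars or {})
    if n_attrs or field_data:
        lines.append(f"POINT_DATA {len(nodes)}")
    for name, vec in (point_vectors or {}).items():
        vec = np.asarray(vec, dtype=float)
        lines.append(f"VECTORS {name} double")
        lines += [" ".join(f"{v:.17g}" for v in row) for row in vec]
    for name, sca in (point_scalars or {}).items():
        sca = np.asarray(sca, dtype=float)
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.17g}" for v in sca]
    if field_data:
        lines.append(f"FIELD metadata {len(field_data)}")
        for name, value in field_data.items():
            lines.append(f"{name} 1 1 double")
            lines.append(f"{float(value):.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_polydata(path: str | Path, field_name: str = "WSS"):
    """Parse a legacy ASCII VTK polydata file written by this package.

    Returns (nodes, triangles, vectors-of-``field_name``, metadata dict).
    """
    tokens = re.split(r"\s+", Path(path).read_text())
    tokens = [t for t in tokens if t]
    i = 0

    def expect(word: str) -> None:
        nonlocal i
        while i < len(tokens) and tokens[i] != word:
            i += 1
        if i >= len(tokens):
            raise ValueError(f"{path}: missing {word} section")
        i += 1

    expect("POINTS")
    n_pts = int(tokens[i]); i += 2  # skip dtype
    nodes = np.array(tokens[i:i + 3 * n_pts], dtype=float).reshape(n_pts, 3)
    i += 3 * n_pts
    expect("POLYGONS")
    n_poly = int(tokens[i]); i += 2  # skip list size
    tris = np.empty((n_poly, 3), dtype=np.int64)
    for j in range(n_poly):
        if tokens[i] != "3":
            raise ValueError(f"{path}: only triangles supported")
        tris[j] = [int(tokens[i + 1]), int(tokens[i + 2]), int(tokens[i + 3])]
        i += 4
    vectors = None
    metadata: dict[str, float] = {}
    while i < len(tokens):
        tok = tokens[i]
        if tok == "VECTORS" and tokens[i + 1] == field_name:
            i += 3
            vectors = np.array(tokens[i:i + 3 * n_pts], dtype=float).reshape(n_pts, 3)
            i += 3 * n_pts
        elif tok == "FIELD":
            n_arrays = int(tokens[i + 2]); i += 3
            for _ in range(n_arrays):
                name = tokens[i]; count = int(tokens[i + 1]) * int(tokens[i + 2]); i += 4
                metadata[name] = float(tokens[i])
                i += count
        else:
            i += 1
    if vectors is None:
        raise ValueError(f"{path}: missing WSS vector field {field_name!r}")
    return nodes, tris, vectors, metadata
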