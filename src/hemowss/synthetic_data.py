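"""Synthetic vessel surfaces and WSS series with known ground truth.

Patient-specific CT-derived geometries and CFD wall fields are not
publicly distributable, so every input the pipeline consumes can instead
be generated here: structured tube and branched-tube meshes, physically
valid Womersley WSS series, inverse-designed oscillation fields with a
prescribed OSI, and phenomenological jet-impingement patterns.  All
generators are deterministic for a given spec and seed.

Geodesic distances on the tube use the unrolled (axial, arc-length)
chart, which is exact for a cylinder.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .surface_fields import SurfaceMesh, WssSeries, write_surface_series
from .vessel_geometry import BranchGeometry
from .waveforms import InflowWaveform, synthesize_waveform
from .womersley import WomersleyCase, analytic_wall_shear

__all__ = [
    "GeneratorSpec",
    "make_tube",
    "womersley_wss_on_tube",
    "prescribed_osi_field",
    "jet_impingement_field",
    "make_branched_tube",
    "generate_scenario",
    "SCENARIOS",
]


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

def make_tube(
    radius: float = 16.0,
    length: float = 100.0,
    axial_res: int = 20,
    circ_res: int = 24,
) -> SurfaceMesh:
    """Structured triangulated open cylinder along +z.

    Parameters in mm.  Node count is ``axial_res * circ_res``; normals are
    exactly radial and outward.
    """
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be positive")
    if axial_res < 3 or circ_res < 3:
        raise ValueError("resolutions must be at least 3")
    z = np.linspace(0.0, length, axial_res)
    theta = 2.0 * np.pi * np.arange(circ_res) / circ_res
    zz, tt = np.meshgrid(z, theta, indexing="ij")
    nodes = np.column_stack(
        [radius * np.cos(tt).ravel(), radius * np.sin(tt).ravel(), zz.ravel()]
    )
    normals = np.column_stack(
        [np.cos(tt).ravel(), np.sin(tt).ravel(), np.zeros(zz.size)]
    )

    def nid(i: int, j: int) -> int:
        return i * circ_res + (j % circ_res)

    tris = []
    for i in range(axial_res - 1):
        for j in range(circ_res):
            a, b = nid(i, j), nid(i, j + 1)
            c, d = nid(i + 1, j), nid(i + 1, j + 1)
            tris.append((a, b, d))
            tris.append((a, d, c))
    return SurfaceMesh(nodes, np.array(tris, dtype=np.int64), normals)


def _tube_chart(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray, float]:
    """(axial, arc-length) chart coordinates for a tube made by make_tube."""
    radius = float(np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1]).mean())
    theta = np.arctan2(mesh.nodes[:, 1], mesh.nodes[:, 0])
    return mesh.nodes[:, 2].copy(), radius * theta, radius


def _tangent_dirs(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    """Axial and circumferential unit tangents at every node of a z-tube."""
    n = mesh.n_nodes
    axial = np.tile([0.0, 0.0, 1.0], (n, 1))
    circ = np.cross(mesh.normals, axial) * -1.0  # +theta direction
    circ /= np.linalg.norm(circ, axis=1, keepdims=True)
    return axial, circ


# ---------------------------------------------------------------------------
# WSS fields
# ---------------------------------------------------------------------------

def womersley_wss_on_tube(
    mesh: SurfaceMesh,
    case: WomersleyCase,
    samples_per_cycle: int = 64,
    direction: int = +1,
) -> WssSeries:
    """Analytic Womersley wall shear applied uniformly along ±z of a tube.

    Every node carries the exact τ_w(t) of the case along the chosen axial
    direction, so the field is spatially uniform and exactly tangent.
    """
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    if abs(np.linalg.norm(mesh.normals[:, :2], axis=1) - 1.0).max() > 1e-9:
        raise ValueError("mesh is not a z-axis tube from make_tube")
    times = case.period * np.arange(samples_per_cycle) / samples_per_cycle
    tau = analytic_wall_shear(case, times)  # (S,)
    wss = np.zeros((samples_per_cycle, mesh.n_nodes, 3))
    wss[:, :, 2] = direction * tau[:, None]
    return WssSeries(times, case.period, wss)


def prescribed_osi_field(
    mesh: SurfaceMesh,
    target_osi: np.ndarray | float,
    tawss_scale: np.ndarray | float = 1.0,
    period: float = 0.8,
) -> WssSeries:
    """Two-phase series whose computed OSI equals the target exactly.

    Each node oscillates along its axial tangent between +a and −b for
    equal half-cycles, with a = 2τ(1−s) and b = 2τs for target OSI s and
    target TAWSS τ.  Under the periodic trapezoidal rule on the two
    samples, OSI = 0.5(1 − |a−b|/(a+b)) = s and TAWSS = (a+b)/2 = τ hold
    to machine precision.  Any target in [0, 0.5] is attainable.
    """
    n = mesh.n_nodes
    s = np.broadcast_to(np.asarray(target_osi, dtype=float), (n,)).copy()
    tau = np.broadcast_to(np.asarray(tawss_scale, dtype=float), (n,)).copy()
    if np.any((s < 0) | (s > 0.5)):
        raise ValueError("target OSI must lie in [0, 0.5]")
    if np.any(tau < 0):
        raise ValueError("TAWSS scale must be non-negative")
    a = 2.0 * tau * (1.0 - s)
    b = 2.0 * tau * s
    axial, _ = _tangent_dirs(mesh)
    wss = np.zeros((2, n, 3))
    wss[0] = a[:, None] * axial
    wss[1] = -b[:, None] * axial
    return WssSeries(np.array([0.0, period / 2.0]), period, wss)


def jet_impingement_field(
    mesh: SurfaceMesh,
    impingement_point: np.ndarray,
    strength: float = 10.0,
    spread: float = 10.0,
    washing_mode: str = "axial",
    waveform: InflowWaveform | None = None,
    samples_per_cycle: int = 32,
    direction_bias: float = 4.0,
    surface_tolerance: float = 1.0,
) -> WssSeries:
    """Phenomenological WSS pattern of a jet striking a tube wall.

    Magnitude decays as a Gaussian of the geodesic distance (unrolled
    chart) from the impingement point: |WSS| = strength·exp(−d²/2σ²) with
    σ = ``spread`` mm.  Directions radiate away from the point in the
    chart and are then biased axially or circumferentially by scaling the
    corresponding chart component by ``direction_bias``.  The pulsatility
    envelope is the inflow waveform normalised to unit mean, so cycle-mean
    magnitudes equal the spatial pattern.

    ``impingement_point`` must lie on the tube surface within
    ``surface_tolerance`` mm.
    """
    if washing_mode not in ("axial", "circumferential"):
        raise ValueError(f"unknown washing mode {washing_mode!r}")
    if strength < 0 or spread <= 0:
        raise ValueError("strength must be >= 0 and spread > 0")
    point = np.asarray(impingement_point, dtype=float).reshape(3)
    z, s_arc, radius = _tube_chart(mesh)
    r_pt = float(np.hypot(point[0], point[1]))
    if abs(r_pt - radius) > surface_tolerance:
        raise ValueError("impingement point is off the tube surface")
    z0 = point[2]
    s0 = radius * np.arctan2(point[1], point[0])

    dz = z - z0
    ds = s_arc - s0
    circumference = 2.0 * np.pi * radius
    ds = (ds + circumference / 2.0) % circumference - circumference / 2.0
    dist = np.hypot(dz, ds)
    magnitude = strength * np.exp(-(dist**2) / (2.0 * spread**2))

    # chart direction radiating from the point, biased per washing mode
    bias = np.array([direction_bias, 1.0]) if washing_mode == "axial" else np.array([1.0, direction_bias])
    chart_dir = np.column_stack([dz * bias[0], ds * bias[1]])
    norms = np.linalg.norm(chart_dir, axis=1)
    at_point = norms < 1e-12
    fallback = np.array([1.0, 0.0]) if washing_mode == "axial" else np.array([0.0, 1.0])
    chart_dir[at_point] = fallback
    norms[at_point] = 1.0
    chart_dir /= norms[:, None]

    axial, circ = _tangent_dirs(mesh)
    direction3d = chart_dir[:, 0:1] * axial + chart_dir[:, 1:2] * circ

    wf = waveform if waveform is not None else synthesize_waveform()
    times = wf.period * np.arange(samples_per_cycle) / samples_per_cycle
    envelope = wf(times) / wf.mean
    wss = envelope[:, None, None] * (magnitude[:, None] * direction3d)[None, :, :]
    return WssSeries(times, wf.period, wss)


# ---------------------------------------------------------------------------
# Branched tube
# ---------------------------------------------------------------------------

def _rot_y(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def make_branched_tube(
    main_radius: float = 16.0,
    branch_radius: float = 3.0,
    alpha_deg: float = 45.0,
    beta_deg: float = 60.0,
    main_length: float = 100.0,
    axial_res: int = 24,
    circ_res: int = 28,
    branch_length: float | None = None,
    branch_axial_res: int = 8,
    branch_circ_res: int = 16,
) -> tuple[SurfaceMesh, BranchGeometry]:
    """Main tube plus a branch stub realising angles (α, β) exactly.

    α is the elevation of the branch axis above the main-vessel wall
    tangent plane at the anastomosis; β is measured against a global
    vertical reference axis (+z).  Because a curved main vessel's
    centerline need not be vertical, the main tube is tilted from
    vertical by α+β in the x–z plane, which places the wall normal, the
    branch axis, and the vertical reference in one plane where both
    requested angles hold simultaneously — pairs with α > β, which are
    impossible against an in-plane axis, are then realisable.

    Returns the combined mesh (main tube nodes first) and the exact
    ground-truth BranchGeometry with reference_axis = +z.
    """
    if not (0.0 < alpha_deg <= 90.0) or not (0.0 < beta_deg <= 90.0):
        raise ValueError("alpha and beta must lie in (0, 90] degrees")
    if branch_radius >= main_radius:
        raise ValueError("branch radius must be smaller than the main radius")
    branch_length = branch_length if branch_length is not None else 5.0 * branch_radius

    vertical = np.array([0.0, 0.0, 1.0])
    branch_axis = _rot_y(beta_deg) @ vertical              # tilt by beta from +z
    wall_normal = _rot_y(alpha_deg + beta_deg - 90.0) @ vertical
    main_axis = _rot_y(alpha_deg + beta_deg) @ vertical    # perpendicular to normal

    # main tube generated along +z, then rotated so its axis is main_axis
    rot = _rot_y(alpha_deg + beta_deg)
    main = make_tube(main_radius, main_length, axial_res, circ_res)
    main_nodes = main.nodes @ rot.T
    main_normals = main.normals @ rot.T
    # anastomosis: local radial direction mapping to wall_normal is (-1, 0, 0)
    anastomosis_local = np.array([-main_radius, 0.0, main_length / 2.0])
    anastomosis = rot @ anastomosis_local

    # branch stub generated along +z, rotated to branch_axis, based at anastomosis
    stub = make_tube(branch_radius, branch_length, branch_axial_res, branch_circ_res)
    rot_b = _rot_y(beta_deg)
    stub_nodes = stub.nodes @ rot_b.T + anastomosis
    stub_normals = stub.normals @ rot_b.T

    nodes = np.vstack([main_nodes, stub_nodes])
    tris = np.vstack([main.triangles, stub.triangles + main.n_nodes])
    normals = np.vstack([main_normals, stub_normals])
    mesh = SurfaceMesh(nodes, tris, normals)
    geom = BranchGeometry(
        branch_axis=branch_axis,
        anastomosis=anastomosis,
        wall_normal=wall_normal,
        reference_axis=vertical,
    )
    return mesh, geom


# ---------------------------------------------------------------------------
# Scenario registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorSpec:
    """Named scenario with geometry/flow parameters and a seed.

    A given (spec, package version) pair produces bit-identical outputs.
    """

    scenario: str
    seed: int = 0
    radius_mm: float = 16.0
    length_mm: float = 100.0
    axial_res: int = 20
    circ_res: int = 24
    period_s: float = 0.8
    samples_per_cycle: int = 64
    extra: dict = field(default_factory=dict)


def _default_case(spec: GeneratorSpec) -> WomersleyCase:
    # steady + 2 harmonics of pressure-gradient forcing at aortic scale
    return WomersleyCase(
        radius=spec.radius_mm / 1000.0,
        period=spec.period_s,
        pressure_gradient={
            0: 40.0,
            1: 120.0 * np.exp(1j * np.radians(-30.0)),
            2: 50.0 * np.exp(1j * np.radians(45.0)),
        },
    )


def _scenario_womersley_tube(spec: GeneratorSpec):
    mesh = make_tube(spec.radius_mm, spec.length_mm, spec.axial_res, spec.circ_res)
    series = womersley_wss_on_tube(mesh, _default_case(spec), spec.samples_per_cycle)
    return mesh, series, {"case": "steady+2 harmonics"}


def _scenario_steady_tube(spec: GeneratorSpec):
    mesh = make_tube(spec.radius_mm, spec.length_mm, spec.axial_res, spec.circ_res)
    case = WomersleyCase(
        radius=spec.radius_mm / 1000.0, period=spec.period_s, pressure_gradient={0: 40.0}
    )
    series = womersley_wss_on_tube(mesh, case, spec.samples_per_cycle)
    return mesh, series, {"case": "steady"}


def _scenario_oscillatory_tube(spec: GeneratorSpec):
    mesh = make_tube(spec.radius_mm, spec.length_mm, spec.axial_res, spec.circ_res)
    case = WomersleyCase(
        radius=spec.radius_mm / 1000.0,
        period=spec.period_s,
        pressure_gradient={0: 0.0, 1: 120.0},
    )
    series = womersley_wss_on_tube(mesh, case, spec.samples_per_cycle)
    return mesh, series, {"case": "zero-mean single harmonic"}


def _scenario_prescribed_osi(spec: GeneratorSpec):
    mesh = make_tube(spec.radius_mm, spec.length_mm, spec.axial_res, spec.circ_res)
    rng = np.random.default_rng(spec.seed)
    targets = rng.uniform(0.0, 0.5, size=mesh.n_nodes)
    series = prescribed_osi_field(mesh, targets, tawss_scale=1.5, period=spec.period_s)
    return mesh, series, {"target_osi": targets.tolist()}


def _scenario_jet(spec: GeneratorSpec, mode: str):
    mesh = make_tube(spec.radius_mm, spec.length_mm, spec.axial_res, spec.circ_res)
    point = np.array([spec.radius_mm, 0.0, spec.length_mm / 2.0])
    strength = float(spec.extra.get("strength", 12.0))
    spread = float(spec.extra.get("spread", 12.0))
    series = jet_impingement_field(
        mesh, point, strength=strength, spread=spread, washing_mode=mode,
        samples_per_cycle=spec.samples_per_cycle,
    )
    meta = {"impingement_point": point.tolist(), "strength": strength,
            "spread": spread, "washing_mode": mode}
    return mesh, series, meta


SCENARIOS = {
    "womersley_tube": _scenario_womersley_tube,
    "steady_tube": _scenario_steady_tube,
    "oscillatory_tube": _scenario_oscillatory_tube,
    "prescribed_osi": _scenario_prescribed_osi,
    "jet_axial": lambda s: _scenario_jet(s, "axial"),
    "jet_circumferential": lambda s: _scenario_jet(s, "circumferential"),
}


def generate_scenario(spec: GeneratorSpec, out_dir: str | Path | None = None):
    """Run a named scenario; optionally write archive + ground-truth sidecar.

    Returns (mesh, series, ground_truth dict).  When ``out_dir`` is given,
    writes ``<scenario>.npz`` and ``<scenario>.json`` there.
    """
    if spec.scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {spec.scenario!r}; known: {sorted(SCENARIOS)}")
    mesh, series, meta = SCENARIOS[spec.scenario](spec)
    truth = {"spec": asdict(spec), **meta}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_surface_series(out / f"{spec.scenario}.npz", mesh, series)
        (out / f"{spec.scenario}.json").write_text(json.dumps(truth, indent=1))
    return mesh, series, truth
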