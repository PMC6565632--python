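"""Cycle-averaged wall-shear-stress indicators and zone classification.

Five per-node indicators are computed from one cardiac cycle of WSS
vectors WSS(s, t) with heartbeat period T:

* TAWSS  = (1/T) ∮ |WSS| dt                 — time-averaged WSS magnitude, Pa
* OSI    = 0.5 [1 − |∮ WSS dt| / ∮ |WSS| dt] — oscillatory shear index, 0..0.5
* RRT    = k / [(1 − 2 OSI) · TAWSS]         — relative residence time
* TransWSS = (1/T) ∮ |WSS · (n × ê_m)| dt    — transverse WSS, Pa, with
  ê_m the unit cycle-mean WSS direction and n the outward wall normal
* OSItr  = TransWSS / TAWSS                  — normalised transverse WSS, 0..1

All cycle integrals use the periodic trapezoidal rule with an explicit
wrap-around segment from the last sample back to the first, so non-uniform
time grids are handled and the cycle closes exactly.

RRT is defined only up to a proportionality constant k (default 1, the
bare reciprocal); ``calibrate_rrt_constant`` recovers k from a reference
row of a published table.

TAWSS zones follow the conventional thresholds: below 0.4 Pa is a low-WSS
zone, above 5 Pa a high-WSS zone; boundary values are classified normal
since the thresholds are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .surface_fields import SurfaceMesh, WssSeries

__all__ = [
    "CycleIndexMap",
    "ZoneMap",
    "periodic_cycle_integral",
    "tawss",
    "osi",
    "rrt",
    "calibrate_rrt_constant",
    "transwss",
    "ositr",
    "compute_indices",
    "classify_zones",
    "washing_direction",
    "LOW_WSS_THRESHOLD_PA",
    "HIGH_WSS_THRESHOLD_PA",
]

LOW_WSS_THRESHOLD_PA = 0.4
HIGH_WSS_THRESHOLD_PA = 5.0

#: OSI singularity guard for RRT: nodes with OSI >= 0.5 - OSI_EPS are invalid.
OSI_EPS = 1e-9

#: Cycle-mean WSS direction is considered degenerate when |∮WSS dt| falls
#: below this fraction of ∮|WSS| dt (round-off of symmetric series).
MEAN_DIRECTION_RTOL = 1e-12


# ---------------------------------------------------------------------------
# Cycle integration
# ---------------------------------------------------------------------------

def periodic_cycle_integral(times: np.ndarray, values: np.ndarray, period: float) -> np.ndarray:
    """∮ f dt over one period by the periodic trapezoidal rule.

    ``values`` has shape (S, ...); sample s lives at ``times[s]``.  The rule
    sums trapezoids between consecutive samples plus the wrap-around
    segment from the last sample at t[-1] back to the first at t[0] + T.
    For a uniform grid this reduces to mean(f) * T.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values)
    dt = np.diff(times)
    dt_wrap = period - times[-1] + times[0]
    if dt_wrap <= 0:
        raise ValueError("samples must span less than one period")
    mid = 0.5 * (values[1:] + values[:-1])
    total = np.tensordot(dt, mid, axes=(0, 0))
    total = total + 0.5 * dt_wrap * (values[-1] + values[0])
    return total


def _node_axes(series: WssSeries):
    """Common integrals: returns (mean |WSS| integral, mean-vector integral)."""
    mags = np.linalg.norm(series.wss, axis=2)            # (S, N)
    int_mag = periodic_cycle_integral(series.times, mags, series.period)
    int_vec = periodic_cycle_integral(series.times, series.wss, series.period)
    return int_mag, int_vec


# ---------------------------------------------------------------------------
# Per-node indicators
# ---------------------------------------------------------------------------

def tawss(series: WssSeries) -> np.ndarray:
    """Time-averaged WSS magnitude (Pa) per node."""
    int_mag, _ = _node_axes(series)
    return int_mag / series.period


def osi(series: WssSeries) -> tuple[np.ndarray, np.ndarray]:
    """Oscillatory shear index per node.

    Returns (osi, valid).  Nodes with zero cycle-mean |WSS| are flagged
    invalid (OSI undefined), never raised.
    """
    int_mag, int_vec = _node_axes(series)
    valid = int_mag > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.linalg.norm(int_vec, axis=1) / int_mag
    out = 0.5 * (1.0 - np.clip(ratio, 0.0, 1.0))
    out[~valid] = np.nan
    return out, valid


def rrt(tawss_values: np.ndarray, osi_values: np.ndarray, k: float = 1.0,
        eps: float = OSI_EPS) -> tuple[np.ndarray, np.ndarray]:
    """Relative residence time  k / [(1 − 2 OSI) TAWSS].

    Nodes at the OSI→0.5 singularity (within ``eps``) or with zero TAWSS
    are flagged invalid; the output never contains infinities.
    """
    tawss_values = np.asarray(tawss_values, dtype=float)
    osi_values = np.asarray(osi_values, dtype=float)
    with np.errstate(invalid="ignore"):
        valid = (tawss_values > 0) & (osi_values < 0.5 - eps) & np.isfinite(osi_values)
    out = np.full_like(tawss_values, np.nan)
    out[valid] = k / ((1.0 - 2.0 * osi_values[valid]) * tawss_values[valid])
    return out, valid


def calibrate_rrt_constant(tawss_ref: float, osi_ref: float, rrt_ref: float) -> float:
    """Recover the RRT proportionality constant from one reference row.

    k = RRT_ref (1 − 2 OSI_ref) TAWSS_ref.  Published RRT columns often
    carry an unstated normalisation; calibrating on one row and applying
    k to the others checks the table's internal consistency.
    """
    if tawss_ref <= 0 or not (0 <= osi_ref < 0.5):
        raise ValueError("reference row is invalid for calibration")
    return float(rrt_ref * (1.0 - 2.0 * osi_ref) * tawss_ref)


def transwss(series: WssSeries, normals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Transverse WSS (Pa) per node: cycle-average of |WSS · (n × ê_m)|.

    ê_m is the unit cycle-mean WSS vector; n the outward wall normal.
    Nodes with vanishing cycle-mean WSS have no defined mean direction and
    are flagged invalid.
    """
    normals = np.asarray(normals, dtype=float)
    int_mag, int_vec = _node_axes(series)
    mean_norm = np.linalg.norm(int_vec, axis=1)
    # relative guard: a symmetric series sums to ~machine epsilon, not zero
    valid = mean_norm > MEAN_DIRECTION_RTOL * int_mag
    e_m = np.zeros_like(int_vec)
    e_m[valid] = int_vec[valid] / mean_norm[valid, None]
    perp = np.cross(normals, e_m)                        # (N, 3)
    comp = np.abs(np.einsum("snk,nk->sn", series.wss, perp))
    out = periodic_cycle_integral(series.times, comp, series.period) / series.period
    out[~valid] = np.nan
    return out, valid


def ositr(transwss_values: np.ndarray, tawss_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalised transverse WSS, TransWSS / TAWSS, guaranteed in [0, 1]."""
    transwss_values = np.asarray(transwss_values, dtype=float)
    tawss_values = np.asarray(tawss_values, dtype=float)
    valid = (tawss_values > 0) & np.isfinite(transwss_values)
    out = np.full_like(tawss_values, np.nan)
    out[valid] = np.clip(transwss_values[valid] / tawss_values[valid], 0.0, 1.0)
    return out, valid


# ---------------------------------------------------------------------------
# Aggregate map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CycleIndexMap:
    """Per-node indicator maps for one cardiac cycle.

    Invalid nodes hold NaN in the affected scalar and False in its mask.
    """

    tawss: np.ndarray
    osi: np.ndarray
    rrt: np.ndarray
    transwss: np.ndarray
    ositr: np.ndarray
    valid_osi: np.ndarray
    valid_rrt: np.ndarray
    valid_transwss: np.ndarray
    rrt_constant: float = 1.0

    @property
    def n_nodes(self) -> int:
        return len(self.tawss)


def compute_indices(mesh: SurfaceMesh, series: WssSeries, rrt_k: float = 1.0) -> CycleIndexMap:
    """Compute all five indicators for every node of the surface."""
    if series.n_nodes != mesh.n_nodes:
        raise ValueError("series and mesh disagree on node count")
    ta = tawss(series)
    os_, v_os = osi(series)
    rr, v_rr = rrt(ta, os_, k=rrt_k)
    tw, v_tw = transwss(series, mesh.normals)
    tr, v_tr = ositr(tw, ta)
    return CycleIndexMap(
        tawss=ta, osi=os_, rrt=rr, transwss=tw, ositr=tr,
        valid_osi=v_os, valid_rrt=v_rr, valid_transwss=v_tw & v_tr,
        rrt_constant=rrt_k,
    )


# ---------------------------------------------------------------------------
# Zone classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZoneMap:
    """Per-node TAWSS zone labels with the thresholds that produced them."""

    labels: np.ndarray  # array of 'low' | 'normal' | 'high'
    low_threshold: float
    high_threshold: float


def classify_zones(
    tawss_values: np.ndarray,
    low: float = LOW_WSS_THRESHOLD_PA,
    high: float = HIGH_WSS_THRESHOLD_PA,
) -> ZoneMap:
    """Label nodes low/normal/high by strict TAWSS thresholds.

    Boundary values (exactly ``low`` or ``high``) are normal.
    """
    if not (0 < low < high):
        raise ValueError("thresholds must satisfy 0 < low < high")
    tawss_values = np.asarray(tawss_values, dtype=float)
    labels = np.full(tawss_values.shape, "normal", dtype=object)
    labels[tawss_values < low] = "low"
    labels[tawss_values > high] = "high"
    return ZoneMap(labels=labels, low_threshold=low, high_threshold=high)


# ---------------------------------------------------------------------------
# Washing-direction metric
# ---------------------------------------------------------------------------

def washing_direction(
    series: WssSeries,
    axial: np.ndarray,
    node: int | None = None,
    threshold_deg: float = 45.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Angle of the cycle-mean WSS direction to the local axial direction.

    Operationalises the distinction between axial washing of the wall and
    circumferential flushing by an impinging jet.  The angle is
    arccos(|ê_m · â|) in [0°, 90°]; a node is labelled 'circumferential'
    when the angle strictly exceeds ``threshold_deg`` (default 45°), else
    'axial'.  Nodes with degenerate cycle-mean WSS are invalid (NaN angle,
    'invalid' label).

    Parameters
    ----------
    axial : (3,) or (N, 3) unit axial direction(s), tangent to the surface
    node : restrict to one node index; default all nodes

    Returns
    -------
    (angles_deg, labels, valid)
    """
    axial = np.asarray(axial, dtype=float)
    int_mag, int_vec = _node_axes(series)
    if node is not None:
        int_vec = int_vec[node:node + 1]
        int_mag = int_mag[node:node + 1]
    if axial.ndim == 1:
        axial = np.broadcast_to(axial, int_vec.shape)
    a_unit = axial / np.linalg.norm(axial, axis=1, keepdims=True)
    mean_norm = np.linalg.norm(int_vec, axis=1)
    valid = mean_norm > MEAN_DIRECTION_RTOL * int_mag
    angles = np.full(len(int_vec), np.nan)
    cosangle = np.abs(np.einsum("nk,nk->n", int_vec, a_unit))
    with np.errstate(invalid="ignore", divide="ignore"):
        angles[valid] = np.degrees(np.arccos(np.clip(cosangle[valid] / mean_norm[valid], 0.0, 1.0)))
    labels = np.full(len(int_vec), "invalid", dtype=object)
    # tiny slack so an exactly-boundary angle stays 'axial' despite round-off
    boundary = threshold_deg + 1e-9
    labels[valid & (angles <= boundary)] = "axial"
    labels[valid & (angles > boundary)] = "circumferential"
    return angles, labels, valid
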