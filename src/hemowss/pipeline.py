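"""End-to-end orchestration: configuration, logging, and report generation.

``run_indices`` takes a surface WSS series to per-node indicator maps
(VTK + CSV), a zone map, and a probe report shaped like a published
hemodynamics table (Position, TAWSS, OSI, RRT, OSItr).  ``run_geometry``
turns branch geometry inputs into a morphometrics table (Diameter, α, β).

Output CSVs use '.' decimals and 6 significant digits, independent of
locale, so reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import surface_fields as sf
from .indices import (
    HIGH_WSS_THRESHOLD_PA,
    LOW_WSS_THRESHOLD_PA,
    CycleIndexMap,
    classify_zones,
    compute_indices,
)
from .vessel_geometry import BranchGeometry, CrossSection, branch_angles, mean_branch_diameter

__all__ = ["RunConfig", "run_indices", "run_geometry", "PipelineError"]

logger = logging.getLogger("hemowss")

#: CSV float format: 6 significant digits, locale-independent.
FLOAT_FORMAT = "%.6g"


class PipelineError(RuntimeError):
    """Stage failure with provenance; message is single-line machine-parsable."""

    def __init__(self, stage: str, reason: str):
        super().__init__(f"stage={stage} error={reason}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Round-trips losslessly through YAML/JSON via ``to_dict``/``from_dict``.
    """

    input_path: str
    output_dir: str
    probes_path: str | None = None
    probe_mode: str = "barycentric"
    rrt_constant: float = 1.0
    low_threshold: float = LOW_WSS_THRESHOLD_PA
    high_threshold: float = HIGH_WSS_THRESHOLD_PA
    field_name: str = "WSS"
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.low_threshold < self.high_threshold):
            raise ValueError("thresholds must satisfy 0 < low < high")
        if self.probe_mode not in ("barycentric", "nearest_node"):
            raise ValueError(f"unknown probe mode {self.probe_mode!r}")

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "output_dir": self.output_dir,
            "probes_path": self.probes_path,
            "probe_mode": self.probe_mode,
            "rrt_constant": self.rrt_constant,
            "low_threshold": self.low_threshold,
            "high_threshold": self.high_threshold,
            "field_name": self.field_name,
            "seed": self.seed,
            "verbosity": self.verbosity,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _indices_frame(index_map: CycleIndexMap, zones) -> pd.DataFrame:
    n = index_map.n_nodes
    valid = index_map.valid_osi & index_map.valid_rrt & index_map.valid_transwss
    return pd.DataFrame(
        {
            "node_id": np.arange(n),
            "tawss": index_map.tawss,
            "osi": index_map.osi,
            "rrt": index_map.rrt,
            "transwss": index_map.transwss,
            "ositr": index_map.ositr,
            "zone": zones.labels,
            "valid": valid,
        }
    )


def run_indices(config: RunConfig):
    """Compute indicator maps, zones, and the probe report for one series.

    Writes ``indices.csv``, ``indices.vtk``, ``probe_report.csv`` (when
    probes are given), and ``run_log.json`` into the output directory.
    Any stage failure removes partial outputs and raises PipelineError.

    Returns (CycleIndexMap, ZoneMap, probe report DataFrame or None).
    """
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        try:
            mesh, series = sf.read_surface_series(
                config.input_path, field_name=config.field_name
            )
        except Exception as exc:
            raise PipelineError("load", str(exc)) from exc
        logger.info("loaded %d nodes, %d samples", mesh.n_nodes, series.n_samples)

        try:
            index_map = compute_indices(mesh, series, rrt_k=config.rrt_constant)
            zones = classify_zones(
                index_map.tawss, low=config.low_threshold, high=config.high_threshold
            )
        except Exception as exc:
            raise PipelineError("indices", str(exc)) from exc
        logger.info(
            "indices done: %d/%d nodes valid",
            int(np.sum(index_map.valid_osi)), index_map.n_nodes,
        )
        logger.debug(
            "validity: osi=%d rrt=%d transwss=%d",
            int(index_map.valid_osi.sum()), int(index_map.valid_rrt.sum()),
            int(index_map.valid_transwss.sum()),
        )

        frame = _indices_frame(index_map, zones)
        csv_path = out_dir / "indices.csv"
        frame.to_csv(csv_path, index=False, float_format=FLOAT_FORMAT)
        written.append(csv_path)

        vtk_path = out_dir / "indices.vtk"
        sf.write_vtk_polydata(
            vtk_path,
            mesh.nodes,
            mesh.triangles,
            point_scalars={
                "TAWSS": index_map.tawss,
                "OSI": np.nan_to_num(index_map.osi, nan=-1.0),
                "RRT": np.nan_to_num(index_map.rrt, nan=-1.0),
                "TransWSS": np.nan_to_num(index_map.transwss, nan=-1.0),
                "OSItr": np.nan_to_num(index_map.ositr, nan=-1.0),
            },
            field_data={"PERIOD": series.period},
        )
        written.append(vtk_path)

        report = None
        if config.probes_path:
            try:
                probes = sf.read_probe_csv(config.probes_path)
                columns = {}
                for name, vals in (
                    ("TAWSS", index_map.tawss),
                    ("OSI", index_map.osi),
                    ("RRT", index_map.rrt),
                    ("OSItr", index_map.ositr),
                ):
                    sampled = sf.probe_values(
                        np.nan_to_num(vals, nan=np.nan), mesh, probes, mode=config.probe_mode
                    )
                    columns[name] = sampled["value"].to_numpy()
                report = pd.DataFrame(
                    {"Position": [p.label for p in probes], **columns}
                )
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError("probe", str(exc)) from exc
            probe_path = out_dir / "probe_report.csv"
            report.to_csv(probe_path, index=False, float_format=FLOAT_FORMAT)
            written.append(probe_path)

        log_path = out_dir / "run_log.json"
        log_path.write_text(
            json.dumps(
                {
                    "config": config.to_dict(),
                    "config_hash": config.config_hash,
                    "n_nodes": mesh.n_nodes,
                    "n_samples": series.n_samples,
                    "n_valid_osi": int(index_map.valid_osi.sum()),
                },
                indent=1, sort_keys=True,
            )
        )
        return index_map, zones, report
    except PipelineError:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def run_geometry(
    branches: dict[str, tuple[BranchGeometry, list[CrossSection]]],
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Morphometrics table: one row (Branch, Diameter, alpha, beta) per branch.

    ``branches`` maps branch name to (geometry, cross-sections).  Raises on
    duplicate names (dict input already forbids them) or malformed inputs.
    """
    rows = []
    for name, (geom, sections) in branches.items():
        try:
            alpha, beta = branch_angles(geom)
            diameter = mean_branch_diameter(sections) if sections else np.nan
        except Exception as exc:
            raise PipelineError("geometry", f"branch={name} {exc}") from exc
        rows.append((name, diameter, alpha, beta))
    table = pd.DataFrame(rows, columns=["Branch", "Diameter_mm", "alpha_deg", "beta_deg"])
    if out_path is not None:
        table.to_csv(out_path, index=False, float_format=FLOAT_FORMAT)
    return table
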