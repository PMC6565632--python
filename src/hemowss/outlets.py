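"""Outlet flow-split bookkeeping for a multi-outlet vessel model.

Each outlet carries a per-vessel percentage of the inlet flow; bilateral
entries (paired left/right vessels) count twice in the mass balance.  The
expanded fractions of a complete split must total 100%, e.g. per-vessel
6.48% (bilateral carotids) + 18.15% (bilateral subclavians) + 8.73%
(bilateral mammaries) leaves 33.28% for the descending aorta:
2·(6.48 + 18.15 + 8.73) + 33.28 = 100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd
import yaml

__all__ = ["OutletEntry", "FlowSplit", "complete_split", "outlet_flows", "load_split"]

#: Closure tolerance on the expanded total, percentage points.
CLOSURE_TOL = 0.01


@dataclass(frozen=True)
class OutletEntry:
    """One named outlet: per-vessel fraction in %, None if unresolved."""

    name: str
    fraction: float | None
    bilateral: bool = False

    @property
    def expanded(self) -> float:
        """Contribution to the mass balance (bilateral counts twice)."""
        if self.fraction is None:
            raise ValueError(f"outlet {self.name!r} has no fraction")
        return self.fraction * (2 if self.bilateral else 1)


@dataclass(frozen=True)
class FlowSplit:
    """Named outlets with per-vessel percentage fractions."""

    outlets: tuple[OutletEntry, ...]
    inlet_scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "outlets", tuple(self.outlets))
        names = [o.name for o in self.outlets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate outlet names")
        for o in self.outlets:
            if o.fraction is not None and o.fraction < 0:
                raise ValueError(f"outlet {o.name!r} has a negative fraction")

    @property
    def is_complete(self) -> bool:
        return all(o.fraction is not None for o in self.outlets)

    def validate_closure(self) -> None:
        total = sum(o.expanded for o in self.outlets)
        if abs(total - 100.0) > CLOSURE_TOL:
            raise ValueError(f"expanded fractions total {total}%, not 100%")


def complete_split(split: FlowSplit) -> FlowSplit:
    """Resolve the single unresolved outlet so the expanded total is 100%.

    Exactly one outlet must lack a fraction; the others' expanded sum must
    stay below 100% (per that outlet's multiplicity).
    """
    missing = [o for o in split.outlets if o.fraction is None]
    if len(missing) != 1:
        raise ValueError(f"expected exactly one unresolved outlet, found {len(missing)}")
    allocated = sum(o.expanded for o in split.outlets if o.fraction is not None)
    remainder = 100.0 - allocated
    mult = 2 if missing[0].bilateral else 1
    if remainder < 0:
        raise ValueError(f"over-allocated split: {allocated}% already assigned")
    resolved = replace(missing[0], fraction=remainder / mult)
    out = FlowSplit(
        outlets=tuple(resolved if o.name == resolved.name else o for o in split.outlets),
        inlet_scale=split.inlet_scale,
    )
    out.validate_closure()
    return out


def outlet_flows(split: FlowSplit, inlet_flow: float) -> pd.DataFrame:
    """Per-physical-outlet flows; bilateral entries expand to _left/_right.

    Returns a DataFrame (outlet, fraction_percent, flow) whose flows sum
    to the inlet flow to rounding.
    """
    if not split.is_complete:
        raise ValueError("split has unresolved outlets")
    split.validate_closure()
    rows = []
    for o in split.outlets:
        sides = [f"{o.name}_left", f"{o.name}_right"] if o.bilateral else [o.name]
        for name in sides:
            rows.append((name, o.fraction, o.fraction / 100.0 * inlet_flow))
    return pd.DataFrame(rows, columns=["outlet", "fraction_percent", "flow"])


def load_split(path: str | Path) -> FlowSplit:
    """Load a split spec from YAML/JSON.

    Schema: ``outlets`` — list of {name, fraction_percent (optional),
    bilateral (default false)}.
    """
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    outlets = tuple(
        OutletEntry(
            name=str(o["name"]),
            fraction=None if o.get("fraction_percent") is None else float(o["fraction_percent"]),
            bilateral=bool(o.get("bilateral", False)),
        )
        for o in data["outlets"]
    )
    return FlowSplit(outlets=outlets, inlet_scale=float(data.get("inlet_scale", 1.0)))
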