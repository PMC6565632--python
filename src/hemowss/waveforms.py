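"""Inflow waveform synthesis and flow-scale bookkeeping.

The inflow boundary condition is a periodic cross-section mean velocity
U(t) expanded in Fourier harmonics.  The built-in aortic-like template has
a systolic peak near T/4 over a low diastolic baseline; rescaling its
cycle mean to a target mean velocity fixes the flow scale.  The default
target, 0.11354 m/s, is the mean velocity that closes Re = ρUD/μ = 1090
for an inlet diameter of 32 mm and blood properties ρ = 1050 kg/m³,
μ = 3.5×10⁻³ kg/m·s.

Named analysis instants default to early/mid/late systole and early
diastole: T1 = 0.11 s, T2 = 0.22 s, T3 = 0.36 s, T4 = 0.58 s within the
default 0.8 s cycle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .womersley import FluidProperties

__all__ = [
    "InflowWaveform",
    "InletSpec",
    "aortic_template_coefficients",
    "synthesize_waveform",
    "reynolds",
    "sample_time_points",
    "DEFAULT_MEAN_VELOCITY",
    "DEFAULT_PERIOD",
    "DEFAULT_TIME_POINTS",
]

#: Cycle-mean inlet velocity (m/s) closing Re = 1090 at D = 32 mm.
DEFAULT_MEAN_VELOCITY = 0.11354
#: Default cardiac period, s.
DEFAULT_PERIOD = 0.8
#: Named analysis instants, s.
DEFAULT_TIME_POINTS = {"T1": 0.11, "T2": 0.22, "T3": 0.36, "T4": 0.58}

#: Inlet aortic diameter, m.
DEFAULT_INLET_DIAMETER = 0.032


@dataclass(frozen=True)
class InflowWaveform:
    """T-periodic cross-section mean velocity as a truncated Fourier series.

    ``coefficients[k]`` is the complex amplitude of harmonic k, so
    U(t) = Re Σ_k c_k exp(2πi k t / T); c_0 is the cycle mean.
    """

    period: float
    coefficients: np.ndarray  # complex, index = harmonic
    time_points: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TIME_POINTS)
    )

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coefficients, dtype=complex)
        object.__setattr__(self, "coefficients", coeffs)
        object.__setattr__(self, "time_points", MappingProxyType(dict(self.time_points)))
        if self.period <= 0:
            raise ValueError("period must be positive")
        if coeffs.ndim != 1 or len(coeffs) < 1:
            raise ValueError("need at least the zeroth Fourier coefficient")
        for label, t in self.time_points.items():
            if not (0 <= t < self.period):
                raise ValueError(f"time point {label!r} = {t} outside [0, T)")

    @property
    def mean(self) -> float:
        """Cycle-mean velocity, m/s."""
        return float(self.coefficients[0].real)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Evaluate U(t), m/s."""
        t = np.asarray(t, dtype=float)
        k = np.arange(len(self.coefficients))
        phases = np.exp(2j * np.pi * np.multiply.outer(t, k) / self.period)
        return (phases @ self.coefficients).real

    def to_csv(self, path: str | Path, n_samples: int = 200) -> None:
        t = np.linspace(0.0, self.period, n_samples, endpoint=False)
        pd.DataFrame({"time_s": t, "velocity_m_per_s": self(t)}).to_csv(path, index=False)


@dataclass(frozen=True)
class InletSpec:
    """Inlet geometry and fluid for Reynolds bookkeeping."""

    diameter: float = DEFAULT_INLET_DIAMETER  # m
    fluid: FluidProperties = field(default_factory=FluidProperties)

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("inlet diameter must be positive")


def aortic_template_coefficients(n_harmonics: int = 10) -> np.ndarray:
    """Fourier coefficients of the built-in aortic-like template.

    Shape: a Gaussian systolic bump centred at t = T/4 (width T/10) on a
    low diastolic baseline, band-limited to ``n_harmonics`` harmonics.
    Computed deterministically by FFT of a dense sampling of the shape.
    """
    n = 4096
    s = np.arange(n) / n  # t / T
    shape = 0.12 + np.exp(-(((s - 0.25) / 0.10) ** 2))
    spec = np.fft.rfft(shape) / n
    coeffs = np.zeros(n_harmonics + 1, dtype=complex)
    coeffs[0] = spec[0].real
    coeffs[1:] = 2.0 * spec[1:n_harmonics + 1]  # one-sided convention
    return coeffs


def synthesize_waveform(
    target_mean: float = DEFAULT_MEAN_VELOCITY,
    period: float = DEFAULT_PERIOD,
    template: np.ndarray | None = None,
    time_points: Mapping[str, float] | None = None,
) -> InflowWaveform:
    """Rescale the template so the cycle mean equals ``target_mean`` (m/s).

    The rescaling is a uniform multiplication of all Fourier coefficients,
    so waveforms at different targets are exact scalings of one another.
    """
    if target_mean <= 0:
        raise ValueError("target mean velocity must be positive")
    coeffs = aortic_template_coefficients() if template is None else np.asarray(
        template, dtype=complex
    )
    mean = coeffs[0].real
    if mean <= 0:
        raise ValueError("template must have a positive cycle mean")
    return InflowWaveform(
        period=period,
        coefficients=coeffs * (target_mean / mean),
        time_points=dict(DEFAULT_TIME_POINTS) if time_points is None else dict(time_points),
    )


def reynolds(mean_velocity: float, inlet: InletSpec | None = None) -> float:
    """Re = ρ U D / μ for the inlet cross-section mean velocity U (m/s)."""
    if mean_velocity <= 0:
        raise ValueError("mean velocity must be positive")
    inlet = inlet or InletSpec()
    return inlet.fluid.density * mean_velocity * inlet.diameter / inlet.fluid.viscosity


def sample_time_points(waveform: InflowWaveform, labels: list[str] | None = None) -> dict[str, float]:
    """Waveform value (m/s) at each named analysis instant."""
    labels = list(waveform.time_points) if labels is None else labels
    out = {}
    for label in labels:
        if label not in waveform.time_points:
            raise KeyError(f"undefined time point label {label!r}")
        out[label] = float(waveform(np.array(waveform.time_points[label])))
    return out


def load_waveform(path: str | Path) -> InflowWaveform:
    """Load a waveform spec from YAML/JSON.

    Schema: ``period_s``, then either ``harmonics`` (list of
    {k, amplitude, phase_deg}) or ``samples`` (uniform tabulation over one
    period, Fourier-transformed to len//2 harmonics), plus optional
    ``time_points`` ({label: seconds}).
    """
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    period = float(data["period_s"])
    if "harmonics" in data:
        kmax = max(int(h["k"]) for h in data["harmonics"])
        coeffs = np.zeros(kmax + 1, dtype=complex)
        for h in data["harmonics"]:
            coeffs[int(h["k"])] = h["amplitude"] * np.exp(1j * np.radians(h.get("phase_deg", 0.0)))
    else:
        samples = np.asarray(data["samples"], dtype=float)
        n = len(samples)
        spec = np.fft.rfft(samples) / n
        coeffs = np.concatenate([[spec[0].real], 2.0 * spec[1:]])
    tp = data.get("time_points", DEFAULT_TIME_POINTS)
    return InflowWaveform(period=period, coefficients=coeffs, time_points={k: float(v) for k, v in tp.items()})
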