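"""Pulsatile Newtonian flow in a rigid straight tube (Womersley flow).

The incompressible Navier–Stokes equations for axial flow u(r, t) in a
rigid circular tube of radius R, driven by a spatially uniform periodic
pressure gradient, reduce to the linear radial diffusion equation

    ρ ∂u/∂t = G(t) + μ (1/r) ∂/∂r (r ∂u/∂r),      u(R, t) = 0,

where G(t) = −∂p/∂z is the (negative) axial pressure gradient.  The
convective term vanishes identically for this unidirectional profile and
continuity is satisfied by construction.  With G expanded in Fourier
harmonics G(t) = Re Σ_k C_k e^{ikωt} (ω = 2π/T), the exact solution is

    k = 0 :  u = C₀ (R² − r²) / (4 μ)                     (Poiseuille)
    k ≥ 1 :  u = Re[ C_k/(iρkω) (1 − J₀(Λ_k r/R)/J₀(Λ_k)) e^{ikωt} ]

with Λ_k = i^{3/2} α_k and the Womersley number α_k = R √(kωρ/μ).  The
wall shear stress on the fluid, τ_w(t) = −μ ∂u/∂r |_{r=R}, follows in
closed form via J₁.

Harmonic amplitudes are kept complex throughout; the real part is taken
only at output, which avoids phase bookkeeping errors.

``fd_solver`` is an independent Crank–Nicolson discretisation of the same
equation, used as a numerical oracle for the closed form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import jv

import yaml

__all__ = [
    "FluidProperties",
    "WomersleyCase",
    "womersley_number",
    "analytic_velocity",
    "analytic_wall_shear",
    "fd_solver",
    "load_case",
]

#: Blood density, kg/m^3.
BLOOD_DENSITY = 1050.0
#: Blood dynamic viscosity, kg/(m s).
BLOOD_VISCOSITY = 3.5e-3


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: density ρ (kg/m³) and dynamic viscosity μ (kg/m·s)."""

    density: float = BLOOD_DENSITY
    viscosity: float = BLOOD_VISCOSITY

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be strictly positive")


@dataclass(frozen=True)
class WomersleyCase:
    """Tube + periodic pressure-gradient forcing.

    ``pressure_gradient`` maps harmonic index k (0 = steady) to the complex
    amplitude C_k in Pa/m of the negative axial pressure gradient, so the
    physical forcing is G(t) = Re Σ_k C_k exp(i k ω t).
    """

    radius: float                       # m
    period: float                       # s
    pressure_gradient: dict[int, complex]
    fluid: FluidProperties = field(default_factory=FluidProperties)

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.period <= 0:
            raise ValueError("radius and period must be positive")
        if 0 not in self.pressure_gradient:
            raise ValueError("at least the zeroth (steady) harmonic is required")
        if any(k < 0 for k in self.pressure_gradient):
            raise ValueError("harmonic indices must be non-negative")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / self.period

    def forcing(self, t: np.ndarray) -> np.ndarray:
        """G(t) = Re Σ C_k e^{ikωt}, Pa/m."""
        t = np.asarray(t, dtype=float)
        total = np.zeros_like(t, dtype=complex)
        for k, c in self.pressure_gradient.items():
            total = total + c * np.exp(1j * k * self.omega * t)
        return total.real


def womersley_number(case: WomersleyCase, harmonic: int = 1) -> float:
    """α_k = R √(k ω ρ / μ) for harmonic k ≥ 1."""
    if harmonic < 1:
        raise ValueError("the Womersley number is defined for harmonics k >= 1")
    return case.radius * np.sqrt(
        harmonic * case.omega * case.fluid.density / case.fluid.viscosity
    )


def _lam(case: WomersleyCase, k: int) -> complex:
    """Λ_k = i^{3/2} α_k (principal branch)."""
    return 1j ** 1.5 * womersley_number(case, k)


def analytic_velocity(case: WomersleyCase, r: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Exact axial velocity u(r, t) in m/s; shape (len(t), len(r)).

    Radial positions must lie in [0, R]; no-slip holds at r = R.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(r < 0) or np.any(r > case.radius):
        raise ValueError("radial positions must lie in [0, R]")
    mu = case.fluid.viscosity
    rho = case.fluid.density
    u = np.zeros((len(t), len(r)), dtype=complex)
    for k, c in case.pressure_gradient.items():
        if c == 0:
            continue
        if k == 0:
            u += (c * (case.radius**2 - r**2) / (4.0 * mu))[None, :]
        else:
            lam = _lam(case, k)
            profile = 1.0 - jv(0, lam * r / case.radius) / jv(0, lam)
            phase = np.exp(1j * k * case.omega * t)
            u += (c / (1j * rho * k * case.omega)) * phase[:, None] * profile[None, :]
    return u.real


def analytic_wall_shear(case: WomersleyCase, t: np.ndarray) -> np.ndarray:
    """Exact wall shear stress τ_w(t) = −μ ∂u/∂r at r = R, in Pa.

    Positive values point along the positive tube axis (steady Poiseuille
    gives τ_w = C₀ R / 2).  Harmonic k contributes
    Re[ C_k R J₁(Λ_k) / (Λ_k J₀(Λ_k)) e^{ikωt} ]  (note μ·Λ²/R² = iρkω).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    tau = np.zeros(len(t), dtype=complex)
    for k, c in case.pressure_gradient.items():
        if c == 0:
            continue
        if k == 0:
            tau += c * case.radius / 2.0
        else:
            lam = _lam(case, k)
            # -mu du/dr|_R, simplified with i rho k w = -mu lam^2 / R^2
            coeff = c * case.radius * jv(1, lam) / (lam * jv(0, lam))
            tau += coeff * np.exp(1j * k * case.omega * t)
    return tau.real


# ---------------------------------------------------------------------------
# Finite-difference oracle
# ---------------------------------------------------------------------------

def fd_solver(
    case: WomersleyCase,
    n_radial: int = 100,
    n_steps_per_cycle: int = 1000,
    cycles: int = 5,
    periodicity_tol: float = 1e-8,
    growth_tol: float = 1e3,
):
    """Crank–Nicolson solution of the radial diffusion equation.

    Marches ``cycles`` cardiac cycles from rest to shed the initial
    transient and returns the final cycle.  Symmetry (∂u/∂r = 0) is imposed
    at the axis and no-slip at the wall; wall shear uses a one-sided
    second-order gradient stencil.

    Parameters
    ----------
    n_radial : number of radial intervals (≥ 8)
    n_steps_per_cycle : time steps per cycle
    cycles : total cycles marched (≥ 3)

    Returns
    -------
    dict with keys ``r`` (radial grid, m), ``t`` (times within the final
    cycle, s), ``u`` (velocity, shape (n_steps_per_cycle, n_radial+1)),
    ``wall_shear`` (Pa), ``cycle_change`` (L2 change between the last two
    cycles, for the periodicity check).

    Raises
    ------
    RuntimeError if the solution energy grows across cycles (instability).
    """
    if n_radial < 8:
        raise ValueError("need at least 8 radial intervals")
    if cycles < 3:
        raise ValueError("need at least 3 cycles to shed the transient")
    rho, mu = case.fluid.density, case.fluid.viscosity
    nu = mu / rho
    R = case.radius
    dr = R / n_radial
    dt = case.period / n_steps_per_cycle
    r = np.linspace(0.0, R, n_radial + 1)

    # interior Laplacian (axisymmetric): u'' + u'/r; axis row via L'Hopital: 4(u1-u0)/dr^2
    n = n_radial  # unknowns 0..n-1 (wall value fixed at 0)
    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    diag[0] = -4.0 / dr**2
    upper[0] = 4.0 / dr**2
    ri = r[1:n]
    lower[1:n] = 1.0 / dr**2 - 1.0 / (2.0 * dr * ri)
    diag[1:n] = -2.0 / dr**2
    upper[1:n] = 1.0 / dr**2 + 1.0 / (2.0 * dr * ri)
    # upper[j] multiplies u_{j+1}; the last interior row's upper neighbour is the
    # wall node (u=0), so it drops out of the system.

    theta = 0.5 * nu * dt
    ab = np.zeros((3, n))
    ab[0, 1:] = -theta * upper[:-1]
    ab[1, :] = 1.0 - theta * diag
    ab[2, :-1] = -theta * lower[1:]

    def apply_explicit(u: np.ndarray) -> np.ndarray:
        lap = np.empty(n)
        lap[0] = diag[0] * u[0] + upper[0] * u[1]
        lap[1:-1] = lower[1:-1] * u[:-2] + diag[1:-1] * u[1:-1] + upper[1:-1] * u[2:]
        lap[-1] = lower[-1] * u[-2] + diag[-1] * u[-1]  # wall neighbour is 0
        return u + theta * lap

    u = np.zeros(n)
    times_cycle = np.arange(n_steps_per_cycle) * dt
    prev_cycle = None
    cycle_change = np.inf
    energy_prev = None
    store_u = np.zeros((n_steps_per_cycle, n_radial + 1))
    store_tau = np.zeros(n_steps_per_cycle)

    t_abs = 0.0
    for cyc in range(cycles):
        snapshots = np.zeros((n_steps_per_cycle, n))
        for step in range(n_steps_per_cycle):
            g_mid = 0.5 * (case.forcing(t_abs) + case.forcing(t_abs + dt))
            rhs = apply_explicit(u) + dt * g_mid / rho
            u = solve_banded((1, 1), ab, rhs)
            t_abs += dt
            snapshots[step] = u
        energy = float(np.sum(snapshots**2))
        if energy_prev is not None and energy_prev > 0 and energy > growth_tol * energy_prev:
            raise RuntimeError("finite-difference solution is growing across cycles (unstable)")
        energy_prev = energy
        if prev_cycle is not None:
            denom = np.sqrt(np.sum(prev_cycle**2)) or 1.0
            cycle_change = float(np.sqrt(np.sum((snapshots - prev_cycle) ** 2)) / denom)
        prev_cycle = snapshots

    # final cycle fields; append the fixed wall value
    store_u[:, :n] = prev_cycle
    store_u[:, n] = 0.0
    # one-sided 2nd-order wall gradient with u_wall = 0:
    # du/dr|_R = (3*0 - 4 u_{n-1} + u_{n-2}) / (2 dr)
    dudr = (-4.0 * prev_cycle[:, -1] + prev_cycle[:, -2]) / (2.0 * dr)
    store_tau = -mu * dudr
    # times of the stored snapshots within the final cycle (end-of-step times)
    t_out = (times_cycle + dt) % case.period
    order = np.argsort(t_out)
    return {
        "r": r,
        "t": t_out[order],
        "u": store_u[order],
        "wall_shear": store_tau[order],
        "cycle_change": cycle_change,
    }


# ---------------------------------------------------------------------------
# Case specification files
# ---------------------------------------------------------------------------

def load_case(path: str | Path) -> WomersleyCase:
    """Load a case from YAML/JSON.

    Schema::

        radius_m: 0.016
        period_s: 0.8
        fluid: {rho: 1050.0, mu: 0.0035}
        harmonics:
          - {k: 0, amplitude_pa_per_m: 100.0, phase_deg: 0.0}
          - {k: 1, amplitude_pa_per_m: 50.0, phase_deg: 30.0}
    """
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    fluid = FluidProperties(
        density=float(data.get("fluid", {}).get("rho", BLOOD_DENSITY)),
        viscosity=float(data.get("fluid", {}).get("mu", BLOOD_VISCOSITY)),
    )
    grad = {
        int(h["k"]): h["amplitude_pa_per_m"]
        * np.exp(1j * np.radians(h.get("phase_deg", 0.0)))
        for h in data["harmonics"]
    }
    return WomersleyCase(
        radius=float(data["radius_m"]),
        period=float(data["period_s"]),
        pressure_gradient=grad,
        fluid=fluid,
    )
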