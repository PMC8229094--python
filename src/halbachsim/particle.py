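"""Cell model: effective magnetization law, forces, Stokes mobility.

A cell with bound superparamagnetic particles is treated as a single
point-like magnetic entity of total moment m(|B|) aligned with the local
field, so the magnetic force is F = m(|B|) grad|B|.  The moment law is
bookkept directly as a total moment in Am^2 (cells are conventionally
quoted in fAm^2 = 1e-15 Am^2) rather than as an effective magnetization
times cell volume; the two are equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .magnetics import MagnetArray, field_at, grad_Bmag_at

__all__ = [
    "MagnetizationModel",
    "CellModel",
    "Fluid",
    "cell_moment",
    "magnetic_force",
    "gravitational_force",
    "stokes_velocity",
    "FEMTO",
]

#: 1 fAm^2 in Am^2
FEMTO = 1e-15

G_ACCEL = 9.81  # m/s^2


@dataclass(frozen=True)
class MagnetizationModel:
    """Effective moment of a labelled cell versus field magnitude.

    variant:
        ``"arctan"``   m(B) = (2/pi) m_s atan(B / Bs) — fit to the measured
                       ferrofluid magnetization curve (Bs = 22 mT).
        ``"saturated"`` m(B) = m_s for any B > 0 (high-field approximation).
        ``"linear"``   m(B) = (2/pi) (m_s / Bs) B — the low-field tangent of
                       the arctan curve (constant-susceptibility
                       approximation), uncapped over the field range.
    m_s:
        Total effective saturation moment of the cell (Am^2).
    Bs:
        Field-scale parameter of the arctangent curve (T).
    """

    variant: Literal["arctan", "saturated", "linear"] = "arctan"
    m_s: float = 10.0 * FEMTO
    Bs: float = 0.022

    def __post_init__(self) -> None:
        if self.variant not in ("arctan", "saturated", "linear"):
            raise ValueError(f"unknown magnetization variant {self.variant!r}")
        if self.m_s < 0 or self.Bs <= 0:
            raise ValueError("need m_s >= 0 and Bs > 0")

    def moment(self, Bmag):
        return cell_moment(self, Bmag)


def cell_moment(model: MagnetizationModel, Bmag):
    """Effective cell moment m(|B|) in Am^2; accepts scalars or arrays."""
    B = np.asarray(Bmag, dtype=float)
    if np.any(B < 0):
        raise ValueError("field magnitude must be non-negative")
    if model.variant == "arctan":
        m = (2.0 / np.pi) * model.m_s * np.arctan(B / model.Bs)
    elif model.variant == "saturated":
        m = np.full_like(B, model.m_s)
    else:  # linear
        m = (2.0 / np.pi) * (model.m_s / model.Bs) * B
    return float(m) if np.isscalar(Bmag) else m


@dataclass(frozen=True)
class CellModel:
    """A spherical cell with bound magnetic label.

    Defaults follow the simulated cells: 10 um diameter, 1077 kg/m^3.
    """

    radius: float = 5e-6
    density: float = 1077.0
    magnetization: MagnetizationModel = MagnetizationModel()

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.density <= 0:
            raise ValueError("radius and density must be positive")

    @property
    def volume(self) -> float:
        return (4.0 / 3.0) * np.pi * self.radius**3

    def with_moment(self, m_s: float) -> "CellModel":
        """Copy of this cell with a different saturation moment (Am^2)."""
        return replace(self, magnetization=replace(self.magnetization, m_s=m_s))


@dataclass(frozen=True)
class Fluid:
    """Carrier fluid (default: water-like buffer at room temperature)."""

    viscosity: float = 8.9e-4  # Pa s
    density: float = 1000.0  # kg/m^3

    def __post_init__(self) -> None:
        if self.viscosity <= 0 or self.density <= 0:
            raise ValueError("viscosity and density must be positive")


def magnetization_table(model: MagnetizationModel, B_max: float = 0.5, n: int = 201):
    """Tabulated m(B) for curve export/plotting.

    Returns (B_T, moment_fAm2) arrays from 0 to ``B_max`` Tesla.
    """
    B = np.linspace(0.0, B_max, n)
    return B, cell_moment(model, B) / FEMTO


def magnetic_force(array: MagnetArray, point, cell: CellModel):
    """Magnetic force (Fx, Fz) in Newton at a point (or (N,2) points).

    With the cell moment parallel to B the force reduces to
    F = m(|B|) * grad|B|, evaluated from the analytic array field.
    """
    b = field_at(array, point)
    bmag = np.linalg.norm(np.atleast_2d(b), axis=1)
    g = grad_Bmag_at(array, point)
    m = cell_moment(cell.magnetization, bmag)
    if np.asarray(point).ndim == 1:
        return float(m[0]) * g
    return m[:, None] * g


def gravitational_force(cell: CellModel, fluid: Fluid) -> float:
    """Net gravity/buoyancy force on the cell, z-component (N).

    Negative = toward the magnet array (the array sits below the channel,
    so a cell denser than the fluid settles toward it).
    """
    return -G_ACCEL * cell.volume * (cell.density - fluid.density)


def stokes_velocity(force, cell: CellModel, fluid: Fluid):
    """Quasi-static drift velocity v = F / (6 pi eta r) for force(s) F."""
    return np.asarray(force, dtype=float) / (
        6.0 * np.pi * fluid.viscosity * cell.radius
    )
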