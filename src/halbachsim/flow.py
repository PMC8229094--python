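"""Flow-cell geometry, laminar velocity profile and Reynolds number."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .particle import Fluid

__all__ = ["Channel", "velocity_profile", "reynolds", "IBIDI_HEIGHTS"]

#: channel heights (m) of the commercial slide family the geometry follows
IBIDI_HEIGHTS = {"0.2": 200e-6, "0.4": 400e-6, "0.6": 600e-6, "0.8": 800e-6}


@dataclass(frozen=True)
class Channel:
    """Rectangular flow channel with the magnet array against its wall.

    Defaults: 800 um high, 5 mm wide, 50 mm long, 200 um wall, 1 mL/min.
    The channel interior occupies z in [wall, wall + height] in array
    coordinates (z = 0 at the magnet surface).
    """

    height: float = 800e-6
    width: float = 5e-3
    length: float = 50e-3
    wall: float = 200e-6
    flow_rate: float = 1e-6 / 60.0  # 1 mL/min in m^3/s

    def __post_init__(self) -> None:
        for name in ("height", "width", "length", "wall", "flow_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def area(self) -> float:
        """Cross-sectional area (m^2)."""
        return self.height * self.width

    @property
    def mean_velocity(self) -> float:
        return self.flow_rate / self.area

    @property
    def hydraulic_diameter(self) -> float:
        """D = 2 h w / (h + w) for a rectangular duct (m)."""
        return 2.0 * self.height * self.width / (self.height + self.width)

    @property
    def z_bottom(self) -> float:
        """z of the inner array-side wall surface (array coordinates)."""
        return self.wall

    @property
    def z_top(self) -> float:
        return self.wall + self.height

    @property
    def nominal_transit_time(self) -> float:
        return self.length / self.mean_velocity


def velocity_profile(channel: Channel, z_local):
    """Plane-Poiseuille axial velocity at height ``z_local`` above the
    inner bottom wall: v(z) = 6 v_mean (z/h)(1 - z/h); zero at both walls.

    The side walls are ignored (width/height = 6.25 for the default
    geometry), matching the parabolic-profile assumption of the validated
    analytic model.
    """
    z = np.asarray(z_local, dtype=float)
    if np.any(z < 0) or np.any(z > channel.height):
        raise ValueError("z_local outside channel interior")
    u = z / channel.height
    v = 6.0 * channel.mean_velocity * u * (1.0 - u)
    return float(v) if np.isscalar(z_local) else v


def reynolds(channel: Channel, fluid: Fluid) -> float:
    """Reynolds number Re = rho (Q/A) D / eta with D the hydraulic
    diameter.  ~6.5 for the default channel and water, well laminar."""
    return (
        fluid.density
        * channel.mean_velocity
        * channel.hydraulic_diameter
        / fluid.viscosity
    )


def is_laminar(channel: Channel, fluid: Fluid, threshold: float = 2000.0) -> bool:
    return reynolds(channel, fluid) < threshold
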