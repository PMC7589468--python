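"""Flow-field and Brownian-motion primitives for the capture simulator.

The inter-pillar region is reduced to a 2D unit cell: a parallel-plate
channel whose gap equals the inter-pillar spacing and whose length equals
the bed length.  Pressure-driven flow through that gap is plane Poiseuille;
particle diffusion follows Stokes–Einstein.  At the micron scales and
sub-mm/s velocities involved, Re << 1, so inertial lift and Taylor
dispersion are neglected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .device_geometry import DeviceGeometry, open_cross_section

__all__ = [
    "BOLTZMANN",
    "TransportContext",
    "stokes_einstein_diffusivity",
    "poiseuille_velocity",
    "mean_interstitial_velocity",
    "brownian_step",
    "flow_ul_min_to_m3_s",
]

BOLTZMANN = 1.380649e-23  # J/K, exact (SI definition)


def flow_ul_min_to_m3_s(flow_ul_min: float) -> float:
    """Convert a volumetric flow rate from µL/min to m³/s."""
    return flow_ul_min * 1e-9 / 60.0


def stokes_einstein_diffusivity(
    diameter: float, temperature: float, viscosity: float
) -> float:
    """Stokes–Einstein diffusivity ``D = k_B T / (3 π η d)`` in m²/s.

    Parameters are the particle diameter (m), absolute temperature (K) and
    dynamic viscosity (Pa·s); all must be positive.  For a 150 nm vesicle
    in water-like plasma at room temperature D is a few 1e-12 m²/s.
    """
    if diameter <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("diameter, temperature and viscosity must be positive")
    return BOLTZMANN * temperature / (3.0 * np.pi * viscosity * diameter)


@dataclass(frozen=True)
class TransportContext:
    """Fluid, particle and flow conditions for one simulation.

    ``diffusivity`` defaults to the Stokes–Einstein value for the stored
    temperature, viscosity and diameter; pass it explicitly to override
    (e.g. for a measured value).
    """

    temperature: float = 298.0  # K
    viscosity: float = 1.0e-3  # Pa·s, water-like plasma surrogate
    particle_diameter: float = 150e-9  # m
    flow_rate: float = 0.0  # m³/s, device-level volumetric flow
    diffusivity: Optional[float] = None  # m²/s; None -> Stokes-Einstein

    def __post_init__(self) -> None:
        if self.flow_rate < 0:
            raise ValueError("flow_rate must be >= 0")
        if self.diffusivity is None:
            object.__setattr__(
                self,
                "diffusivity",
                stokes_einstein_diffusivity(
                    self.particle_diameter, self.temperature, self.viscosity
                ),
            )
        elif self.diffusivity <= 0:
            raise ValueError("diffusivity override must be positive")

    def with_flow(self, flow_rate_m3_s: float) -> "TransportContext":
        """Copy of this context at a different device-level flow rate."""
        return TransportContext(
            temperature=self.temperature,
            viscosity=self.viscosity,
            particle_diameter=self.particle_diameter,
            flow_rate=flow_rate_m3_s,
            diffusivity=self.diffusivity,
        )


def poiseuille_velocity(y, gap: float, mean_velocity: float):
    """Plane-Poiseuille streamwise velocity at lateral position ``y``.

    ``u(y) = 6 u_mean (y/gap)(1 − y/gap)``: zero at both walls (no slip)
    and 1.5 × u_mean at the centerline.  ``y`` may be a scalar or array and
    must lie in [0, gap].
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > gap):
        raise ValueError("y outside channel [0, gap]")
    frac = y / gap
    out = 6.0 * mean_velocity * frac * (1.0 - frac)
    return float(out) if out.ndim == 0 else out


def mean_interstitial_velocity(
    ctx: TransportContext, device: DeviceGeometry
) -> float:
    """Mean fluid velocity in the inter-pillar gaps, m/s.

    Device-level volumetric flow divided by the open cross-section; for a
    parallel device the per-bed split is implicit in the summed open area.
    """
    area = open_cross_section(device)
    if area <= 0:
        raise ValueError("device open cross-section is zero")
    return ctx.flow_rate / area


def brownian_step(
    D: float, dt: float, rng_draw: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Longitudinal and lateral Brownian displacements for one time step.

    ``rng_draw`` is an array of independent standard-normal deviates with
    leading dimension 2 (one row per axis); each displacement component is
    ``sqrt(2 D dt)`` times a deviate, so the per-axis variance is 2 D dt.
    """
    if D < 0:
        raise ValueError("diffusivity must be >= 0")
    if dt <= 0:
        raise ValueError("time step must be positive")
    draws = np.asarray(rng_draw, dtype=float)
    sigma = np.sqrt(2.0 * D * dt)
    return sigma * draws[0], sigma * draws[1]
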