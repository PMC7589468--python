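"""Chang–Hammer forward-rate kinetics for antibody capture of vesicles.

The Chang–Hammer picture treats bond formation between a surface-tethered
antibody and a particle-borne antigen as a two-stage process: the pair must
first form an encounter complex of radius ``a`` (set by the reach of the
antibody arms, ~10 nm), then react at an intrinsic rate while the complex
persists.  Relative motion between the particle and the wall shortens the
encounter lifetime, so the effective forward rate is the intrinsic rate
attenuated by the encounter Péclet number ``Pe = a v / D``:

    k_f(v) = k_in · n_antigen / (1 + Pe/2)

which reduces to the reaction-limited rate as ``Pe → 0`` and decays
monotonically with slip velocity.  The ``1 + Pe/2`` attenuation follows
from the crossover of the encounter duration between its diffusive
(``a²/2D``) and convective (``a/v``) limits.  The per-particle antigen
count enters as a linear valency factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

__all__ = [
    "KineticsParams",
    "chang_hammer_forward_rate",
    "binding_probability",
    "wall_capture_velocity",
]


@dataclass(frozen=True)
class KineticsParams:
    """Rate constants and surface densities for the capture reaction.

    Parameters
    ----------
    intrinsic_on_rate : float
        Intrinsic (zero-velocity) forward rate per antigen per unit areal
        antibody density, m²·mol⁻¹·s⁻¹.  Multiplied by the areal mAb
        density (mol/m²) it yields a first-order rate (1/s) inside the
        encounter layer.
    encounter_radius : float
        Encounter-complex radius ``a``, meters; also the thickness of the
        near-wall layer inside which binding can occur.
    mab_surface_density : float
        Immobilized antibody density, mol/m² (4 pmole/cm² = 4e-8 mol/m²).
    antigens_per_ev : float
        Antigen copies per particle; linear valency factor.
    mode : {"rate", "per_encounter"}
        "rate": exponential first-order binding during wall contact.
        "per_encounter": a fixed probability per wall encounter
        (``per_encounter_prob``), bypassing the exponential form; with
        probability 1 this is a perfectly absorbing wall.
    capture_surface_factor : float
        Effective ligand-density multiplier folding floor/ceiling capture
        into the two unit-cell walls (default 1.0).
    """

    intrinsic_on_rate: float
    encounter_radius: float
    mab_surface_density: float
    antigens_per_ev: float = 1.0
    mode: Literal["rate", "per_encounter"] = "rate"
    per_encounter_prob: float = 1.0
    capture_surface_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.intrinsic_on_rate < 0:
            raise ValueError("intrinsic_on_rate must be >= 0")
        if self.encounter_radius <= 0:
            raise ValueError("encounter_radius must be positive")
        if self.mab_surface_density < 0 or self.antigens_per_ev < 0:
            raise ValueError("densities and antigen counts must be >= 0")
        if self.mode not in ("rate", "per_encounter"):
            raise ValueError(f"unknown kinetics mode {self.mode!r}")
        if not 0.0 <= self.per_encounter_prob <= 1.0:
            raise ValueError("per_encounter_prob must be in [0, 1]")

    @property
    def effective_mab_density(self) -> float:
        """Areal antibody density including the capture-surface factor."""
        return self.mab_surface_density * self.capture_surface_factor


def chang_hammer_forward_rate(
    params: KineticsParams, slip_velocity: float, D: float
) -> float:
    """Effective forward rate ``k_f`` (per unit ligand density) at a wall.

    ``k_f = k_in · n_antigen / (1 + Pe/2)`` with ``Pe = a v / D``.  Returns
    the reaction-limited rate at zero slip velocity and decreases
    monotonically with velocity.
    """
    if params.intrinsic_on_rate == 0.0:
        return 0.0
    if slip_velocity < 0:
        raise ValueError("slip_velocity must be >= 0")
    if slip_velocity > 0 and D <= 0:
        raise ValueError("Péclet number undefined: D = 0 with nonzero velocity")
    pe = params.encounter_radius * slip_velocity / D if slip_velocity > 0 else 0.0
    return params.intrinsic_on_rate * params.antigens_per_ev / (1.0 + 0.5 * pe)


def binding_probability(k_f: float, ligand_density: float, dt: float):
    """Probability of bond formation during a contact of duration ``dt``.

    ``P = 1 − exp(−k_f · ρ · dt)``; applied only while a particle is within
    the encounter radius of a capture surface.  Saturates at 1 and is
    monotone in every argument.  Accepts array ``dt``.
    """
    if k_f < 0 or ligand_density < 0:
        raise ValueError("rate and ligand density must be >= 0")
    dt = np.asarray(dt, dtype=float)
    if np.any(dt < 0):
        raise ValueError("contact duration must be >= 0")
    out = -np.expm1(-k_f * ligand_density * dt)
    return float(out) if out.ndim == 0 else out


def wall_capture_velocity(
    params: KineticsParams, slip_velocity: float, D: float
) -> float:
    """Robin-boundary capture velocity ``k_w = k_f · ρ · a`` in m/s.

    First-order binding at rate ``k_f ρ`` inside a layer of thickness
    ``a`` is equivalent, for ``k_f ρ a² / D << 1``, to a partially
    absorbing wall with this uptake velocity.
    """
    k_f = chang_hammer_forward_rate(params, slip_velocity, D)
    return k_f * params.effective_mab_density * params.encounter_radius
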