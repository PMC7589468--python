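"""Monte Carlo engine: particle tracking through micropillar beds.

Each particle enters the 2D unit cell (a channel of gap = inter-pillar
spacing, length = bed length) at x = 0 and is stepped forward with plane
Poiseuille convection at its current lateral position plus longitudinal
and lateral Brownian displacements.  Wall interactions either bind the
particle (capture) or reflect it back into the fluid; a particle that
reaches x = bed length is lost.  Batches are repeated until the binomial
confidence interval on the recovery fraction is tighter than the
convergence tolerance.

Wall-binding numerics
---------------------
Two schemes are used, matched to the kinetics mode:

* ``rate`` mode — the partially absorbing (Robin) boundary is realised
  with the Erban–Chapman scheme: when a step attempts to cross a wall the
  particle binds with probability ``1 − exp(−k_f ρ τ_c)`` where
  ``τ_c = a·sqrt(π·dt/D)`` is the effective near-wall contact time of a
  crossing step, and is otherwise reflected.  The scheme converges to the
  boundary condition ``−D ∂c/∂y = k_w c`` (``k_w = k_f ρ a``) and the
  bound fraction is insensitive to the time step.
* ``per_encounter`` mode — wall touches are detected exactly with the
  Brownian-bridge first-passage probability between step endpoints, and
  each touch binds with a fixed probability.  With probability 1 this is
  a perfectly absorbing wall, which is what the closed-form eigenfunction
  benchmark assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .binding_kinetics import (
    KineticsParams,
    binding_probability,
    chang_hammer_forward_rate,
)
from .device_geometry import BedGeometry, DeviceGeometry
from .transport_physics import (
    TransportContext,
    flow_ul_min_to_m3_s,
    poiseuille_velocity,
)

__all__ = [
    "SimulationConfig",
    "RecoveryResult",
    "SweepResult",
    "SampleLoad",
    "simulate_bed",
    "simulate_device",
    "recovery_flow_sweep",
    "run_until_converged",
    "capacity_guard",
    "ParticleStuckError",
]


class ParticleStuckError(RuntimeError):
    """A batch exceeded the hard step cap (likely a unit or config error)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Run controls for the Monte Carlo engine.

    ``flow_rate_ul_min`` (device-level, µL/min) overrides the flow stored
    in the transport context when given.  ``dt = None`` selects the auto
    rule ``sqrt(2 D dt) = gap/20``.  ``launch`` chooses the inlet seeding:
    flux-weighted (probability ∝ local velocity, the physical inlet
    condition for a pressure-driven stream) or uniform across the gap.
    """

    flow_rate_ul_min: Optional[float] = None
    n_particles_per_batch: int = 5000
    max_batches: int = 40
    dt: Optional[float] = None
    seed: int = 0
    convergence_halfwidth: float = 0.005
    ci_level: float = 0.95
    launch: str = "flux"  # "flux" | "uniform"
    plug_flow: bool = False
    min_batches: int = 2
    step_cap_factor: float = 50.0

    def __post_init__(self) -> None:
        if self.n_particles_per_batch <= 0 or self.max_batches <= 0:
            raise ValueError("particle and batch counts must be positive")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("non-positive dt")
        if self.launch not in ("flux", "uniform"):
            raise ValueError(f"unknown launch mode {self.launch!r}")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of one converged simulation."""

    n_bound: int
    n_lost: int
    recovery: float
    ci_low: float
    ci_high: float
    batches_run: int
    converged: bool
    per_batch_recoveries: Tuple[float, ...]

    @property
    def n_total(self) -> int:
        return self.n_bound + self.n_lost


@dataclass(frozen=True)
class SweepResult:
    """Recovery across a grid of volumetric flow rates for one device."""

    flow_rates: Tuple[float, ...]  # µL/min
    recoveries: Tuple[RecoveryResult, ...]
    device: str

    def __post_init__(self) -> None:
        if len(self.flow_rates) != len(self.recoveries):
            raise ValueError("flow_rates and recoveries must have equal length")
        if any(b <= a for a, b in zip(self.flow_rates, self.flow_rates[1:])):
            raise ValueError("flow_rates must be strictly increasing")


@dataclass(frozen=True)
class SampleLoad:
    """A sample to be processed: volume (µL) and particle concentration (1/µL)."""

    volume_ul: float
    particles_per_ul: float

    def __post_init__(self) -> None:
        if self.volume_ul < 0 or self.particles_per_ul < 0:
            raise ValueError("volume and concentration must be >= 0")


# ---------------------------------------------------------------------------
# single-bed batch kernel
# ---------------------------------------------------------------------------


def _auto_dt(gap: float, D: float) -> float:
    # sqrt(2 D dt) = gap / 20
    return gap * gap / (800.0 * D)


def _launch_positions(
    n: int, gap: float, rng: np.random.Generator, launch: str, plug_flow: bool
) -> np.ndarray:
    if launch == "uniform" or plug_flow:
        return rng.uniform(0.0, gap, size=n)
    # flux-weighted for the parabolic profile via rejection against u_max
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = 2 * (n - filled) + 16
        y = rng.uniform(0.0, gap, size=m)
        frac = y / gap
        accept = rng.random(m) < 4.0 * frac * (1.0 - frac)  # u(y)/u_max
        take = y[accept][: n - filled]
        out[filled : filled + take.size] = take
        filled += take.size
    return out


def _run_batch(
    n: int,
    gap: float,
    length: float,
    u_mean: float,
    D: float,
    dt: float,
    kin: KineticsParams,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    y0: Optional[np.ndarray] = None,
) -> Tuple[int, int]:
    """Track ``n`` particles through one bed; return (n_bound, n_lost)."""
    if kin.encounter_radius >= gap / 2.0:
        raise ValueError("encounter_radius must be smaller than half the gap")
    sigma = math.sqrt(2.0 * D * dt)

    if kin.mode == "rate":
        # slip velocity at the encounter distance from the wall
        a = kin.encounter_radius
        if cfg.plug_flow:
            v_slip = u_mean
        else:
            v_slip = poiseuille_velocity(min(a, gap / 2.0), gap, u_mean)
        k_f = chang_hammer_forward_rate(kin, v_slip, D)
        tau_contact = a * math.sqrt(math.pi * dt / D)
        p_bind = binding_probability(k_f, kin.effective_mab_density, tau_contact)
    else:
        p_bind = kin.per_encounter_prob

    if y0 is None:
        y = _launch_positions(n, gap, rng, cfg.launch, cfg.plug_flow)
    else:
        y = np.array(y0, dtype=float)
        n = y.size
    x = np.zeros(n)

    n_bound = 0
    n_lost = 0
    if u_mean > 0:
        expected_steps = (length / u_mean) / dt
        step_cap = max(int(cfg.step_cap_factor * expected_steps), 10_000)
    else:
        step_cap = max(int(cfg.step_cap_factor * (gap * gap / D) / dt), 10_000)

    inv_2Ddt = 1.0 / (2.0 * D * dt)  # Brownian-bridge exponent scale
    steps = 0
    while x.size:
        steps += 1
        if steps > step_cap:
            raise ParticleStuckError(
                f"{x.size} particles still active after {step_cap} steps "
                f"(gap={gap:g} m, L={length:g} m, u_mean={u_mean:g} m/s, "
                f"D={D:g} m²/s, dt={dt:g} s, mode={kin.mode})"
            )
        if cfg.plug_flow:
            u = u_mean
        else:
            frac = y / gap
            u = 6.0 * u_mean * frac * (1.0 - frac)
        x = x + u * dt + sigma * rng.standard_normal(x.size)
        y_new = y + sigma * rng.standard_normal(x.size)

        if kin.mode == "per_encounter":
            # exact first-passage to either wall via the Brownian bridge
            p_lo = np.exp(np.minimum(-y * y_new * 2.0 * inv_2Ddt, 0.0))
            gy, gy_new = gap - y, gap - y_new
            p_hi = np.exp(np.minimum(-gy * gy_new * 2.0 * inv_2Ddt, 0.0))
            touched = (rng.random(x.size) < p_lo) | (rng.random(x.size) < p_hi)
            if p_bind >= 1.0:
                bound = touched
            else:
                bound = touched & (rng.random(x.size) < p_bind)
        else:
            crossing = (y_new < 0.0) | (y_new > gap)
            bound = crossing & (rng.random(x.size) < p_bind)

        # fold survivors back into the channel (single fold suffices for
        # steps << gap, but repeat defensively)
        y_new = np.abs(y_new)
        over = y_new > gap
        while np.any(over):
            y_new[over] = 2.0 * gap - y_new[over]
            y_new = np.abs(y_new)
            over = y_new > gap

        lost = (~bound) & (x >= length)
        n_bound += int(np.count_nonzero(bound))
        n_lost += int(np.count_nonzero(lost))
        keep = ~(bound | lost)
        x, y = x[keep], y_new[keep]
    return n_bound, n_lost


# ---------------------------------------------------------------------------
# convergence driver
# ---------------------------------------------------------------------------


def run_until_converged(
    batch_runner: Callable[[int, np.random.Generator], Tuple[int, int]],
    cfg: SimulationConfig,
    stream_offset: int = 0,
) -> RecoveryResult:
    """Repeat batches until the recovery CI half-width meets tolerance.

    ``batch_runner(batch_index, rng) -> (n_bound, n_total)`` must be
    deterministic given its substream generator.  Substreams are derived
    from the master seed with a counter-based spawn key, so batches are
    independent and the whole run is reproducible bit-for-bit.
    """
    n_bound_total = 0
    n_total = 0
    per_batch: List[float] = []
    converged = False
    for batch in range(cfg.max_batches):
        rng = np.random.Generator(
            np.random.Philox(
                np.random.SeedSequence(cfg.seed, spawn_key=(stream_offset, batch))
            )
        )
        b, tot = batch_runner(batch, rng)
        n_bound_total += b
        n_total += tot
        per_batch.append(b / tot if tot else float("nan"))
        if batch + 1 >= cfg.min_batches:
            lo, hi = proportion_confint(
                n_bound_total, n_total, alpha=1.0 - cfg.ci_level, method="wilson"
            )
            if (hi - lo) / 2.0 <= cfg.convergence_halfwidth:
                converged = True
                break
    else:
        lo, hi = proportion_confint(
            n_bound_total, n_total, alpha=1.0 - cfg.ci_level, method="wilson"
        )
    if converged:
        lo, hi = proportion_confint(
            n_bound_total, n_total, alpha=1.0 - cfg.ci_level, method="wilson"
        )
    recovery = n_bound_total / n_total if n_total else float("nan")
    return RecoveryResult(
        n_bound=n_bound_total,
        n_lost=n_total - n_bound_total,
        recovery=recovery,
        ci_low=float(lo),
        ci_high=float(hi),
        batches_run=len(per_batch),
        converged=converged,
        per_batch_recoveries=tuple(per_batch),
    )


# ---------------------------------------------------------------------------
# bed- and device-level entry points
# ---------------------------------------------------------------------------


def _resolve_flow(ctx: TransportContext, cfg: SimulationConfig) -> float:
    if cfg.flow_rate_ul_min is not None:
        return flow_ul_min_to_m3_s(cfg.flow_rate_ul_min)
    return ctx.flow_rate


def simulate_bed(
    bed: BedGeometry,
    ctx: TransportContext,
    kin: KineticsParams,
    cfg: SimulationConfig,
    stream_offset: int = 0,
) -> RecoveryResult:
    """Monte Carlo recovery of a single bed at the flow it carries."""
    q = _resolve_flow(ctx, cfg)
    u_mean = q / bed.open_cross_section
    D = ctx.diffusivity
    gap = bed.pillar_spacing
    dt = cfg.dt if cfg.dt is not None else _auto_dt(gap, D)

    def runner(batch: int, rng: np.random.Generator) -> Tuple[int, int]:
        b, lost = _run_batch(
            cfg.n_particles_per_batch, gap, bed.length, u_mean, D, dt, kin, cfg, rng
        )
        return b, b + lost

    return run_until_converged(runner, cfg, stream_offset=stream_offset)


def simulate_device(
    device: DeviceGeometry,
    ctx: TransportContext,
    kin: KineticsParams,
    cfg: SimulationConfig,
    stream_offset: int = 0,
) -> RecoveryResult:
    """Monte Carlo recovery of a whole device.

    Parallel: identical beds each carry Q/n, so the device recovery equals
    a single bed simulated at the per-bed flow.  Serial: survivors of bed i
    seed bed i+1 within each batch, so the device recovery composes as
    ``1 − Π(1 − rᵢ)``.
    """
    q = _resolve_flow(ctx, cfg)
    D = ctx.diffusivity

    if device.arrangement == "parallel":
        bed = device.beds[0]
        per_bed = replace(
            cfg, flow_rate_ul_min=None
        )  # flow passed through ctx below
        bed_ctx = ctx.with_flow(q / device.n_beds)
        return simulate_bed(bed, bed_ctx, kin, per_bed, stream_offset=stream_offset)

    # serial: propagate survivors bed to bed inside each batch
    beds = device.beds
    dts = []
    u_means = []
    for bed in beds:
        u_means.append(q / bed.open_cross_section)
        gap = bed.pillar_spacing
        dts.append(cfg.dt if cfg.dt is not None else _auto_dt(gap, D))

    def runner(batch: int, rng: np.random.Generator) -> Tuple[int, int]:
        n = cfg.n_particles_per_batch
        alive = n
        bound_total = 0
        for bed, u_mean, dt in zip(beds, u_means, dts):
            if alive == 0:
                break
            b, lost = _run_batch(
                alive, bed.pillar_spacing, bed.length, u_mean, D, dt, kin, cfg, rng
            )
            bound_total += b
            alive = lost
        return bound_total, n

    return run_until_converged(runner, cfg, stream_offset=stream_offset)


def recovery_flow_sweep(
    device: DeviceGeometry,
    ctx: TransportContext,
    kin: KineticsParams,
    cfg: SimulationConfig,
    flow_rates: Sequence[float],
) -> SweepResult:
    """Recovery at each flow rate (µL/min), independent RNG substreams."""
    flow_rates = tuple(float(f) for f in flow_rates)
    if not flow_rates:
        raise ValueError("flow_rates must be non-empty")
    results = []
    for i, f in enumerate(flow_rates):
        cfg_i = replace(cfg, flow_rate_ul_min=f)
        results.append(simulate_device(device, ctx, kin, cfg_i, stream_offset=i))
    return SweepResult(
        flow_rates=flow_rates, recoveries=tuple(results), device=device.name
    )


def capacity_guard(
    result: RecoveryResult,
    device: DeviceGeometry,
    sample: SampleLoad,
    ev_diameter: float = 150e-9,
) -> str:
    """Check that a run stays below the monolayer load capacity.

    Returns ``"ok"`` when the expected number of captured particles
    (volume × concentration × recovery) is below the device's monolayer
    capacity, ``"warning"`` otherwise (boundary inclusive) — beyond that
    point the linear-capture assumption of the model is violated.
    """
    from .device_geometry import ev_load_capacity, internal_surface_area

    expected = sample.volume_ul * sample.particles_per_ul * result.recovery
    capacity = ev_load_capacity(internal_surface_area(device), ev_diameter)
    return "warning" if expected >= capacity else "ok"
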