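"""Monte Carlo engine: conservation, determinism, composition, oracles."""

import dataclasses

import numpy as np
import pytest

import evcapture as ev
from evcapture.capture_simulator import SimulationConfig, simulate_bed, simulate_device

from conftest import absorbing_series_capture


@pytest.fixture(scope="module")
def single_gap():
    return ev.make_toy_fixture("single_gap")


def _cfg(**kw):
    defaults = dict(
        n_particles_per_batch=2000,
        max_batches=4,
        seed=42,
        convergence_halfwidth=0.01,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulateBed:
    def test_no_binding_recovery_is_exactly_zero(self):
        device, ctx, kin = ev.make_toy_fixture("no_binding")
        res = simulate_bed(device.beds[0], ctx, kin, _cfg())
        assert res.recovery == 0.0
        assert res.n_bound == 0

    def test_conservation_every_run(self, single_gap):
        device, ctx, kin = single_gap
        cfg = _cfg()
        res = simulate_bed(device.beds[0], ctx, kin, cfg)
        assert res.n_bound + res.n_lost == res.batches_run * cfg.n_particles_per_batch
        assert 0.0 <= res.recovery <= 1.0
        assert res.ci_low <= res.recovery <= res.ci_high

    def test_bit_identical_under_fixed_seed(self, single_gap):
        device, ctx, kin = single_gap
        a = simulate_bed(device.beds[0], ctx, kin, _cfg(seed=7))
        b = simulate_bed(device.beds[0], ctx, kin, _cfg(seed=7))
        assert a == b
        c = simulate_bed(device.beds[0], ctx, kin, _cfg(seed=8))
        assert c != a

    def test_absorbing_channel_matches_eigenfunction_series(self):
        device, ctx, kin = ev.make_toy_fixture("absorbing_channel")
        cfg = _cfg(
            n_particles_per_batch=10_000, max_batches=1, min_batches=1, plug_flow=True
        )
        res = simulate_bed(device.beds[0], ctx, kin, cfg)
        assert res.recovery == pytest.approx(absorbing_series_capture(1.0), abs=0.02)

    def test_uniform_launch_runs(self, single_gap):
        device, ctx, kin = single_gap
        res = simulate_bed(device.beds[0], ctx, kin, _cfg(launch="uniform"))
        assert 0.0 < res.recovery < 1.0

    def test_stuck_particles_raise_diagnostic(self):
        device, ctx, kin = ev.make_toy_fixture("no_binding")
        still = ctx.with_flow(0.0)
        cfg = _cfg(n_particles_per_batch=20, max_batches=1, min_batches=1,
                   step_cap_factor=2.0)
        with pytest.raises(ev.ParticleStuckError, match="u_mean"):
            simulate_bed(device.beds[0], still, kin, cfg)


class TestSimulateDevice:
    def test_parallel_equals_single_bed_at_split_flow(self, single_gap):
        device, ctx, kin = single_gap
        bed = device.beds[0]
        parallel = ev.DeviceGeometry([bed] * 3, "parallel", name="par3")
        cfg = _cfg()
        dev_res = simulate_device(parallel, ctx.with_flow(3 * ctx.flow_rate), kin, cfg)
        bed_res = simulate_bed(bed, ctx, kin, cfg)
        assert dev_res == bed_res

    def test_serial_survival_composition(self, single_gap):
        device, ctx, kin = single_gap
        bed = device.beds[0]
        serial = ev.DeviceGeometry([bed, bed], "serial", name="ser2")
        cfg = _cfg(n_particles_per_batch=4000)
        two = simulate_device(serial, ctx, kin, cfg)
        one = simulate_bed(bed, ctx, kin, cfg)
        composed = 1 - (1 - one.recovery) ** 2
        spread = (one.ci_high - one.ci_low) + (two.ci_high - two.ci_low)
        assert two.recovery == pytest.approx(composed, abs=spread)


class TestRunUntilConverged:
    def test_constant_runner_converges_at_min_batches(self):
        cfg = _cfg(convergence_halfwidth=0.1, max_batches=10)
        res = ev.run_until_converged(lambda i, rng: (50, 100), cfg)
        assert res.converged
        assert res.batches_run == cfg.min_batches
        assert res.recovery == 0.5

    def test_pooled_recovery_is_weighted_mean(self):
        outcomes = [(10, 100), (90, 300), (5, 50)]
        cfg = _cfg(convergence_halfwidth=0.0, max_batches=3, min_batches=1)
        res = ev.run_until_converged(lambda i, rng: outcomes[i], cfg)
        total_b = sum(b for b, _ in outcomes)
        total_n = sum(n for _, n in outcomes)
        assert res.recovery == pytest.approx(total_b / total_n)
        assert not res.converged  # zero tolerance can never be met
        assert res.per_batch_recoveries == pytest.approx(
            tuple(b / n for b, n in outcomes)
        )

    def test_ci_halfwidth_shrinks_as_inverse_sqrt_particles(self):
        def bernoulli(i, rng):
            n = 2000
            return int(rng.binomial(n, 0.3)), n

        short = ev.run_until_converged(
            bernoulli, _cfg(convergence_halfwidth=0.0, max_batches=2, min_batches=1)
        )
        long = ev.run_until_converged(
            bernoulli, _cfg(convergence_halfwidth=0.0, max_batches=8, min_batches=1)
        )
        ratio = ((short.ci_high - short.ci_low) / (long.ci_high - long.ci_low))
        assert ratio == pytest.approx(2.0, rel=0.2)  # 4x particles -> half width


class TestCapacityGuard:
    def test_below_capacity_ok(self, device_3bed):
        res = dataclasses.replace(_fake_result(), recovery=0.41)
        sample = ev.SampleLoad(volume_ul=100.0, particles_per_ul=1.6e8 / 100.0)
        assert ev.capacity_guard(res, device_3bed, sample) == "ok"

    def test_boundary_is_inclusive_warning(self, device_3bed):
        capacity = ev.ev_load_capacity(ev.internal_surface_area(device_3bed), 150e-9)
        res = dataclasses.replace(_fake_result(), recovery=1.0)
        sample = ev.SampleLoad(volume_ul=1.0, particles_per_ul=capacity)
        assert ev.capacity_guard(res, device_3bed, sample) == "warning"

    def test_zero_concentration_ok(self, device_3bed):
        res = dataclasses.replace(_fake_result(), recovery=1.0)
        assert ev.capacity_guard(res, device_3bed, ev.SampleLoad(100.0, 0.0)) == "ok"


def _fake_result() -> ev.RecoveryResult:
    return ev.RecoveryResult(
        n_bound=1, n_lost=1, recovery=0.5, ci_low=0.4, ci_high=0.6,
        batches_run=2, converged=True, per_batch_recoveries=(0.5, 0.5),
    )


class TestSweep:
    def test_recovery_monotone_in_flow(self, single_gap):
        device, ctx, kin = single_gap
        base = ctx.flow_rate * 1e9 * 60  # µL/min of the toy fixture
        sweep = ev.recovery_flow_sweep(
            device, ctx, kin, _cfg(), [base, 2 * base, 4 * base]
        )
        rec = sweep.recoveries
        for a, b in zip(rec, rec[1:]):
            assert b.recovery <= a.recovery + (a.ci_high - a.ci_low)

    def test_flow_rates_must_increase(self, single_gap):
        device, ctx, kin = single_gap
        with pytest.raises(ValueError):
            ev.recovery_flow_sweep(device, ctx, kin, _cfg(), [2.0, 1.0])

    def test_recovery_non_decreasing_in_bed_length(self, single_gap):
        device, ctx, kin = single_gap
        short_bed = device.beds[0]
        long_bed = dataclasses.replace(short_bed, length=3 * short_bed.length)
        cfg = _cfg(n_particles_per_batch=4000)
        # same interstitial velocity: same Q through identical cross-sections
        r_short = simulate_bed(short_bed, ctx, kin, cfg)
        r_long = simulate_bed(long_bed, ctx, kin, cfg)
        assert r_long.recovery > r_short.recovery
        assert r_long.ci_low > r_short.ci_high  # clearly separated
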