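"""Config parsing, packaged fixtures, result serialization and run records.

Human-edited configs are YAML; machine-readable run records are JSON; and
tabular sweep results are CSV with a fixed column order.  Two device
fixtures matching the published 3-bed and 7-bed designs ship with the
package, along with a calibrated kinetics fixture.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple, Union

import pandas as pd
import yaml

from . import __version__
from .binding_kinetics import KineticsParams
from .capture_simulator import RecoveryResult, SimulationConfig, SweepResult
from .device_geometry import BedGeometry, DeviceGeometry
from .transport_physics import TransportContext, mean_interstitial_velocity

__all__ = [
    "ConfigError",
    "load_device_config",
    "load_kinetics_config",
    "packaged_fixture_path",
    "make_toy_fixture",
    "write_results",
    "read_sweep_json",
    "validate_sweep_json",
    "RunRecord",
    "log_run_header",
]

logger = logging.getLogger("evcapture")

SWEEP_CSV_COLUMNS = [
    "flow_ul_min",
    "recovery",
    "ci_low",
    "ci_high",
    "n_bound",
    "n_lost",
    "batches",
    "converged",
]


class ConfigError(ValueError):
    """A config file is missing a key or uses an unknown unit/field."""


# ---------------------------------------------------------------------------
# device / kinetics configs
# ---------------------------------------------------------------------------

_BED_UNIT_KEYS = {
    "length_mm": ("length", 1e-3),
    "width_mm": ("width", 1e-3),
    "depth_um": ("depth", 1e-6),
    "pillar_size_um": ("pillar_size", 1e-6),
    "pillar_spacing_um": ("pillar_spacing", 1e-6),
}


def _bed_from_dict(d: Dict[str, Any], index: int) -> BedGeometry:
    kwargs: Dict[str, Any] = {}
    for key, (field, scale) in _BED_UNIT_KEYS.items():
        if key not in d:
            raise ConfigError(f"beds[{index}]: missing key '{key}'")
        kwargs[field] = float(d[key]) * scale
    for key in ("pillar_shape", "n_pillars"):
        if key not in d:
            raise ConfigError(f"beds[{index}]: missing key '{key}'")
    known = set(_BED_UNIT_KEYS) | {"pillar_shape", "n_pillars"}
    for key in d:
        if key not in known:
            raise ConfigError(
                f"beds[{index}]: unknown key '{key}' (unrecognized unit suffix?)"
            )
    return BedGeometry(
        pillar_shape=str(d["pillar_shape"]),
        n_pillars=int(d["n_pillars"]),
        **kwargs,
    )


def load_device_config(path: Union[str, Path]) -> DeviceGeometry:
    """Load and validate a device geometry YAML, normalizing units to SI."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: device config must be a mapping")
    for key in ("name", "arrangement", "beds"):
        if key not in doc:
            raise ConfigError(f"{path}: missing key '{key}'")
    beds = [_bed_from_dict(b, i) for i, b in enumerate(doc["beds"])]
    return DeviceGeometry(
        beds=beds, arrangement=str(doc["arrangement"]), name=str(doc["name"])
    )


def load_kinetics_config(path: Union[str, Path]) -> KineticsParams:
    """Load a kinetics YAML block into :class:`KineticsParams`."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: kinetics config must be a mapping")
    for key in ("mode", "intrinsic_on_rate", "encounter_radius_nm",
                "mab_density_pmol_cm2", "antigens_per_ev"):
        if key not in doc:
            raise ConfigError(f"{path}: missing key '{key}'")
    return KineticsParams(
        intrinsic_on_rate=float(doc["intrinsic_on_rate"]),
        encounter_radius=float(doc["encounter_radius_nm"]) * 1e-9,
        mab_surface_density=float(doc["mab_density_pmol_cm2"]) * 1e-12 / 1e-4,
        antigens_per_ev=float(doc["antigens_per_ev"]),
        mode=str(doc["mode"]),
        per_encounter_prob=float(doc.get("per_encounter_prob", 1.0)),
        capture_surface_factor=float(doc.get("capture_surface_factor", 1.0)),
    )


def packaged_fixture_path(name: str) -> Path:
    """Path of a packaged fixture file (e.g. ``evmap_3bed.yaml``)."""
    ref = resources.files("evcapture").joinpath("data", name)
    with resources.as_file(ref) as p:
        return Path(p)


# ---------------------------------------------------------------------------
# toy fixtures
# ---------------------------------------------------------------------------


def make_toy_fixture(
    name: str,
) -> Tuple[DeviceGeometry, TransportContext, KineticsParams]:
    """Small, fast configurations with analytically known behavior.

    * ``absorbing_channel`` — perfectly absorbing walls (per-encounter
      probability 1) with flow chosen so the diffusive Fourier number
      ``D·t_res/gap²`` equals 1; pair with ``plug_flow=True`` to compare
      against the absorbing-wall eigenfunction series.
    * ``no_binding`` — zero intrinsic rate; recovery is exactly 0.
    * ``single_gap`` — one short inter-pillar gap with moderate rate
      kinetics; a sub-5-second smoke configuration.
    """
    bed = BedGeometry(
        length=2e-3,
        width=1e-3,
        depth=50e-6,
        pillar_shape="circular",
        pillar_size=10e-6,
        pillar_spacing=10e-6,
        n_pillars=0,
    )
    device = DeviceGeometry(beds=[bed], arrangement="serial", name=name)
    ctx = TransportContext()
    D = ctx.diffusivity
    gap = bed.pillar_spacing

    if name == "absorbing_channel":
        t_res = gap * gap / D  # Fourier number 1
        u = bed.length / t_res
        ctx = ctx.with_flow(u * bed.open_cross_section)
        kin = KineticsParams(
            intrinsic_on_rate=0.0,
            encounter_radius=1e-9,
            mab_surface_density=0.0,
            mode="per_encounter",
            per_encounter_prob=1.0,
        )
    elif name == "no_binding":
        u = 1e-4
        ctx = ctx.with_flow(u * bed.open_cross_section)
        kin = KineticsParams(
            intrinsic_on_rate=0.0,
            encounter_radius=10e-9,
            mab_surface_density=4e-8,
        )
    elif name == "single_gap":
        u = 2e-4
        ctx = ctx.with_flow(u * bed.open_cross_section)
        kin = KineticsParams(
            intrinsic_on_rate=1e7,
            encounter_radius=10e-9,
            mab_surface_density=4e-8,
            antigens_per_ev=10.0,
        )
    else:
        raise ValueError(f"unknown toy fixture {name!r}")
    return device, ctx, kin


# ---------------------------------------------------------------------------
# run records and result serialization
# ---------------------------------------------------------------------------


@dataclass
class RunRecord:
    """Everything needed to re-execute a run bit-identically."""

    config: Dict[str, Any]
    seed: int
    software_version: str = __version__
    started: str = ""
    finished: str = ""
    outputs: List[str] = dataclasses.field(default_factory=list)

    @classmethod
    def start(cls, config: Dict[str, Any], seed: int) -> "RunRecord":
        return cls(
            config=config,
            seed=seed,
            started=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        )

    def finish(self, outputs: List[str]) -> "RunRecord":
        self.finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
        self.outputs = list(outputs)
        return self


def _result_row(flow: Optional[float], r: RecoveryResult) -> Dict[str, Any]:
    return {
        "flow_ul_min": flow,
        "recovery": r.recovery,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "n_bound": r.n_bound,
        "n_lost": r.n_lost,
        "batches": r.batches_run,
        "converged": r.converged,
    }


def sweep_to_frame(sweep: SweepResult) -> pd.DataFrame:
    rows = [_result_row(f, r) for f, r in zip(sweep.flow_rates, sweep.recoveries)]
    return pd.DataFrame(rows, columns=SWEEP_CSV_COLUMNS)


def _sweep_to_json_obj(sweep: SweepResult) -> Dict[str, Any]:
    return {
        "device": sweep.device,
        "flow_rates": list(sweep.flow_rates),
        "recoveries": [asdict(r) for r in sweep.recoveries],
    }


def write_results(
    obj: Union[RecoveryResult, SweepResult],
    path: Union[str, Path],
    fmt: str = "csv",
    run_record: Optional[RunRecord] = None,
) -> List[str]:
    """Serialize a result or sweep; returns the list of files written.

    CSV uses the documented column order with floats at 17 significant
    digits (bit-stable round trips); JSON serializes the full structure
    including per-batch traces.  A run record, when given, is written
    beside the data as ``<path>.run.json``.
    """
    path = Path(path)
    written: List[str] = []
    try:
        if path.parent and not path.parent.exists():
            path.parent.mkdir(parents=True, exist_ok=True)
        if fmt == "csv":
            if isinstance(obj, RecoveryResult):
                frame = pd.DataFrame(
                    [_result_row(None, obj)], columns=SWEEP_CSV_COLUMNS
                )
            else:
                frame = sweep_to_frame(obj)
            frame.to_csv(path, index=False, float_format="%.17g")
        elif fmt == "json":
            doc = (
                asdict(obj)
                if isinstance(obj, RecoveryResult)
                else _sweep_to_json_obj(obj)
            )
            path.write_text(json.dumps(doc, indent=1))
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except OSError as exc:
        raise OSError(f"failed writing results to {path}: {exc}") from exc
    written.append(str(path))
    if run_record is not None:
        rec_path = path.with_suffix(path.suffix + ".run.json")
        rec_path.write_text(json.dumps(asdict(run_record.finish(written)), indent=1))
        written.append(str(rec_path))
    return written


_RECOVERY_FIELDS = {
    "n_bound": int,
    "n_lost": int,
    "recovery": float,
    "ci_low": float,
    "ci_high": float,
    "batches_run": int,
    "converged": bool,
    "per_batch_recoveries": list,
}


def validate_sweep_json(doc: Dict[str, Any]) -> None:
    """Raise ``ConfigError`` if a sweep JSON document is malformed."""
    for key, typ in (("device", str), ("flow_rates", list), ("recoveries", list)):
        if key not in doc:
            raise ConfigError(f"sweep JSON: missing key '{key}'")
        if not isinstance(doc[key], typ):
            raise ConfigError(f"sweep JSON: '{key}' must be {typ.__name__}")
    if len(doc["flow_rates"]) != len(doc["recoveries"]):
        raise ConfigError("sweep JSON: flow_rates/recoveries length mismatch")
    for i, rec in enumerate(doc["recoveries"]):
        for key, typ in _RECOVERY_FIELDS.items():
            if key not in rec:
                raise ConfigError(f"sweep JSON: recoveries[{i}] missing '{key}'")
            if not isinstance(rec[key], typ):
                raise ConfigError(
                    f"sweep JSON: recoveries[{i}].{key} must be {typ.__name__}"
                )


def read_sweep_json(path: Union[str, Path]) -> SweepResult:
    """Read a sweep JSON written by :func:`write_results` back into objects."""
    doc = json.loads(Path(path).read_text())
    validate_sweep_json(doc)
    recs = tuple(
        RecoveryResult(
            n_bound=r["n_bound"],
            n_lost=r["n_lost"],
            recovery=r["recovery"],
            ci_low=r["ci_low"],
            ci_high=r["ci_high"],
            batches_run=r["batches_run"],
            converged=r["converged"],
            per_batch_recoveries=tuple(r["per_batch_recoveries"]),
        )
        for r in doc["recoveries"]
    )
    return SweepResult(
        flow_rates=tuple(doc["flow_rates"]), recoveries=recs, device=doc["device"]
    )


def log_run_header(
    device: DeviceGeometry,
    ctx: TransportContext,
    cfg: SimulationConfig,
) -> None:
    """Log the derived physical quantities so unit errors are visible."""
    from .capture_simulator import _auto_dt, _resolve_flow
    from .device_geometry import open_cross_section

    q = _resolve_flow(ctx, cfg)
    area = open_cross_section(device)
    u = q / area if area else float("nan")
    gap = device.beds[0].pillar_spacing
    dt = cfg.dt if cfg.dt is not None else _auto_dt(gap, ctx.diffusivity)
    logger.info(
        "device=%s Q=%.3g m^3/s open_area=%.3g m^2 u_mean=%.3g m/s "
        "D=%.3g m^2/s dt=%.3g s gap=%.3g m",
        device.name, q, area, u, ctx.diffusivity, dt, gap,
    )
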