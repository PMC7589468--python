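"""Deterministic assay-planning arithmetic: times, throughput, timelines."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Tuple

from .device_geometry import DeviceGeometry

__all__ = [
    "OperatingCondition",
    "processing_time",
    "throughput_ratio",
    "assay_timeline",
]


@dataclass(frozen=True)
class OperatingCondition:
    """Sample volume (µL) to be processed at a volumetric flow rate (µL/min)."""

    flow_rate_ul_min: float
    sample_volume_ul: float

    def __post_init__(self) -> None:
        if self.flow_rate_ul_min < 0 or self.sample_volume_ul < 0:
            raise ValueError("flow rate and volume must be >= 0")


def processing_time(cond: OperatingCondition) -> Tuple[float, float]:
    """Time to push the sample through the device: ``(minutes, hours)``."""
    if cond.flow_rate_ul_min <= 0:
        raise ValueError("flow rate must be positive to compute a time")
    minutes = cond.sample_volume_ul / cond.flow_rate_ul_min
    return minutes, minutes / 60.0


def throughput_ratio(
    dev_a: DeviceGeometry, dev_b: DeviceGeometry, pillar_corrected: bool = False
) -> float:
    """Flow-rate ratio of two devices at matched mean channel velocity.

    Ratio of total cross-sectional flow areas (Σ width × depth over
    parallel beds).  The default uses the raw bed cross-section; set
    ``pillar_corrected=True`` to use the open (pillar-row constriction)
    cross-section instead.
    """
    if pillar_corrected:
        from .device_geometry import open_cross_section

        a, b = open_cross_section(dev_a), open_cross_section(dev_b)
    else:
        a, b = dev_a.total_flow_cross_section, dev_b.total_flow_cross_section
    if a <= 0 or b <= 0:
        raise ValueError("zero flow cross-section")
    return a / b


def assay_timeline(
    stage_durations: Iterable[Tuple[str, float]]
) -> Tuple[float, float, List[Tuple[str, float]]]:
    """Total assay time from per-stage durations.

    Returns ``(total_minutes, total_hours, stages)`` where ``stages`` is
    the per-stage breakdown as given.
    """
    stages = [(str(label), float(minutes)) for label, minutes in stage_durations]
    if any(m < 0 for _, m in stages):
        raise ValueError("stage durations must be >= 0")
    total = sum(m for _, m in stages)
    return total, total / 60.0, stages
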