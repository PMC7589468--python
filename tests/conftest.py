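import numpy as np
import pytest

import evcapture as ev


@pytest.fixture(scope="session")
def device_3bed() -> ev.DeviceGeometry:
    return ev.load_device_config(ev.packaged_fixture_path("evmap_3bed.yaml"))


@pytest.fixture(scope="session")
def device_7bed() -> ev.DeviceGeometry:
    return ev.load_device_config(ev.packaged_fixture_path("evmap_7bed.yaml"))


@pytest.fixture(scope="session")
def kinetics() -> ev.KineticsParams:
    return ev.load_kinetics_config(ev.packaged_fixture_path("kinetics_cd8_ev.yaml"))


@pytest.fixture(scope="session")
def ctx() -> ev.TransportContext:
    return ev.TransportContext()


def absorbing_series_capture(fourier_number: float, n_terms: int = 399) -> float:
    """Closed-form capture fraction for a plug-flow channel with absorbing
    walls: 1 minus the eigenfunction survival series for an initially
    uniform concentration between two absorbing plates."""
    n = np.arange(1, n_terms + 1, 2)
    survival = np.sum(
        8.0 / (n**2 * np.pi**2) * np.exp(-(n * np.pi) ** 2 * fourier_number)
    )
    return 1.0 - float(survival)
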