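import numpy as np
import pytest

from minicirc import geometry as geo


@pytest.fixture(scope="session")
def params() -> geo.HelixParameters:
    return geo.default_helix_parameters()


@pytest.fixture(scope="session")
def make_circle(params):
    """Factory: ideal circularized minicircle (open topology) for a given
    size and helix-phase advance, with the twist quantized to close."""

    def _make(n_bp: int = 105, phase_deg: float = 0.0,
              angle_mode: str = "centerline") -> geo.MinicircleModel:
        p = params.with_phase_shift(phase_deg) if phase_deg else params
        twist = geo.quantize_twist(params.twist_deg, n_bp)
        linear = geo.build_ideal_linear("A" * n_bp, p, twist_override=twist)
        return geo.circularize(linear, angle_mode=angle_mode)

    return _make


@pytest.fixture(scope="session")
def closed105(make_circle) -> geo.MinicircleModel:
    return geo.close_topology(make_circle(105))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260903)
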