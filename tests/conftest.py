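import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from vismem import ModelParams, build_ternus, correspondence, stream_events

# Decay rate fitted to the retinotopic dominance data (time constant ~34 ms)
TAU_FITTED = 0.0291


@pytest.fixture
def tau_fitted() -> float:
    return TAU_FITTED


@pytest.fixture
def gen_params() -> ModelParams:
    """Generating parameters used for synthetic observers throughout."""
    return ModelParams(tau=TAU_FITTED, sigma=80.0, readout=300.0, variant="gated")


def ternus_train(spec: str, frame_ms: float = 30.0, isi_ms: float = 160.0,
                 percept: str = "group", attended: int = 2):
    display = build_ternus(spec, frame_ms, isi_ms)
    return stream_events(display, correspondence(display, percept), attended)


@pytest.fixture
def make_train():
    return ternus_train
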