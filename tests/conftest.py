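import numpy as np
import pytest

from alternans import (PipelineConfig, TwaPattern, make_beat_template,
                       simulate_tracing)


@pytest.fixture(scope="session")
def template():
    return make_beat_template()


@pytest.fixture(scope="session")
def study_cfg():
    return PipelineConfig.simulation_study()


@pytest.fixture(scope="session")
def stationary50(template):
    """Clean 128-beat tracing with stationary 50 µV alternans + truth."""
    return simulate_tracing(template, TwaPattern(kind="stationary", amplitude_uv=50.0))


@pytest.fixture(scope="session")
def quiescent(template):
    """Clean 128-beat tracing with no alternans at all."""
    return simulate_tracing(template, TwaPattern(kind="none"))
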