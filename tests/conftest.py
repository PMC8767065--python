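import numpy as np
import pytest

import excitoq as xq


@pytest.fixture(scope="session")
def cortical_small():
    """Small seeded cortical cohort shared by estimator tests."""
    params = xq.preset("cortical", n_cells=60, seed=7)
    return xq.gen_calcium_cohort(params)


@pytest.fixture(scope="session")
def cortical_results(cortical_small):
    return xq.analyze_cohort(cortical_small.traces, cortical_small.events)


@pytest.fixture
def simple_events():
    return xq.EventSchedule({"glu_on": 100.0, "glu_off": 400.0, "fccp_on": 700.0})


def make_step_trace(
    levels: list[tuple[float, float]],
    dt: float = 5.0,
    t_end: float = 800.0,
    cell_id: str = "cell",
    kind: str = "excitation_ratio",
) -> xq.RatioTrace:
    """Piecewise-constant trace: ``levels`` is [(start_time, level), ...]."""
    t = np.arange(0.0, t_end + dt / 2, dt)
    v = np.full_like(t, levels[0][1])
    for start, level in levels:
        v[t >= start] = level
    return xq.RatioTrace(cell_id, t, v, kind=kind)


@pytest.fixture
def step_trace_factory():
    return make_step_trace
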