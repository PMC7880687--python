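import numpy as np
import pytest

from cdktrace import (PROLIFERATIVE, QUIESCENT, CdkTrace, TraceSet,
                      TraceSimConfig, simulate_traces)


def make_trace(times, ratios, cell_id="c1", fate=PROLIFERATIVE, lineage="sim"):
    return CdkTrace(cell_id=cell_id, times=np.asarray(times, dtype=float),
                    ratios=np.asarray(ratios, dtype=float), fate=fate,
                    lineage=lineage)


@pytest.fixture(scope="session")
def default_traces():
    """200 traces (100 per fate) at the default generator parameters."""
    return simulate_traces(TraceSimConfig(n_traces_per_class=100, seed=42))


@pytest.fixture
def separable_pair():
    """Two tiny, perfectly separated trace groups on a shared 5-min grid."""
    times = np.arange(0, 65, 5.0)
    high = [make_trace(times, 0.5 + 0.005 * times + 0.01 * i,
                       cell_id=f"p{i}", fate=PROLIFERATIVE) for i in range(4)]
    low = [make_trace(times, np.full(times.size, 0.12 + 0.01 * i),
                      cell_id=f"q{i}", fate=QUIESCENT) for i in range(4)]
    return TraceSet(high), TraceSet(low)
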